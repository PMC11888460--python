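# Methods

## Problem and model

`casgen` designs candidate CRISPR-Cas protein sequences by optimizing in the
latent space of a sequence autoencoder whose geometry has been shaped for
exactly that purpose. The model is a latent-space-regularized max-margin
transformer:

* **Tokenization.** Sequences over the 20 standard amino acids (plus `X` for
  unknown residues) are encoded as `[start, residues…, end, pad…]` over a
  24-symbol vocabulary (pad 0, start 1, end 2, A–Y alphabetical 3–22, X 23)
  at a fixed padded length (1,600 by default, sized so full Cas9/Cas12
  proteins fit; the desk-scale benchmark uses 64). Non-standard residue
  letters (B, Z, J, U, O) map to `X` with a warning; sequences longer than
  `max_len − 2` are rejected rather than truncated, since overflow signals
  bad input.
* **Encoder.** Token embedding plus sinusoidal positional encoding, then a
  stack of post-norm transformer blocks (multi-head self-attention with
  padding-key masking, feed-forward network, residual connections, layer
  normalization, dropout). Per-token outputs are pooled to one d-vector
  `X_i` by a mean over non-pad positions (start-token pooling is available);
  masked mean pooling makes the latent invariant to the amount of padding.
* **Decoder.** The latent is linearly expanded to a `max_len × channels`
  grid and refined by kernel-5, same-padded 1-D convolutions with ReLU,
  ending in a width-24 projection of per-position token logits. Greedy
  (argmax) decoding yields the candidate sequence.
* **Classifier head.** A two-layer perceptron `d → d → 2` with ReLU produces
  Cas/non-Cas logits from the pooled latent; softmax gives probabilities.

## Losses

With latents `X_i`, binary labels (1 = Cas, 0 = non-Cas), and decoder
outputs `ŷ_it`:

* **Classification:** mean cross-entropy `−(1/n) Σ_i log p_{i,y_i}`,
  optionally class-weighted with inverse-frequency weights
  `w_j = n_total / (2 n_j)`; the weighted mean is normalized by the total
  applied weight so balanced data reduces to the plain mean.
* **Margin:** `L_margin = w_cas d_cas + w_noncas d_noncas − w_inter d_inter`,
  where `d_cas`/`d_noncas` are mean squared Euclidean distances over
  unordered same-class pairs (0 for classes with fewer than two members —
  the pair count would otherwise divide by zero) and `d_inter` is the mean
  over all cross-class pairs. The pair sums are computed by the
  Gram-identity `Σ_{ij}‖x_i−y_j‖² = m₂Σ‖x_i‖² + m₁Σ‖y_j‖² − 2⟨Σx, Σy⟩`
  rather than a pair loop, and the implementation is verified against
  brute-force double loops to 1e−9. The loss is unbounded below through the
  `−w_inter d_inter` term; training relies on global gradient-norm clipping
  (default 1.0) to keep steps bounded.
* **Reconstruction:** mean per-position cross-entropy of the true token
  under the softmaxed decoder logits. Positions after the end token are
  excluded by default so the decoder is not rewarded for predicting padding;
  an unmasked mode averaging all `N·T` positions is retained.
* **Total:** `L = α L_recon + β L_CE + γ L_margin`, defaults α=β=γ=1 and
  unit margin weights.

Log arguments are clamped at 1e−12 with a warning.

## Training

Adam (lr 1e−3), global gradient-norm clipping at 1.0, 80/20 stratified
train/validation split, stratified batches guaranteeing both classes per
batch whenever γ > 0 (the margin terms are degenerate on single-class
batches). All randomness — initialization, dropout, splits, batch order —
derives from the configured seeds, so identical configs give bit-identical
histories. Early stopping exists but is off by default to keep runs
deterministic. Per-epoch diagnostics: loss breakdowns on both splits,
validation classifier accuracy, and validation latent silhouette
(Euclidean). With `validation_fraction=0` the validation metrics are
computed on the training split (used by memorization tests).

## Generation

The generative loop is Bayesian optimization over the latent space:

1. k training Cas sequences are encoded and Gaussian-perturbed
   (scale 0.1) to seed the observation set.
2. A Gaussian-process surrogate (constant × RBF + white-noise kernel,
   normalized targets) is fitted to all (latent, objective) pairs each
   iteration.
3. The acquisition function — expected improvement by default, UCB
   optional — is maximized over a 256-point candidate pool: half local
   Gaussian perturbations (scale 0.25) of observed points, half uniform
   draws in the observed bounding box inflated by 20%. Pool enumeration
   rather than gradient ascent keeps proposals deterministic under seed and
   robust in moderate dimension.
4. Proposals are gated by the classifier (threshold 0.5): failures are
   returned unscored with objective `p_cas − 1 ∈ [−1, 0)`, which keeps every
   gated-out value below every structure score while still pointing the
   surrogate toward the Cas region. Gated-pass latents are decoded and
   scored by the structure oracle in [0, 1].
5. After the budget (counted in total evaluations, seeds included) is
   spent, scored candidates are aligned against the reference database and
   any candidate at ≥ 50% identity to a known protein is rejected as
   non-novel.

Percent identity is the best local (Smith–Waterman) alignment under
BLOSUM62 with gap open 11 / extend 1 (first gap residue 11, each further
residue 1), identical columns over alignment length with gap columns
included — the BLAST-style identity denominator. One consequence worth
noting: a terminal mismatch whose substitution score is negative is trimmed
by the optimal local alignment, so e.g. two length-10 sequences differing
only in a final L→W read as 100%, not 90%, identity.

The structure-oracle interface (`score(sequence) → [0,1]`, pTM/TM-score
semantics) is pluggable; external predictors (AlphaFold, Boltz) plug in
behind it and are out of this package's scope. The built-in mock oracle is
the deterministic radial score `exp(−‖encode(seq) − x*‖²/τ)` around a
planted latent target (τ defaults to the latent dimension), which gives the
optimizer a smooth objective with a known optimum and makes the
BO-vs-random comparison meaningful without any external tool. In the
benchmark the planted target is the mean Cas latent shifted by 0.5 per
coordinate and τ is set to the mean squared distance of the Cas latents to
that target, so scores span (0, 1) at whatever scale the trained latent
space settled — a fixed width can underflow to a flat objective when the
margin loss inflates distances. Greedy decoding truncates terminator-less
outputs to `max_len − 2` residues so every candidate is re-encodable under
the model's own length budget.

## Synthetic data

Each family is a uniform-random consensus plus independent per-site
substitutions (uniform over the other 19 letters) at a configurable rate,
with conserved blocks whose lower rate overrides the family rate — a
minimal emulation of motif structure such as the RuvC/HNH domains of Cas9.
A uniform rather than natural-frequency consensus maximizes between-family
divergence, making fixtures crisp (a natural-frequency mode exists). No
indels are generated by default, keeping identity arithmetic transparent.

What this does *not* emulate: phylogenetic correlation between sequences,
indel variation, realistic domain architectures, or any
sequence–structure relationship. Passing benchmarks therefore demonstrates
that the machinery is correct and that the regularizers shape the latent
space as intended on cleanly separable families — not that the model
generates functional Cas proteins from real corpora; that requires
full-scale training and external structure prediction.

## The desk-scale benchmark

The reference experiment (`casgen.benchmark`) uses two families of 100
sequences, length 56 (padded to 64 tokens), 8% per-site divergence, with
two invariant blocks in the Cas-like family and one in the non-Cas family;
model: latent dim 16, 2 encoder layers, width 64, 4 heads, 3 decoder
convolutions; training: 30 epochs, batch 32. These sizes keep a full
train-and-generate cycle to a few CPU-minutes while leaving the
architecture faithful. The paired BO experiment uses 20 seeds at a
40-evaluation budget against uniform random search over the same inflated
box, same seeds, same budget.

At this scale the decoder reconstructs sequences close to the training
families, so generated candidates usually fail the 50%-novelty filter
against the training database — the honest desk-scale outcome; novelty at
the 28–55% identity level requires full-scale training diversity.

## Numerical choices and edge cases

* All computation in float64; the autodiff core is validated against
  central finite differences.
* Softmax and log-softmax subtract a detached row max for stability.
* GP predictive standard deviations are floored at 1e−12; the surrogate's
  interpolation of a noiseless function is tested to 1e−4, and the
  posterior variance at observed points is checked against the fitted
  noise level up to solver jitter (1e−6 of the target variance).
* A failed surrogate fit or prediction falls back to a uniform draw in the
  inflated box with a warning; a failed oracle call marks the candidate
  `score_failed` with objective 0 and the loop continues.
* Malformed token streams decode leniently (warning) because early-training
  decoder output is arbitrary; out-of-range codes are rejected.
* Tie-breaks: acquisition argmax takes the first maximizer in pool order;
  greedy decoding takes NumPy argmax (lowest code wins ties).

## Known limitations

* Desk-scale defaults are not the (unreported) full-scale training
  configuration; headline full-scale results (TM-score, RMSD against real
  Cas structures) are out of scope by design.
* The margin loss treats Cas9/Cas12 as one Cas class, per its two-class
  definition; family labels are carried only as record ids.
* The pure-NumPy model trains comfortably at benchmark sizes but is not
  engineered for corpus-scale runs; swap-in of a GPU framework would be a
  mechanical port of `model_core`/`autodiff`.
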