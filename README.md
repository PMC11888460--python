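# casgen

Generative design of CRISPR-Cas proteins by regularized latent-space
optimization.

Cas9/Cas12 nucleases are the workhorses of programmable genome editing, and
finding novel orthologs — sequences distant from known proteins yet still
folding into a Cas-like architecture — is a search problem over an
astronomically large sequence space. `casgen` attacks it the way a protein
engineer with a labeled corpus would: learn a compact latent representation
of Cas and non-Cas sequences, *shape* that representation so the Cas region
is compact and well separated, then optimize inside it.

The model is a transformer-encoder / 1-D-convolutional-decoder autoencoder
trained under the composite objective

```
L_total = α·L_recon + β·L_CE + γ·L_margin
L_margin = w_cas·d_cas + w_noncas·d_noncas − w_inter·d_inter
```

where `L_recon` is per-position reconstruction cross-entropy, `L_CE` is the
(inverse-class-frequency weighted) Cas/non-Cas classification cross-entropy
on the pooled latent `X_i ∈ R^d`, and the margin term contrasts mean squared
intra-class pair distances (`d_cas`, `d_noncas`) against the mean squared
inter-class pair distance (`d_inter`).

Generation is Bayesian optimization over the latent space: a Gaussian-process
surrogate with an expected-improvement (or UCB) acquisition proposes latent
vectors; a classifier gate forwards only Cas-classified vectors to the
decoder; decoded sequences are scored by a pluggable structure oracle
(pTM/TM-score semantics; external predictors plug in behind the interface,
and a deterministic mock oracle is built in); finally a novelty filter
rejects any candidate at ≥ 50% local-alignment identity (BLOSUM62, BLAST-style
gap costs) to a reference database.

Everything runs on a deterministic NumPy autodiff core plus scikit-learn and
Biopython — no deep-learning framework required — and every stage is seeded
and bit-reproducible. A synthetic-family generator (consensus + per-site
substitution + conserved motif blocks) makes the whole pipeline trainable
and testable without downloading a corpus.

## Worked example

Train the desk-scale benchmark (two synthetic families, 100 sequences each)
and run the generative loop:

```python
from casgen.benchmark import benchmark_dataset, train_benchmark, planted_oracle
from casgen.generation import GenerationConfig, generate_candidates

model, history = train_benchmark(seed=0, gamma=1.0)
final = history.epochs[-1]
print(f"val_accuracy={final.val_accuracy:.3f} val_silhouette={final.val_silhouette:.4f}")

records, labels = benchmark_dataset(seed=0)
cas = [r for r in records if labels[r.id] == 1]
out = generate_candidates(
    model, planted_oracle(model, cas), cas,
    GenerationConfig(iteration_budget=40, initial_seed_count=5, rng_seed=7), cas,
)
best = max(c.objective for c in out)
print(f"candidates={len(out)} best_objective={best:.4f} "
      f"accepted={sum(c.status == 'accepted' for c in out)}")
```

prints

```
val_accuracy=1.000 val_silhouette=0.9999
candidates=40 best_objective=0.3751 accepted=0
```

The classifier separates the two families perfectly and the margin loss
drives the validation silhouette to ~1 (the same seed with `gamma=0` ends
near 0.996 — the regularizer measurably tightens the latent geometry). The
best objective is the mock oracle's radial structure score of the best
decoded candidate. `accepted=0` is the expected desk-scale outcome: a
decoder trained on two small families reconstructs sequences close to them,
so candidates fail the 50%-novelty filter against the training database
itself — novelty requires corpus-scale diversity, which is precisely what
the filter is there to certify.

The same pipeline is scriptable from the shell: `casgen simulate-data`,
`casgen tokenize`, `casgen train`, `casgen generate` (see `casgen --help`).

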