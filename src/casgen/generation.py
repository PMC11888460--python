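"""Classifier-gated Bayesian-optimization generation of novel Cas candidates.

The loop searches the trained latent space for vectors that decode to
foldable Cas-like sequences:

1. **Seeding** — k training Cas sequences are encoded and perturbed with
   Gaussian noise to form the initial observations.
2. **Proposal** — a Gaussian-process surrogate is fitted to all (latent,
   objective) observations and an acquisition function (expected improvement
   or upper confidence bound) is maximized over a candidate pool of local
   perturbations around observed points plus global uniform draws in the
   observed bounding box inflated by 20%.
3. **Gate** — the classifier head scores the proposed latent; vectors below
   the Cas-probability threshold are returned to the optimizer unscored.
4. **Decode and score** — gated-pass latents are decoded to sequences and
   scored by a pluggable structure oracle (pTM/TM-score semantics in [0, 1]).
5. **Objective** — scored points contribute their structure score; gated-out
   points contribute ``cas_probability - 1`` (in [-1, 0)), keeping every
   gated-out value below every scored value while still giving the surrogate
   a gradient toward the Cas region.
6. **Novelty filter** — after the budget is spent, scored candidates are
   aligned against a reference database; any candidate at >= 50% identity
   (BLAST-style local alignment identity) to a known protein is rejected.

Percent identity is computed from the best local alignment under BLOSUM62
with gap open 11 / extend 1, as identical columns over alignment length
including gap columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .model_core import CasGenModel
from .sequence_io import ProteinRecord, encode_sequence, load_fasta, write_fasta

logger = logging.getLogger(__name__)

__all__ = [
    "GenerationConfig",
    "CandidateProtein",
    "SurrogateState",
    "StructureOracle",
    "LatentRadialOracle",
    "classification_gate",
    "propose_next_latent",
    "generate_candidates",
    "pairwise_identity",
    "novelty_filter",
    "write_candidate_outputs",
]


@dataclass(frozen=True)
class GenerationConfig:
    """Knobs of the generative loop.

    ``iteration_budget`` counts *all* objective evaluations including the
    ``initial_seed_count`` seed points, so a budget equal to the seed count
    runs no optimization iterations.
    """

    iteration_budget: int = 40
    initial_seed_count: int = 5
    seed_perturbation_scale: float = 0.1
    gate_threshold: float = 0.5
    acquisition: str = "EI"  # or "UCB"
    ucb_kappa: float = 2.0
    identity_threshold_percent: float = 50.0
    candidate_pool_size: int = 256
    local_proposal_scale: float = 0.25
    strategy: str = "bo"  # or "random": uniform draws in the inflated box
    rng_seed: int = 0

    def __post_init__(self):
        if self.iteration_budget < self.initial_seed_count:
            raise ValueError("iteration_budget must be >= initial_seed_count")
        if not 0.0 <= self.gate_threshold < 1.0:
            raise ValueError("gate_threshold must be in [0, 1)")
        if self.acquisition not in ("EI", "UCB"):
            raise ValueError("acquisition must be 'EI' or 'UCB'")
        if self.strategy not in ("bo", "random"):
            raise ValueError("strategy must be 'bo' or 'random'")


@dataclass
class CandidateProtein:
    """One generated design and its provenance through the loop."""

    latent: np.ndarray
    cas_probability: float
    status: str  # proposed | gated_out | scored | score_failed | rejected_similar | accepted
    sequence: str | None = None
    structure_score: float | None = None
    max_identity_percent: float | None = None
    objective: float = 0.0
    iteration: int = -1


class StructureOracle:
    """Interface: map an amino-acid sequence to a foldability score in [0, 1].

    Implementations must be deterministic for a given sequence within one
    session.  Adapters for external structure predictors implement this
    interface by shelling out; the built-in mock below keeps the loop fully
    self-contained.
    """

    def score(self, sequence: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class LatentRadialOracle(StructureOracle):
    """Deterministic mock oracle: ``exp(-||encode(seq) - target||^2 / tau)``.

    The score peaks at sequences whose (re-)encoded latent lies at a planted
    target, giving the optimizer a smooth objective with a known optimum.
    """

    def __init__(self, model: CasGenModel, target_latent: np.ndarray, tau: float | None = None):
        self.model = model
        self.target = np.asarray(target_latent, dtype=np.float64)
        self.tau = float(tau) if tau is not None else float(len(self.target))

    def score(self, sequence: str) -> float:
        tokens = encode_sequence(ProteinRecord(id="query", sequence=sequence),
                                 self.model.config.max_len)
        z = self.model.encode_to_latent(tokens)[0]
        return float(np.exp(-np.sum((z - self.target) ** 2) / self.tau))


class SurrogateState:
    """Gaussian-process surrogate over observed (latent, objective) pairs."""

    def __init__(self, rng_seed: int = 0, noise_level: float = 1e-6):
        kernel = ConstantKernel(1.0, (1e-4, 1e6)) * RBF(1.0, (1e-2, 1e2)) + WhiteKernel(
            noise_level, (1e-12, 1e-1)
        )
        self.gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, n_restarts_optimizer=1,
            random_state=rng_seed,
        )
        self.X: np.ndarray | None = None
        self.y: np.ndarray | None = None

    def update(self, X: np.ndarray, y: np.ndarray) -> None:
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.float64)
        self.gp.fit(self.X, self.y)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu, sigma = self.gp.predict(np.asarray(X), return_std=True)
        return mu, np.maximum(sigma, 1e-12)

    @property
    def noise_level(self) -> float:
        return float(self.gp.kernel_.k2.noise_level)


def classification_gate(model: CasGenModel, latent: np.ndarray,
                        gate_threshold: float = 0.5) -> tuple[bool, float]:
    """Return (passes, cas_probability); passes iff p_cas >= threshold."""
    p_cas = float(model.classify_latent(np.asarray(latent))[1])
    return p_cas >= gate_threshold, p_cas


def _inflated_box(X: np.ndarray, factor: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    return lo - factor * span, hi + factor * span


def propose_next_latent(surrogate: SurrogateState, config: GenerationConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Maximize the acquisition function over a finite candidate pool.

    The pool mixes local Gaussian perturbations of observed points with
    uniform draws in the observed bounding box inflated by 20%.  If the
    surrogate cannot predict (fit failure), a uniform draw is returned with a
    warning.
    """
    X, y = surrogate.X, surrogate.y
    if X is None or len(X) < 2:
        raise ValueError("surrogate must be fitted on at least 2 observations")
    lo, hi = _inflated_box(X)
    n_local = config.candidate_pool_size // 2
    anchors = X[rng.integers(0, len(X), size=n_local)]
    local = anchors + rng.normal(0.0, config.local_proposal_scale, size=anchors.shape)
    global_ = rng.uniform(lo, hi, size=(config.candidate_pool_size - n_local, X.shape[1]))
    pool = np.clip(np.vstack([local, global_]), lo, hi)
    try:
        mu, sigma = surrogate.predict(pool)
    except Exception:  # fit/predict failure: fall back to a uniform proposal
        logger.warning("surrogate prediction failed; falling back to a uniform proposal")
        return rng.uniform(lo, hi, size=X.shape[1])
    if config.acquisition == "UCB":
        acq = mu + config.ucb_kappa * sigma
    else:
        best = float(y.max())
        z = (mu - best) / sigma
        acq = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
    return pool[int(np.argmax(acq))]


def expected_improvement(surrogate: SurrogateState, X: np.ndarray) -> np.ndarray:
    """EI of candidate points against the incumbent best observation."""
    mu, sigma = surrogate.predict(np.atleast_2d(X))
    best = float(surrogate.y.max())
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


# ----------------------------------------------------------------- identity
_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of the best local alignment of two sequences.

    Smith-Waterman under BLOSUM62 (gap open 11, extend 1); identity is
    100 x identical columns / alignment length, gap columns included in the
    length.  Returns 0 when no positive-scoring local alignment exists.
    Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    alignments = _aligner().align(a, b)
    try:
        best = alignments[0]
    except IndexError:
        return 0.0
    counts = best.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    if length == 0:
        return 0.0
    return 100.0 * counts.identities / length


def novelty_filter(candidates: list[CandidateProtein],
                   reference: list[ProteinRecord],
                   identity_threshold_percent: float = 50.0) -> list[CandidateProtein]:
    """Annotate scored candidates with their maximum identity to the
    reference database and reject those at or above the threshold.

    Candidates without a decoded sequence (gated out) pass through untouched.
    """
    if not reference:
        raise ValueError("reference database must be nonempty")
    for cand in candidates:
        if cand.sequence is None or cand.status in ("gated_out", "score_failed"):
            continue
        if not cand.sequence:
            cand.status = "score_failed"
            continue
        cand.max_identity_percent = max(
            pairwise_identity(cand.sequence, ref.sequence) for ref in reference
        )
        if cand.max_identity_percent >= identity_threshold_percent:
            cand.status = "rejected_similar"
        else:
            cand.status = "accepted"
    return candidates


# ---------------------------------------------------------------- main loop
def _evaluate_latent(model: CasGenModel, oracle: StructureOracle, latent: np.ndarray,
                     config: GenerationConfig, iteration: int) -> CandidateProtein:
    passes, p_cas = classification_gate(model, latent, config.gate_threshold)
    cand = CandidateProtein(latent=np.asarray(latent, dtype=np.float64).copy(),
                            cas_probability=p_cas, status="proposed", iteration=iteration)
    if not passes:
        cand.status = "gated_out"
        cand.objective = p_cas - 1.0
        return cand
    cand.sequence = model.decode_to_sequence(latent)
    try:
        if not cand.sequence:
            raise ValueError("decoded sequence is empty")
        cand.structure_score = float(oracle.score(cand.sequence))
    except Exception as exc:
        logger.warning("structure oracle failed at iteration %d: %s", iteration, exc)
        cand.status = "score_failed"
        cand.structure_score = None
        cand.objective = 0.0
        return cand
    cand.status = "scored"
    cand.objective = cand.structure_score
    return cand


def generate_candidates(
    model: CasGenModel,
    oracle: StructureOracle,
    reference_db: list[ProteinRecord] | str | Path,
    config: GenerationConfig,
    seed_records: list[ProteinRecord],
) -> list[CandidateProtein]:
    """Run the full generative loop and return all candidates with statuses.

    ``seed_records`` are training Cas sequences; ``initial_seed_count`` of
    them (sampled with the loop seed) are encoded and Gaussian-perturbed to
    seed the surrogate.  The loop is fully deterministic given the seed,
    model, oracle, and database.
    """
    if isinstance(reference_db, (str, Path)):
        reference_db = load_fasta(reference_db)
    if not reference_db:
        raise ValueError("reference database must be nonempty")
    if not seed_records:
        raise ValueError("seed_records must be nonempty")
    rng = np.random.default_rng(config.rng_seed)

    k = min(config.initial_seed_count, config.iteration_budget)
    picks = rng.choice(len(seed_records), size=k, replace=len(seed_records) < k)
    seed_tokens = np.stack(
        [encode_sequence(seed_records[i], model.config.max_len).codes for i in picks]
    )
    latents = model.encode_to_latent(seed_tokens)
    latents = latents + rng.normal(0.0, config.seed_perturbation_scale, size=latents.shape)

    candidates = [
        _evaluate_latent(model, oracle, z, config, iteration=i)
        for i, z in enumerate(latents)
    ]
    surrogate = SurrogateState(rng_seed=config.rng_seed)
    box_X = np.array([c.latent for c in candidates])
    for it in range(k, config.iteration_budget):
        X = np.array([c.latent for c in candidates])
        y = np.array([c.objective for c in candidates])
        if config.strategy == "random":
            lo, hi = _inflated_box(box_X)
            nxt = rng.uniform(lo, hi, size=X.shape[1])
        else:
            try:
                surrogate.update(X, y)
                nxt = propose_next_latent(surrogate, config, rng)
            except Exception:
                logger.warning("surrogate fit failed at iteration %d; uniform fallback", it)
                lo, hi = _inflated_box(X)
                nxt = rng.uniform(lo, hi, size=X.shape[1])
        candidates.append(_evaluate_latent(model, oracle, nxt, config, iteration=it))

    return novelty_filter(candidates, reference_db, config.identity_threshold_percent)


def best_objective_trace(candidates: list[CandidateProtein]) -> np.ndarray:
    """Best-so-far objective by iteration (non-decreasing)."""
    ordered = sorted(candidates, key=lambda c: c.iteration)
    return np.maximum.accumulate([c.objective for c in ordered])


def write_candidate_outputs(candidates: list[CandidateProtein], out_dir: str | Path) -> None:
    """Write accepted candidates as FASTA plus a TSV ledger of all candidates."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    accepted = [
        ProteinRecord(id=f"candidate_{i}", sequence=c.sequence)
        for i, c in enumerate(candidates)
        if c.status == "accepted" and c.sequence
    ]
    if accepted:
        write_fasta(accepted, out_dir / "accepted.fasta")
    lines = ["id\tstatus\tcas_probability\tstructure_score\tmax_identity_percent\tobjective"]
    for i, c in enumerate(candidates):
        score = "" if c.structure_score is None else f"{c.structure_score:.6f}"
        ident = "" if c.max_identity_percent is None else f"{c.max_identity_percent:.3f}"
        lines.append(
            f"candidate_{i}\t{c.status}\t{c.cas_probability:.6f}\t{score}\t{ident}\t{c.objective:.6f}"
        )
    (out_dir / "candidates.tsv").write_text("\n".join(lines) + "\n")
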