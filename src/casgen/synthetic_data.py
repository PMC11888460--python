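"""Synthetic labeled protein families for training and testing the pipeline.

Real Cas/non-Cas corpora share a simple coarse structure: each family is a
cloud of sequences around a family consensus, with near-invariant motif
blocks (for Cas9, the RuvC and HNH nuclease domains) embedded in more
variable scaffold.  The generator emulates exactly that: one uniform-random
consensus per family, independent per-site substitution at a configurable
rate, and conserved blocks whose (lower) substitution rate overrides the
family rate.  Families drawn with independent consensuses are far below the
novelty-filter threshold from each other, while within-family identity is
controlled by the substitution rate — which makes classifier and
novelty-filter behavior predictable in tests.

No indels are introduced by default, keeping percent-identity arithmetic
transparent; an optional natural-frequency consensus mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import AMINO_ACIDS, ProteinRecord, write_fasta, write_labels

__all__ = [
    "FamilySpec",
    "family_consensus",
    "generate_family",
    "generate_labeled_dataset",
    "benchmark_specs",
]

# Approximate background amino-acid frequencies in natural proteins
# (UniProt-scale averages), for the optional natural-frequency mode.
_NATURAL_FREQ = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class FamilySpec:
    """One synthetic protein family.

    ``substitution_rate`` is the per-site probability that a sequence differs
    from the consensus (uniform over the other 19 letters);
    ``conserved_blocks`` are ``(start, end, rate)`` half-open intervals whose
    rate overrides the family rate (typically 0 for invariant motifs).
    """

    name: str
    consensus_length: int
    n_sequences: int
    substitution_rate: float = 0.05
    conserved_blocks: tuple[tuple[int, int, float], ...] = ()
    class_label: str = "cas"
    natural_frequencies: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if self.class_label not in ("cas", "noncas"):
            raise ValueError("class_label must be 'cas' or 'noncas'")
        for start, end, rate in self.conserved_blocks:
            if not (0 <= start < end <= self.consensus_length):
                raise ValueError(f"block ({start}, {end}) outside [0, {self.consensus_length})")
            if not 0.0 <= rate <= 1.0:
                raise ValueError("block rates must be in [0, 1]")


def _site_rates(spec: FamilySpec) -> np.ndarray:
    rates = np.full(spec.consensus_length, spec.substitution_rate)
    for start, end, rate in spec.conserved_blocks:
        rates[start:end] = rate
    return rates


def _draw_consensus(spec: FamilySpec, rng: np.random.Generator) -> np.ndarray:
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    if spec.natural_frequencies:
        p = np.array([_NATURAL_FREQ[a] for a in AMINO_ACIDS])
        p /= p.sum()
        return rng.choice(alphabet, size=spec.consensus_length, p=p)
    return rng.choice(alphabet, size=spec.consensus_length)


def family_consensus(spec: FamilySpec) -> str:
    """The consensus sequence a spec's seed deterministically produces."""
    return _draw_consensus(spec, np.random.default_rng(spec.rng_seed)).tobytes().decode()


def generate_family(spec: FamilySpec) -> tuple[list[ProteinRecord], list[int]]:
    """Draw a consensus and ``n_sequences`` mutated copies; seeded.

    Returns the records plus parallel integer labels (1 = cas, 0 = noncas).
    Record ids are ``{name}_{k}``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    consensus = _draw_consensus(spec, rng)
    rates = _site_rates(spec)
    label = 1 if spec.class_label == "cas" else 0
    records, labels = [], []
    for k in range(spec.n_sequences):
        seq = consensus.copy()
        hit = rng.random(spec.consensus_length) < rates
        for pos in np.flatnonzero(hit):
            # uniform over the 19 letters other than the consensus residue
            options = alphabet[alphabet != consensus[pos]]
            seq[pos] = rng.choice(options)
        records.append(ProteinRecord(id=f"{spec.name}_{k}", sequence=seq.tobytes().decode()))
        labels.append(label)
    return records, labels


def generate_labeled_dataset(
    specs: list[FamilySpec],
    fasta_path: str | Path | None = None,
    labels_path: str | Path | None = None,
) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Concatenate families; optionally write FASTA + label TSV.

    Family names must be distinct so record ids are unique.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("family names must be unique")
    records: list[ProteinRecord] = []
    labels: dict[str, int] = {}
    for spec in specs:
        recs, labs = generate_family(spec)
        records.extend(recs)
        labels.update({r.id: y for r, y in zip(recs, labs)})
    if fasta_path is not None:
        write_fasta(records, fasta_path)
    if labels_path is not None:
        write_labels(labels, labels_path)
    return records, labels


def benchmark_specs(seed: int = 0, n_per_class: int = 100,
                    consensus_length: int = 56) -> list[FamilySpec]:
    """The standard two-family benchmark: one Cas-like family with two
    invariant motif blocks (RuvC/HNH-like) and one non-Cas family, 100
    sequences each, 8% per-site divergence.  Block positions scale with the
    consensus length (at length 56: residues 10-18 and 34-42 for the Cas
    family, 20-26 for the non-Cas family)."""

    def block(lo_frac: float, hi_frac: float) -> tuple[int, int, float]:
        return (round(lo_frac * consensus_length), round(hi_frac * consensus_length), 0.0)

    return [
        FamilySpec(
            name="casfam",
            consensus_length=consensus_length,
            n_sequences=n_per_class,
            substitution_rate=0.08,
            conserved_blocks=(block(10 / 56, 18 / 56), block(34 / 56, 42 / 56)),
            class_label="cas",
            rng_seed=seed,
        ),
        FamilySpec(
            name="nonfam",
            consensus_length=consensus_length,
            n_sequences=n_per_class,
            substitution_rate=0.08,
            conserved_blocks=(block(20 / 56, 26 / 56),),
            class_label="noncas",
            rng_seed=seed + 1,
        ),
    ]
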