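"""Amino-acid tokenization and FASTA input/output.

Sequences are encoded over a 24-symbol vocabulary: the 20 standard amino
acids in IUPAC one-letter notation, the unknown-residue symbol ``X``, and
three special tokens (padding, start-of-sequence, end-of-sequence).  Every
encoded sequence has the fixed layout ``[start, residues..., end, pad...]``
and a fixed total length (1,600 positions by default, sized so that full
Cas9/Cas12 proteins fit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

PAD, START, END = 0, 1, 2
UNKNOWN = 23
#: 20 standard amino acids in alphabetical one-letter order, codes 3..22.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Full symbol -> code mapping (the tokenization table).
VOCABULARY: dict[str, int] = {
    "<pad>": PAD,
    "<start>": START,
    "<end>": END,
    **{aa: code for code, aa in enumerate(AMINO_ACIDS, start=3)},
    "X": UNKNOWN,
}
VOCAB_SIZE = 24
DEFAULT_MAX_LEN = 1600

_CODE_TO_SYMBOL = {code: sym for sym, code in VOCABULARY.items()}
# letters accepted in input sequences beyond the standard 20; all map to X
_NONSTANDARD = set("BZJUO")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: an identifier and an uppercase amino-acid string."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if not self.sequence.isupper() or any(c.isspace() for c in self.sequence):
            raise ValueError(f"record {self.id!r}: sequence must be uppercase, no whitespace")
        if "-" in self.sequence or "*" in self.sequence:
            raise ValueError(f"record {self.id!r}: gap/stop characters must be stripped first")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TokenSequence:
    """Fixed-length integer encoding of one protein."""

    codes: np.ndarray
    source_length: int = field(default=0)

    @property
    def max_len(self) -> int:
        return int(self.codes.shape[0])


def load_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; gap (``-``) and stop (``*``) characters are
    stripped with a logged warning.  Raises on a missing or empty file and on
    records whose sequence is empty after cleaning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        raw = str(entry.seq).upper()
        cleaned = raw.replace("-", "").replace("*", "")
        if cleaned != raw:
            logger.warning("record %s: stripped %d gap/stop characters", entry.id, len(raw) - len(cleaned))
        if not cleaned:
            raise ValueError(f"record {entry.id!r} is empty after cleaning")
        records.append(ProteinRecord(id=entry.id, sequence=cleaned))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    """Write records to ``path`` in FASTA format (60-column wrapping)."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seq_records, str(path), "fasta")


def encode_sequence(record: ProteinRecord, max_len: int = DEFAULT_MAX_LEN) -> TokenSequence:
    """Encode one protein as ``[start, residue codes..., end, pad...]``.

    Residues outside the 20 standard letters map to the unknown code with a
    warning.  A sequence longer than ``max_len - 2`` is rejected rather than
    truncated: the fixed length is chosen so valid inputs always fit, and
    overflow signals bad input.
    """
    seq = record.sequence
    if len(seq) > max_len - 2:
        raise ValueError(
            f"record {record.id!r}: length {len(seq)} exceeds max_len - 2 = {max_len - 2}"
        )
    codes = np.zeros(max_len, dtype=np.int64)
    codes[0] = START
    n_unknown = 0
    for i, aa in enumerate(seq, start=1):
        code = VOCABULARY.get(aa)
        if code is None or aa == "X":
            code = UNKNOWN
            if aa != "X":
                n_unknown += 1
        codes[i] = code
    if n_unknown:
        logger.warning("record %s: %d non-standard residues mapped to X", record.id, n_unknown)
    codes[len(seq) + 1] = END
    return TokenSequence(codes=codes, source_length=len(seq))


def decode_tokens(tokens: TokenSequence | np.ndarray) -> str:
    """Invert :func:`encode_sequence`: read codes between start and end/pad.

    Malformed streams (missing start or end) are decoded leniently with a
    logged warning rather than rejected, since decoder outputs early in
    training are arbitrary.
    """
    codes = tokens.codes if isinstance(tokens, TokenSequence) else np.asarray(tokens)
    codes = codes.astype(np.int64).ravel()
    if codes.size and (codes.min() < 0 or codes.max() >= VOCAB_SIZE):
        raise ValueError("token codes out of range 0..23")
    start = 0
    if codes.size and codes[0] == START:
        start = 1
    else:
        logger.warning("token stream does not begin with the start token; decoding leniently")
    out: list[str] = []
    for code in codes[start:]:
        if code in (END, PAD):
            break
        if code == START:
            logger.warning("unexpected start token mid-stream; skipped")
            continue
        out.append(_CODE_TO_SYMBOL[int(code)])
    return "".join(out)


def tokenize_records(records: list[ProteinRecord], max_len: int = DEFAULT_MAX_LEN) -> np.ndarray:
    """Encode a list of records into one ``(n, max_len)`` integer matrix."""
    return np.stack([encode_sequence(r, max_len).codes for r in records])


def load_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV (record id, class name) into id -> {0,1} labels.

    Class names ``cas`` and ``noncas`` (case-insensitive) map to 1 and 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels: dict[str, int] = {}
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{line_no}: expected two tab-separated columns")
        rid, cls = parts[0].strip(), parts[1].strip().lower()
        if cls not in ("cas", "noncas"):
            raise ValueError(f"{path}:{line_no}: class must be 'cas' or 'noncas', got {cls!r}")
        labels[rid] = 1 if cls == "cas" else 0
    return labels


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    lines = [f"{rid}\t{'cas' if y == 1 else 'noncas'}" for rid, y in labels.items()]
    Path(path).write_text("\n".join(lines) + "\n")
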