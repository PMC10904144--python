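"""Peptide dataset handling: records, file I/O, synthetic data and splits.

The synthetic generator emulates a labelled DPP-IV inhibitory-peptide
benchmark: variable-length peptides over the 20-letter alphabet where the
positive class carries a planted compositional/positional motif.  The
default motif places proline or alanine at the second residue, the
biological signature of DPP-IV substrate recognition (the enzyme cleaves
after a P/A at the N-terminal dipeptide position), so every downstream
stage — training, evaluation, interpretability — can be exercised without
any external dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from sklearn.model_selection import train_test_split

from .chem import AMINO_ACID_SMILES

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
MIN_LENGTH = 2
MAX_LENGTH = 90

__all__ = [
    "ALPHABET",
    "PeptideRecord",
    "MotifSpec",
    "read_fasta",
    "read_csv",
    "write_fasta",
    "write_csv",
    "generate_synthetic",
    "split_benchmark",
]


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide: identifier, uppercase sequence and optional binary label."""

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not (MIN_LENGTH <= len(seq) <= MAX_LENGTH):
            raise ValueError(
                f"record {self.id!r}: length {len(seq)} outside [{MIN_LENGTH}, {MAX_LENGTH}]"
            )
        bad = sorted({c for c in seq if c not in AMINO_ACID_SMILES})
        if bad:
            raise ValueError(f"record {self.id!r}: non-standard residue(s) {bad}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")


@dataclass
class MotifSpec:
    """Specification of the planted class-separating motif.

    ``motif_positions`` lists ``(position, residue, insertion_probability)``
    triples with 1-based positions; entries sharing a position are mutually
    exclusive alternatives (their probabilities must sum to at most 1, the
    remainder falling back to the background distribution).
    """

    motif_positions: list[tuple[int, str, float]] = field(
        default_factory=lambda: [(2, "P", 0.5), (2, "A", 0.5)]
    )
    length_range: tuple[int, int] = (5, 30)
    background: np.ndarray | None = None  # length-20 frequencies over ALPHABET
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (MIN_LENGTH <= lo <= hi <= MAX_LENGTH):
            raise ValueError(f"length_range {self.length_range} outside [{MIN_LENGTH}, {MAX_LENGTH}]")
        if self.background is None:
            self.background = np.full(len(ALPHABET), 1.0 / len(ALPHABET))
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.background.shape != (len(ALPHABET),) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be 20 frequencies summing to 1")
        by_pos: dict[int, float] = {}
        for pos, residue, prob in self.motif_positions:
            if residue not in AMINO_ACID_SMILES:
                raise ValueError(f"motif residue {residue!r} is not a standard amino acid")
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"insertion probability {prob} outside [0, 1]")
            if pos < 1:
                raise ValueError(f"motif position {pos} must be >= 1 (1-based)")
            if pos > lo:
                raise ValueError(
                    f"motif position {pos} exceeds the minimum length {lo}: "
                    "some positives could not carry the motif"
                )
            by_pos[pos] = by_pos.get(pos, 0.0) + prob
        for pos, total in by_pos.items():
            if total > 1.0 + 1e-9:
                raise ValueError(f"insertion probabilities at position {pos} sum to {total} > 1")


def _random_sequence(rng: np.random.Generator, length: int, background: np.ndarray) -> list[str]:
    idx = rng.choice(len(ALPHABET), size=length, p=background)
    return [ALPHABET[i] for i in idx]


def generate_synthetic(n_pos: int, n_neg: int, spec: MotifSpec | None = None) -> list[PeptideRecord]:
    """Generate a labelled synthetic peptide set with a planted motif.

    Positives carry the motif residues at the configured positions with the
    configured insertion probabilities; negatives are drawn from the
    background alone.  Fully determined by ``spec.seed``.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must both be >= 1")
    spec = spec or MotifSpec()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    by_pos: dict[int, list[tuple[str, float]]] = {}
    for pos, residue, prob in spec.motif_positions:
        by_pos.setdefault(pos, []).append((residue, prob))

    records: list[PeptideRecord] = []
    for i in range(n_pos):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length, spec.background)
        for pos, choices in by_pos.items():
            u = rng.random()
            acc = 0.0
            for residue, prob in choices:
                acc += prob
                if u < acc:
                    seq[pos - 1] = residue
                    break
        records.append(PeptideRecord(id=f"pos_{i:05d}", sequence="".join(seq), label=1))
    for i in range(n_neg):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length, spec.background)
        records.append(PeptideRecord(id=f"neg_{i:05d}", sequence="".join(seq), label=0))
    return records


def _label_from_id(identifier: str) -> tuple[str, int | None]:
    """Split a FASTA id of the form ``name|1`` / ``name|0`` into (name, label)."""
    if "|" in identifier:
        stem, _, tail = identifier.rpartition("|")
        if tail in ("0", "1"):
            return stem, int(tail)
    return identifier, None


def read_fasta(path) -> list[PeptideRecord]:
    """Read peptides from a FASTA file.

    The description after the first whitespace is ignored.  A trailing
    ``|1`` / ``|0`` on the id is interpreted as the binary label.
    """
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {i + 1} ({rec.id!r}) has an empty sequence")
        name, label = _label_from_id(rec.id)
        records.append(PeptideRecord(id=name, sequence=seq, label=label))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def read_csv(path) -> list[PeptideRecord]:
    """Read peptides from a CSV with columns ``sequence`` and optional ``label``/``id``."""
    import pandas as pd

    df = pd.read_csv(path)
    if "sequence" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sequence'")
    has_label = "label" in df.columns
    has_id = "id" in df.columns
    records = []
    for i, row in df.iterrows():
        label = int(row["label"]) if has_label and not pd.isna(row["label"]) else None
        ident = str(row["id"]) if has_id else f"rec_{i:05d}"
        records.append(PeptideRecord(id=ident, sequence=str(row["sequence"]), label=label))
    return records


def write_fasta(records: list[PeptideRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            suffix = "" if rec.label is None else f"|{rec.label}"
            fh.write(f">{rec.id}{suffix}\n{rec.sequence}\n")


def write_csv(records: list[PeptideRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "sequence": [r.sequence for r in records],
            "label": [r.label for r in records],
        }
    ).to_csv(path, index=False)


def split_benchmark(
    records: list[PeptideRecord], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Stratified, seeded split into a benchmark (training) and test set."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    labels = [r.label for r in records]
    if any(l is None for l in labels):
        raise ValueError("all records need labels for a stratified split")
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present to split")
    train, test = train_test_split(
        records, train_size=train_fraction, random_state=seed, stratify=labels
    )
    return list(train), list(test)
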