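"""Model interpretability: Grad-CAM maps, mutational scanning and composition statistics.

Three complementary views of what the classifier has learned:

* **Grad-CAM** — gradients of the positive-class logit flowing into the last
  convolutional feature map of the structural branch weight its activation
  channels; the rectified weighted sum, mapped back onto (residue, atom)
  cells, scores every atom and (by summing a residue's atoms) every
  sequence position.
* **Perturbation scanning** — every position of a peptide is substituted by
  each of the 20 residues and the change in predicted score is recorded;
  absolute changes measure importance, signed changes measure direction of
  effect, and averaging signed changes per (original → substituted) pair
  over a dataset yields the conversion matrix.
* **AAC fold** — the ratio of a residue's amino-acid-composition frequency
  in the positive set to that in the negative set; folds above 1 mark
  residues enriched in inhibitory peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import encode_peptide
from .data import ALPHABET
from .model import ModelParams, predict, preprocess
from . import nnops as nn

__all__ = [
    "ImportanceReport",
    "ConversionMatrix",
    "cam_scores",
    "aggregate_cam",
    "perturb_scan",
    "perturbation_importance",
    "aac_fold",
    "conversion_matrix",
]

logger = logging.getLogger(__name__)

_GRANULARITIES = ("position", "atom", "aa_type")
_METHODS = ("cam", "perturbation_abs", "perturbation_signed")
_AGGREGATIONS = ("single", "dataset_mean", "dataset_sum")


@dataclass
class ImportanceReport:
    """Per-position, per-atom or per-residue-type importance scores.

    Keys are 0-based position ints (``position``), ``(position, atom_index)``
    tuples (``atom``) or one-letter residue codes (``aa_type``).
    """

    granularity: str
    scores: dict
    method: str
    sequence_context: str | None = None
    aggregation: str = "single"
    from_trained_model: bool = True

    def __post_init__(self) -> None:
        if self.granularity not in _GRANULARITIES:
            raise ValueError(f"granularity must be one of {_GRANULARITIES}")
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.aggregation not in _AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {_AGGREGATIONS}")
        if not self.from_trained_model:
            logger.warning("importance report computed from an untrained model")

    # -- lossless CSV round-trip ----------------------------------------
    def to_csv(self, path: str | Path) -> None:
        keys = list(self.scores)
        if self.granularity == "atom":
            key_strs = [f"{r}:{a}" for r, a in keys]
        else:
            key_strs = [str(k) for k in keys]
        df = pd.DataFrame({"key": key_strs, "score": [repr(self.scores[k]) for k in keys]})
        with open(path, "w") as fh:
            fh.write(f"# granularity={self.granularity}\n")
            fh.write(f"# method={self.method}\n")
            fh.write(f"# aggregation={self.aggregation}\n")
            fh.write(f"# sequence_context={self.sequence_context or ''}\n")
            fh.write(f"# from_trained_model={int(self.from_trained_model)}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ImportanceReport":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("# "):
                k, _, v = line[2:].strip().partition("=")
                meta[k] = v
            else:
                body.append(line)
        from io import StringIO

        # scores stay strings: Python float() is round-trip exact, the
        # default pandas float parser is not
        df = pd.read_csv(StringIO("".join(body)), dtype={"key": str, "score": str})
        gran = meta["granularity"]
        scores = {}
        for key_str, score_str in zip(df["key"], df["score"]):
            if gran == "atom":
                r, _, a = key_str.partition(":")
                key = (int(r), int(a))
            elif gran == "position":
                key = int(key_str)
            else:
                key = key_str
            scores[key] = float(score_str)
        return cls(
            granularity=gran,
            scores=scores,
            method=meta["method"],
            sequence_context=meta["sequence_context"] or None,
            aggregation=meta["aggregation"],
            from_trained_model=bool(int(meta["from_trained_model"])),
        )


@dataclass
class ConversionMatrix:
    """Mean model-score change when mutating a row residue into a column residue."""

    aa_subset: list[str]
    matrix: pd.DataFrame  # rows: original residue, columns: substituted residue
    missing: set = field(default_factory=set)  # residues absent from the dataset

    def to_csv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConversionMatrix":
        m = pd.read_csv(path, index_col=0)
        missing = {r for r in m.index if m.loc[r].drop(labels=[r], errors="ignore").isna().all()}
        return cls(aa_subset=list(m.index), matrix=m, missing=missing)


# -- Grad-CAM ------------------------------------------------------------


def cam_scores(
    params: ModelParams, sequence: str
) -> tuple[ImportanceReport, ImportanceReport]:
    """Grad-CAM importance of one peptide at position and atom granularity.

    The differentiation target is the positive-class logit (pre-sigmoid).
    At the structural branch's last convolutional feature map the logit's
    gradient weights the activations *per spatial cell* (gradient x
    activation, summed over channels and rectified).  Globally averaged
    channel weights — the classic formulation for globally-pooled
    classifiers — would discard localization here, because with a
    flatten+linear readout the spatial attention lives in the readout
    weights rather than in activation magnitude.  The rectified map is
    assigned back onto (residue, atom) cells (each stride-2 cell covers a
    2x2 block).  Padding cells score exactly zero; a residue's position
    score is the sum over its atoms.
    """
    if params.config.branch == "text_only":
        raise ValueError("Grad-CAM needs the structural branch; model is text_only")
    tensor = encode_peptide(sequence, params.config.max_residues)
    struct, indices, mask = preprocess([sequence], params.config.max_residues)
    logit, cam_map = params.forward(struct, indices, mask, training=False)
    logit.backward(np.ones(1))
    grads = cam_map.grad[0]  # (C, H', W')
    acts = cam_map.data[0]
    coarse = np.maximum((grads * acts).sum(axis=0), 0.0)
    atom_scores = {}
    position_scores = {}
    for r in range(len(sequence)):
        n_atoms = int(tensor.atom_mask[r].sum())
        total = 0.0
        for a in range(n_atoms):
            s = float(coarse[r // 2, a // 2])
            atom_scores[(r, a)] = s
            total += s
        position_scores[r] = total
    common = dict(
        method="cam", sequence_context=sequence, from_trained_model=params.trained
    )
    return (
        ImportanceReport(granularity="position", scores=position_scores, **common),
        ImportanceReport(granularity="atom", scores=atom_scores, **common),
    )


def aggregate_cam(reports: list[ImportanceReport], by: str) -> ImportanceReport:
    """Aggregate position-level reports across a dataset.

    ``by="position"`` averages scores per position index over the reports
    long enough to reach that position (no zero-imputation for short
    peptides); ``by="aa_type"`` sums scores grouped by residue identity.
    """
    if not reports:
        raise ValueError("cannot aggregate an empty list of reports")
    if any(r.granularity != "position" for r in reports):
        raise ValueError("aggregate_cam expects position-granularity reports")
    if by == "position":
        sums: dict[int, float] = {}
        counts: dict[int, int] = {}
        for rep in reports:
            for pos, score in rep.scores.items():
                sums[pos] = sums.get(pos, 0.0) + score
                counts[pos] = counts.get(pos, 0) + 1
        scores = {pos: sums[pos] / counts[pos] for pos in sums}
        aggregation = "dataset_mean"
    elif by == "aa_type":
        scores = {}
        for rep in reports:
            if rep.sequence_context is None:
                raise ValueError("aa_type aggregation needs sequence_context on every report")
            for pos, score in rep.scores.items():
                aa = rep.sequence_context[pos]
                scores[aa] = scores.get(aa, 0.0) + score
        aggregation = "dataset_sum"
    else:
        raise ValueError(f"unknown aggregation target {by!r}")
    return ImportanceReport(
        granularity="position" if by == "position" else "aa_type",
        scores=scores,
        method=reports[0].method,
        aggregation=aggregation,
        from_trained_model=all(r.from_trained_model for r in reports),
    )


# -- perturbation scanning -------------------------------------------------


def perturb_scan(params: ModelParams, sequence: str) -> np.ndarray:
    """(length x 20) matrix of score deltas for every single-residue substitution.

    Entry (i, b) is ``score(sequence with position i replaced by ALPHABET[b])
    − score(sequence)``; identity substitutions are exactly 0.
    """
    base = float(predict([sequence], params)[0])
    mutants = []
    where = []
    for i in range(len(sequence)):
        for b, residue in enumerate(ALPHABET):
            if residue == sequence[i]:
                continue
            mutants.append(sequence[:i] + residue + sequence[i + 1 :])
            where.append((i, b))
    deltas = np.zeros((len(sequence), len(ALPHABET)))
    if mutants:
        scores = predict(mutants, params)
        for (i, b), s in zip(where, scores):
            deltas[i, b] = s - base
    return deltas


def perturbation_importance(
    scans: list[tuple[str, np.ndarray]], mode: str = "absolute", by: str = "position"
) -> ImportanceReport:
    """Dataset-level perturbation importance.

    ``scans`` pairs each sequence with its :func:`perturb_scan` matrix.
    ``mode="absolute"`` averages |delta| (importance magnitude);
    ``mode="signed"`` averages the raw delta (direction of effect).
    Grouping: ``by="position"`` over all non-identity substitutions at a
    position, ``by="aa_type"`` over all substitutions introducing a residue
    type.  Identity substitutions (X→X) are excluded from the averages.
    """
    if not scans:
        raise ValueError("no perturbation scans given")
    if mode not in ("absolute", "signed"):
        raise ValueError(f"mode must be 'absolute' or 'signed', got {mode!r}")
    if by not in ("position", "aa_type"):
        raise ValueError(f"by must be 'position' or 'aa_type', got {by!r}")
    sums: dict = {}
    counts: dict = {}
    for sequence, deltas in scans:
        if deltas.shape != (len(sequence), len(ALPHABET)):
            raise ValueError("scan matrix shape does not match its sequence")
        for i in range(len(sequence)):
            for b, residue in enumerate(ALPHABET):
                if residue == sequence[i]:
                    continue
                v = abs(deltas[i, b]) if mode == "absolute" else deltas[i, b]
                key = i if by == "position" else residue
                sums[key] = sums.get(key, 0.0) + v
                counts[key] = counts.get(key, 0) + 1
    scores = {k: sums[k] / counts[k] for k in sums}
    return ImportanceReport(
        granularity="position" if by == "position" else "aa_type",
        scores=scores,
        method="perturbation_abs" if mode == "absolute" else "perturbation_signed",
        aggregation="dataset_mean",
    )


def pair_mean_deltas(scans: list[tuple[str, np.ndarray]]) -> dict[tuple[str, str], float]:
    """Mean signed delta per (original residue → substituted residue) pair."""
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for sequence, deltas in scans:
        for i, original in enumerate(sequence):
            for b, residue in enumerate(ALPHABET):
                if residue == original:
                    continue
                key = (original, residue)
                sums[key] = sums.get(key, 0.0) + deltas[i, b]
                counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


# -- composition statistics -------------------------------------------------


def aac_fold(positives: list[str], negatives: list[str]) -> dict[str, float]:
    """Amino-acid-composition fold change, positive set over negative set.

    ``fold(r) = AAC_pos(r) / AAC_neg(r)`` where AAC is the frequency of
    residue ``r`` among all residues of a set.  Folds above 1 mark residues
    enriched in the positive (inhibitory) class.  A residue present in the
    positives but absent from the negatives yields ``inf`` (logged with its
    counts); a residue absent from both yields ``nan``.
    """
    if not positives or not negatives:
        raise ValueError("both sequence sets must be non-empty")

    def _freq(seqs: list[str]) -> tuple[dict[str, int], int]:
        counts = {r: 0 for r in ALPHABET}
        total = 0
        for s in seqs:
            for c in s:
                counts[c] += 1
                total += 1
        return counts, total

    pos_counts, pos_total = _freq(positives)
    neg_counts, neg_total = _freq(negatives)
    folds: dict[str, float] = {}
    for r in ALPHABET:
        p = pos_counts[r] / pos_total
        n = neg_counts[r] / neg_total
        if n == 0.0:
            folds[r] = np.inf if p > 0 else np.nan
            if p > 0:
                logger.warning(
                    "residue %s absent from negatives (positive count %d); fold is infinite",
                    r,
                    pos_counts[r],
                )
        else:
            folds[r] = p / n
    return folds


# -- conversion matrix -------------------------------------------------------


def conversion_matrix(
    params: ModelParams,
    dataset: list[str],
    aa_subset: list[str] | None = None,
    scans: list[tuple[str, np.ndarray]] | None = None,
) -> ConversionMatrix:
    """Mean score change for mutating one residue identity into another.

    Entry (X, Y) averages ``score(mutant) − score(original)`` over every
    occurrence of X in the dataset, with Y substituted at that occurrence.
    The diagonal is exactly 0.  ``aa_subset`` defaults to the four residues
    that occur most frequently in the dataset.  Precomputed ``scans`` (from
    :func:`perturb_scan`) can be passed to avoid re-scoring.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    counts = {r: 0 for r in ALPHABET}
    for seq in dataset:
        for c in seq:
            counts[c] += 1
    if aa_subset is None:
        aa_subset = sorted(ALPHABET, key=lambda r: (-counts[r], r))[:4]
    if scans is None:
        scans = [(seq, perturb_scan(params, seq)) for seq in dataset]
    matrix = pd.DataFrame(0.0, index=list(aa_subset), columns=list(aa_subset))
    missing = set()
    for x in aa_subset:
        if counts[x] == 0:
            missing.add(x)
            matrix.loc[x, :] = np.nan
            matrix.loc[x, x] = 0.0
            logger.warning("residue %s absent from dataset; conversion row flagged missing", x)
            continue
        for y in aa_subset:
            if x == y:
                continue
            b = ALPHABET.index(y)
            acc, m = 0.0, 0
            for seq, deltas in scans:
                for i, c in enumerate(seq):
                    if c == x:
                        acc += deltas[i, b]
                        m += 1
            matrix.loc[x, y] = acc / m
    return ConversionMatrix(aa_subset=list(aa_subset), matrix=matrix, missing=missing)
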