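"""Success classification for assemblies, with and without a reference.

Two modes are implemented:

- reference mode: an assembly succeeds when its composite score reaches 99
  or higher (inclusive);
- novel mode (no reference available): an assembly succeeds when it is a
  single contig of at least 130 kbp carrying an inverted repeat of at least
  17 kbp.

The novel-mode cutoffs can be re-calibrated against a labeled collection of
assemblies by exhaustive grid search maximizing the F1 score, mirroring how
such thresholds are chosen against score-derived truth on reference-bearing
data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats_io import SeqRecord
from .plastome_structure import find_ir

#: default novel-mode thresholds (bp)
DEFAULT_MIN_TOTAL_LEN = 130_000
DEFAULT_MIN_IR_LEN = 17_000
#: reference-mode success threshold (score points, inclusive)
SCORE_SUCCESS_THRESHOLD = 99.0


@dataclass(frozen=True)
class NovelCriteria:
    min_total_len: int = DEFAULT_MIN_TOTAL_LEN
    min_ir_len: int = DEFAULT_MIN_IR_LEN
    require_single_contig: bool = True

    def __post_init__(self) -> None:
        if self.min_total_len <= 0 or self.min_ir_len <= 0:
            raise ValueError("cutoff lengths must be positive")


@dataclass(frozen=True)
class ClassificationOutcome:
    mode: str  # "reference" | "novel"
    success: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.success and self.reasons:
            raise ValueError("a successful outcome cannot carry failure reasons")


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass(frozen=True)
class AssemblyFeatures:
    """Precomputed per-assembly features consumed by threshold search."""

    n_contigs: int
    total_len: int
    max_ir_len: int


def classify_reference_mode(score: float) -> ClassificationOutcome:
    """Success iff the composite score is >= 99 (inclusive)."""
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"score {score} outside [0, 100]")
    if score >= SCORE_SUCCESS_THRESHOLD:
        return ClassificationOutcome("reference", True)
    return ClassificationOutcome(
        "reference", False, (f"score {score:.2f} below {SCORE_SUCCESS_THRESHOLD}",)
    )


def extract_features(assembly: Sequence[SeqRecord], min_probe_ir: int = 1_000) -> AssemblyFeatures:
    """Contig count, total length, and longest IR of the largest contig.

    The IR probe treats the largest contig as circular, which is how a
    finished single-contig plastome is interpreted; ``min_probe_ir`` bounds
    the search below the classification cutoffs of interest.
    """
    if not assembly:
        raise ValueError("empty assembly")
    total = sum(len(rec.seq) for rec in assembly)
    largest = max(assembly, key=lambda rec: len(rec.seq))
    as_circular = SeqRecord(largest.id, largest.seq, "circular")
    structure = find_ir(as_circular, min_ir_len=min_probe_ir)
    return AssemblyFeatures(
        n_contigs=len(assembly),
        total_len=total,
        max_ir_len=structure.ir_len if structure is not None else 0,
    )


def classify_features(
    features: AssemblyFeatures, criteria: NovelCriteria
) -> ClassificationOutcome:
    """Novel-mode criteria applied to precomputed features (inclusive bounds)."""
    reasons = []
    if criteria.require_single_contig and features.n_contigs != 1:
        reasons.append(f"{features.n_contigs} contigs (single contig required)")
    if features.total_len < criteria.min_total_len:
        reasons.append(
            f"total length {features.total_len} below {criteria.min_total_len}"
        )
    if features.max_ir_len < criteria.min_ir_len:
        reasons.append(
            f"longest IR {features.max_ir_len} below {criteria.min_ir_len}"
        )
    return ClassificationOutcome("novel", not reasons, tuple(reasons))


def classify_novel_mode(
    assembly: Sequence[SeqRecord], criteria: NovelCriteria = NovelCriteria()
) -> ClassificationOutcome:
    """Reference-free success call from contig count, length, and IR content."""
    return classify_features(extract_features(assembly), criteria)


def prf(predicted: Sequence[bool], truth: Sequence[bool]) -> PRF:
    """Precision, recall, F1 from paired boolean calls (0 when undefined)."""
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    tp = sum(1 for p, t in zip(predicted, truth) if p and t)
    fp = sum(1 for p, t in zip(predicted, truth) if p and not t)
    fn = sum(1 for p, t in zip(predicted, truth) if not p and t)
    tn = len(truth) - tp - fp - fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return PRF(precision, recall, f1, tp, fp, fn, tn)


def default_length_grid() -> list[int]:
    """100-160 kbp in 1 kbp steps, bracketing typical plastome sizes."""
    return list(range(100_000, 160_001, 1_000))


def default_ir_grid() -> list[int]:
    """10-30 kbp in 0.5 kbp steps, bracketing typical plastome IR sizes."""
    return list(range(10_000, 30_001, 500))


def select_cutoffs(
    labeled: Sequence[tuple[AssemblyFeatures, bool]],
    length_grid: Sequence[int] | None = None,
    ir_grid: Sequence[int] | None = None,
) -> tuple[int, int, PRF]:
    """Grid-search the (min_total_len, min_ir_len) pair maximizing F1.

    Features are precomputed once; every grid point only re-applies the
    inclusive threshold comparisons. Ties break toward the smallest length
    cutoff, then the smallest IR cutoff.
    """
    if not labeled:
        raise ValueError("labeled set is empty")
    length_grid = list(length_grid) if length_grid is not None else default_length_grid()
    ir_grid = list(ir_grid) if ir_grid is not None else default_ir_grid()
    if not length_grid or not ir_grid:
        raise ValueError("grids must be non-empty")

    single = np.array([f.n_contigs == 1 for f, _ in labeled])
    lengths = np.array([f.total_len for f, _ in labeled])
    irs = np.array([f.max_ir_len for f, _ in labeled])
    truth = np.array([t for _, t in labeled], dtype=bool)

    best: tuple[float, int, int] | None = None  # (f1, length_cut, ir_cut)
    best_prf: PRF | None = None
    for length_cut in sorted(length_grid):
        len_ok = single & (lengths >= length_cut)
        for ir_cut in sorted(ir_grid):
            predicted = len_ok & (irs >= ir_cut)
            result = prf(predicted.tolist(), truth.tolist())
            key = (result.f1, length_cut, ir_cut)
            if best is None or result.f1 > best[0]:
                best, best_prf = key, result
    assert best is not None and best_prf is not None
    return best[1], best[2], best_prf
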