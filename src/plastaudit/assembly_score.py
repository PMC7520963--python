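"""The four-component composite assembly score and run-to-run consistency.

An assembly is scored against its reference on a 0-100 scale from four
equally weighted terms::

    score = 25 * (cov_ref + cov_qry + min(cov_qry/cov_ref, cov_ref/cov_qry)
                  + 1/n_contigs)

- completeness ``cov_ref``: fraction of the reference covered by the
  assembly;
- correctness ``cov_qry``: fraction of the assembly covered by the
  reference;
- repeat resolution ``min(cov_qry/cov_ref, cov_ref/cov_qry)``: penalizes a
  size mismatch between assembly and reference, e.g. surplus genome copies
  or unresolved repeats;
- continuity ``1/n_contigs``: rewards single-contig assemblies.

A perfect single-contig assembly scores exactly 100. When either coverage
is zero the repeat term is defined as 0 so failed mappings still yield a
finite (low) score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .alignment_coverage import Aligner, CoverageResult, bidirectional_coverage
from .formats_io import AlignmentRecord, SeqRecord

#: score differences at or below this are treated as identical between runs
CONSISTENCY_TOLERANCE = 0.01


@dataclass(frozen=True)
class ScoreBreakdown:
    cov_ref: float
    cov_qry: float
    repeat_term: float
    n_contigs: int
    score: float

    def rounded(self) -> float:
        """Score at the 2-decimal reporting precision."""
        return round(self.score, 2)

    def as_row(self) -> dict[str, float | int]:
        return {
            "cov_ref": round(self.cov_ref, 6),
            "cov_qry": round(self.cov_qry, 6),
            "repeat_term": round(self.repeat_term, 6),
            "n_contigs": self.n_contigs,
            "score": self.rounded(),
        }


def compute_score(cov_ref: float, cov_qry: float, n_contigs: int) -> ScoreBreakdown:
    """Composite score from the two coverage fractions and the contig count."""
    for name, frac in (("cov_ref", cov_ref), ("cov_qry", cov_qry)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name}={frac} outside [0, 1]")
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if cov_ref == 0.0 or cov_qry == 0.0:
        repeat_term = 0.0
    else:
        repeat_term = min(cov_qry / cov_ref, cov_ref / cov_qry)
    score = 25.0 * (cov_ref + cov_qry + repeat_term + 1.0 / n_contigs)
    return ScoreBreakdown(cov_ref, cov_qry, repeat_term, n_contigs, score)


def score_assembly(
    assembly: Sequence[SeqRecord],
    reference: SeqRecord,
    aligner: Aligner | None = None,
    paf_ref: Sequence[AlignmentRecord] | None = None,
    paf_qry: Sequence[AlignmentRecord] | None = None,
) -> tuple[ScoreBreakdown, CoverageResult]:
    """Score an assembly against a reference through bidirectional coverage."""
    if not assembly:
        raise ValueError("empty assembly")
    coverage = bidirectional_coverage(
        assembly, reference, aligner=aligner, paf_ref=paf_ref, paf_qry=paf_qry
    )
    breakdown = compute_score(coverage.cov_ref, coverage.cov_qry, len(assembly))
    return breakdown, coverage


@dataclass(frozen=True)
class ConsistencyEntry:
    dataset: str
    score_run1: float | None
    score_run2: float | None
    both_succeeded: bool
    abs_diff: float | None
    identical: bool


@dataclass(frozen=True)
class ConsistencyReport:
    entries: tuple[ConsistencyEntry, ...]
    n_identical: int
    n_one_sided_failures: int
    max_abs_diff: float


def compare_runs(
    run1: Mapping[str, ScoreBreakdown | float | None],
    run2: Mapping[str, ScoreBreakdown | float | None],
    tolerance: float = CONSISTENCY_TOLERANCE,
) -> ConsistencyReport:
    """Compare the scores of two independent evaluation runs per dataset.

    ``None`` marks a dataset whose run produced no assembly. Datasets that
    failed in exactly one run are counted as one-sided failures; score pairs
    within ``tolerance`` (inclusive) count as identical.
    """
    if set(run1) != set(run2):
        only1 = sorted(set(run1) - set(run2))
        only2 = sorted(set(run2) - set(run1))
        raise KeyError(f"dataset key mismatch: only run1 {only1}, only run2 {only2}")

    def _score(value: ScoreBreakdown | float | None) -> float | None:
        if value is None:
            return None
        return value.score if isinstance(value, ScoreBreakdown) else float(value)

    entries = []
    for dataset in sorted(run1):
        s1, s2 = _score(run1[dataset]), _score(run2[dataset])
        both = s1 is not None and s2 is not None
        diff = abs(s1 - s2) if both else None
        entries.append(
            ConsistencyEntry(
                dataset=dataset,
                score_run1=s1,
                score_run2=s2,
                both_succeeded=both,
                abs_diff=diff,
                # small epsilon keeps the boundary inclusive under binary
                # floating point (|92.81 - 92.80| slightly exceeds 0.01)
                identical=both and diff <= tolerance + 1e-9,
            )
        )
    one_sided = sum(
        1 for e in entries if (e.score_run1 is None) != (e.score_run2 is None)
    )
    diffs = [e.abs_diff for e in entries if e.abs_diff is not None]
    return ConsistencyReport(
        entries=tuple(entries),
        n_identical=sum(1 for e in entries if e.identical),
        n_one_sided_failures=one_sided,
        max_abs_diff=max(diffs, default=0.0),
    )
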