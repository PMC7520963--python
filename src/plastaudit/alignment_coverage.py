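"""Bidirectional alignment coverage between assembly and reference.

The composite score consumes two coverage fractions:

- ``cov_ref`` — fraction of the *reference* covered when the assembly is
  mapped onto it (completeness);
- ``cov_qry`` — fraction of the *assembly* covered when the reference is
  mapped onto it (correctness).

Both are computed from primary alignments only: every base of the mapped
(query) sequence is assigned to at most one alignment block. That is what
lets surplus sequence show up — a reference mapped onto an assembly holding
two copies of the genome covers only one copy, so ``cov_qry`` drops to 0.5
instead of saturating at 1.

Alignments can come from an external PAF file (e.g. minimap2 output) or
from the built-in exact-match anchor aligner, which finds maximal exact
match blocks on both strands via shared k-mers. The exact aligner is
complete for assemblies that are substrings, rearrangements, rotations or
reverse complements of the reference, which covers every synthetic fixture
in this package; real, diverged data should be aligned externally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .formats_io import AlignmentRecord, SeqRecord, revcomp
from .plastome_structure import maximal_exact_matches

DEFAULT_ANCHOR_K = 15

Aligner = Callable[[SeqRecord, SeqRecord], list[AlignmentRecord]]


@dataclass(frozen=True)
class CoverageResult:
    cov_ref: float
    cov_qry: float
    ref_intervals: dict[str, list[tuple[int, int]]]
    qry_intervals: dict[str, list[tuple[int, int]]]


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals: disjoint, sorted."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def covered_fraction(
    alignments: Sequence[AlignmentRecord],
    side: str,
    total_len_by_id: dict[str, int],
) -> tuple[float, dict[str, list[tuple[int, int]]]]:
    """Fraction of bases covered by the union of primary alignment intervals.

    ``side`` selects which end of each alignment contributes intervals
    ("query" or "target"). The fraction pools all sequences listed in
    ``total_len_by_id``: summed union lengths / summed total lengths.
    """
    if side not in ("query", "target"):
        raise ValueError(f"side must be 'query' or 'target', not {side!r}")
    by_id: dict[str, list[tuple[int, int]]] = {sid: [] for sid in total_len_by_id}
    for aln in alignments:
        if not aln.is_primary:
            continue
        sid = getattr(aln, f"{side}_id")
        start = getattr(aln, f"{side}_start")
        end = getattr(aln, f"{side}_end")
        if sid not in total_len_by_id:
            raise KeyError(f"alignment references unknown sequence {sid!r}")
        if end > total_len_by_id[sid]:
            raise ValueError(
                f"interval [{start}, {end}) exceeds length of {sid!r}"
            )
        by_id[sid].append((start, end))
    merged = {sid: merge_intervals(iv) for sid, iv in by_id.items()}
    covered = sum(end - start for iv in merged.values() for start, end in iv)
    total = sum(total_len_by_id.values())
    if total == 0:
        raise ValueError("total sequence length is zero")
    return covered / total, merged


def _candidate_blocks(
    query: SeqRecord, target: SeqRecord, k: int
) -> list[tuple[int, int, int, str]]:
    """Maximal exact-match blocks (q_start, q_end, t_start, strand) on both strands."""
    blocks: list[tuple[int, int, int, str]] = []
    if len(query.seq) >= k and len(target.seq) >= k:
        for i, j, length in maximal_exact_matches(query.seq, target.seq, k):
            blocks.append((i, i + length, j, "+"))
        rcq = revcomp(query.seq)
        qlen = len(query.seq)
        for i, j, length in maximal_exact_matches(rcq, target.seq, k):
            # block on rc(query) [i, i+L) is query [qlen-i-L, qlen-i) on minus strand
            blocks.append((qlen - i - length, qlen - i, j, "-"))
    return blocks


def _subtract(
    interval: tuple[int, int], covered: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Sub-intervals of interval not overlapped by the (merged) covered list."""
    free = [interval]
    for cs, ce in covered:
        nxt = []
        for fs, fe in free:
            if ce <= fs or cs >= fe:
                nxt.append((fs, fe))
                continue
            if fs < cs:
                nxt.append((fs, cs))
            if ce < fe:
                nxt.append((ce, fe))
        free = nxt
    return free


def _overlap_len(interval: tuple[int, int], covered: Sequence[tuple[int, int]]) -> int:
    s, e = interval
    return sum(max(0, min(e, ce) - max(s, cs)) for cs, ce in covered)


class _PrimaryAssigner:
    """Greedy assignment of query bases to candidate alignment blocks.

    Every query base lands in at most one emitted block (primary-only
    semantics); blocks are trimmed to the still-unassigned sub-intervals of
    their query range. Among the trimmed candidates the assigner repeatedly
    picks the one contributing the most *new target coverage* (longest block
    on ties), which resolves inverted-repeat placement ambiguity: when an
    assembly's IR copy matches both reference IR copies equally well, the
    placement that explains not-yet-covered reference sequence wins, as a
    colinear chaining aligner would choose.
    """

    def __init__(self, min_len: int) -> None:
        self.min_len = min_len
        self.q_covered: dict[str, list[tuple[int, int]]] = {}
        self.t_covered: dict[str, list[tuple[int, int]]] = {}
        self.pending: list[tuple[str, int, int, int, str, SeqRecord, SeqRecord]] = []

    def add(self, query: SeqRecord, target: SeqRecord, k: int) -> None:
        for qs, qe, ts, strand in _candidate_blocks(query, target, k):
            self.pending.append((query.id, qs, qe, ts, strand, query, target))

    def _trimmed_subblocks(self):
        """Yield (gain, length, qid, fs, fe, nts, nte, strand, query, target)."""
        for qid, qs, qe, ts, strand, query, target in self.pending:
            for fs, fe in _subtract((qs, qe), self.q_covered.get(qid, [])):
                if fe - fs < self.min_len:
                    continue
                if strand == "+":
                    nts, nte = ts + (fs - qs), ts + (fe - qs)
                else:
                    nts, nte = ts + (qe - fe), ts + (qe - fs)
                gain = (nte - nts) - _overlap_len(
                    (nts, nte), self.t_covered.get(target.id, [])
                )
                yield gain, fe - fs, qid, fs, fe, nts, nte, strand, query, target

    def assign(self) -> list[AlignmentRecord]:
        records: list[AlignmentRecord] = []
        while True:
            best = max(
                self._trimmed_subblocks(),
                key=lambda b: (b[0], b[1], b[2], -b[3], b[7], -b[5]),
                default=None,
            )
            if best is None:
                break
            _, _, qid, fs, fe, nts, nte, strand, query, target = best
            records.append(
                AlignmentRecord(
                    query_id=query.id,
                    query_len=len(query.seq),
                    query_start=fs,
                    query_end=fe,
                    strand=strand,
                    target_id=target.id,
                    target_len=len(target.seq),
                    target_start=nts,
                    target_end=nte,
                    n_matches=fe - fs,
                    block_len=fe - fs,
                    is_primary=True,
                )
            )
            self.q_covered[qid] = merge_intervals(
                self.q_covered.get(qid, []) + [(fs, fe)]
            )
            self.t_covered[target.id] = merge_intervals(
                self.t_covered.get(target.id, []) + [(nts, nte)]
            )
        return records


def exact_anchor_align(
    query: SeqRecord, target: SeqRecord, k: int = DEFAULT_ANCHOR_K
) -> list[AlignmentRecord]:
    """Exact-match anchor alignment of query against target, both strands.

    Returns primary alignments only: maximal exact match blocks seeded on
    shared k-mers, with each query base assigned to at most one block
    (longest blocks claim their bases first).
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if k > len(query.seq) or k > len(target.seq):
        raise ValueError("k exceeds a sequence length")
    assigner = _PrimaryAssigner(min_len=k)
    assigner.add(query, target, k)
    return assigner.assign()


def bidirectional_coverage(
    assembly: Sequence[SeqRecord],
    reference: SeqRecord,
    aligner: Aligner | None = None,
    paf_ref: Sequence[AlignmentRecord] | None = None,
    paf_qry: Sequence[AlignmentRecord] | None = None,
    k: int = DEFAULT_ANCHOR_K,
) -> CoverageResult:
    """Coverage fractions in both mapping directions.

    assembly -> reference gives cov_ref (reference bases covered);
    reference -> assembly gives cov_qry (assembly bases covered, pooled over
    contigs). Pre-computed alignments may be supplied per direction as
    parsed PAF records (``paf_ref`` for assembly->reference, ``paf_qry`` for
    reference->assembly); otherwise the given aligner (default: the internal
    exact anchor aligner) is run. In the reference->assembly direction the
    primary assignment is global: each reference base maps to at most one
    block across *all* contigs, so duplicated contigs do not double-count.
    """
    if not assembly:
        raise ValueError("empty assembly")
    ref_lens = {reference.id: len(reference.seq)}
    asm_lens = {rec.id: len(rec.seq) for rec in assembly}

    if paf_ref is not None:
        fwd_alignments = list(paf_ref)
    elif aligner is not None:
        fwd_alignments = [a for rec in assembly for a in aligner(rec, reference)]
    else:
        assigner = _PrimaryAssigner(min_len=k)
        for rec in assembly:
            assigner.add(rec, reference, k)
        fwd_alignments = assigner.assign()
    cov_ref, ref_iv = covered_fraction(fwd_alignments, "target", ref_lens)

    if paf_qry is not None:
        rev_alignments = list(paf_qry)
    elif aligner is not None:
        rev_alignments = [a for rec in assembly for a in aligner(reference, rec)]
    else:
        assigner = _PrimaryAssigner(min_len=k)
        for rec in assembly:
            assigner.add(reference, rec, k)
        rev_alignments = assigner.assign()
    cov_qry, qry_iv = covered_fraction(rev_alignments, "target", asm_lens)

    return CoverageResult(
        cov_ref=cov_ref, cov_qry=cov_qry, ref_intervals=ref_iv, qry_intervals=qry_iv
    )
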