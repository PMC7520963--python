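"""Inverted-repeat detection and canonical orientation of plastomes.

Chloroplast genomes are circular molecules with a characteristic
quadripartite layout: a large single-copy region (LSC) and a small
single-copy region (SSC), separated by two identical but oppositely
oriented repeat blocks (IRa, IRb). This module finds that structure on a
circular contig and rotates/orients assemblies into a deterministic
canonical layout (LSC, IRa, SSC, IRb starting at LSC base 1), so that
assemblies differing only by start point, strand, or SSC orientation —
all biologically equivalent representations of the same molecule —
compare as equal.

The IR search is exact-match: the two copies must be perfect reverse
complements of each other. Candidate blocks are seeded with shared
k-mers between the doubled sequence and its doubled reverse complement,
merged per diagonal, and maximally extended; circularity is handled by
reducing coordinates modulo the sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats_io import SeqRecord, revcomp

DEFAULT_K = 11


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class Interval:
    """Half-open interval on a circle of circumference ``total``.

    ``start`` is in ``[0, total)``; the interval may wrap the origin, in
    which case ``end = start + length > total`` and positions are taken
    modulo ``total``.
    """

    start: int
    length: int
    total: int

    @property
    def end(self) -> int:
        return self.start + self.length

    def positions(self) -> set[int]:
        return {(self.start + t) % self.total for t in range(self.length)}

    def extract(self, seq: str) -> str:
        doubled = seq + seq
        return doubled[self.start : self.start + self.length]


def _circular_disjoint(a_start: int, a_len: int, b_start: int, b_len: int, n: int) -> bool:
    """True if [a_start, a_start+a_len) and [b_start, b_start+b_len) mod n do not overlap."""
    # gap from end of a to start of b, walking forward on the circle
    gap_ab = (b_start - (a_start + a_len)) % n
    gap_ba = (a_start - (b_start + b_len)) % n
    return gap_ab + gap_ba == n - a_len - b_len and a_len + b_len <= n


@dataclass(frozen=True)
class QuadripartiteStructure:
    """The four regions of a plastome on a circular contig."""

    lsc: Interval
    ira: Interval
    ssc: Interval
    irb: Interval
    ir_len: int
    total_len: int

    def region_table(self) -> list[tuple[str, int, int]]:
        """(region, start, end) rows; end may exceed total_len for wrapping intervals."""
        return [
            ("LSC", self.lsc.start, self.lsc.end),
            ("IRa", self.ira.start, self.ira.end),
            ("SSC", self.ssc.start, self.ssc.end),
            ("IRb", self.irb.start, self.irb.end),
        ]


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _max_extend(a: str, b: str, i: int, j: int, length: int) -> tuple[int, int, int]:
    """Maximally extend an exact match a[i:i+length] == b[j:j+length]."""
    while i > 0 and j > 0 and a[i - 1] == b[j - 1]:
        i -= 1
        j -= 1
        length += 1
    while i + length < len(a) and j + length < len(b) and a[i + length] == b[j + length]:
        length += 1
    return i, j, length


def maximal_exact_matches(
    a: str, b: str, k: int, max_kmer_hits: int = 200
) -> list[tuple[int, int, int]]:
    """Maximal exact match blocks (i, j, length >= k) between strings a and b.

    Seeds on shared k-mers, merges seeds per diagonal, then extends each run
    to its maximal block. K-mers occurring more than ``max_kmer_hits`` times
    in ``b`` are skipped as repeats (their context is still recovered through
    extension of neighbouring seeds).
    """
    if k > len(a) or k > len(b):
        raise ValueError(f"k={k} exceeds a sequence length")
    index = _kmer_index(b, k)
    by_diag: dict[int, list[int]] = {}
    for i in range(len(a) - k + 1):
        hits = index.get(a[i : i + k])
        if hits is None or len(hits) > max_kmer_hits:
            continue
        for j in hits:
            by_diag.setdefault(i - j, []).append(i)
    blocks: set[tuple[int, int, int]] = set()
    for diag, positions in by_diag.items():
        positions.sort()
        run_start = positions[0]
        run_end = positions[0] + k
        for i in positions[1:]:
            if i <= run_end:
                run_end = max(run_end, i + k)
            else:
                blocks.add(_max_extend(a, b, run_start, run_start - diag, run_end - run_start))
                run_start, run_end = i, i + k
        blocks.add(_max_extend(a, b, run_start, run_start - diag, run_end - run_start))
    return sorted(blocks)


def find_ir(
    record: SeqRecord, min_ir_len: int, k: int = DEFAULT_K
) -> QuadripartiteStructure | None:
    """Locate the inverted-repeat pair on a circular contig.

    Returns the maximal-length pair of disjoint blocks (i, j, L) such that
    the sequence over block i equals the reverse complement of the sequence
    over block j, or ``None`` when the best L falls below ``min_ir_len``.
    The two single-copy gaps between the copies become LSC (larger) and SSC
    (smaller). Ties between equal-length candidates break on the smallest
    start coordinate.
    """
    if record.topology != "circular":
        raise StructureError(
            f"find_ir requires a circular sequence; {record.id!r} is {record.topology}"
        )
    s = record.seq
    n = len(s)
    if n == 0:
        raise StructureError("empty sequence")
    if n < 2 * min_ir_len or n <= k:
        return None
    s2 = s + s
    r2 = revcomp(s) * 2
    best: tuple[int, int, int] | None = None  # (L, i, j)
    for i2, m2, length in maximal_exact_matches(s2, r2, k):
        # reduce block starts to one circular representative
        if length > n:
            length = n
        i = i2 % n
        # r2[m : m+L] corresponds to the reverse complement of the circular
        # block starting at j = (n - m - L) mod n on the forward strand
        j = (n - (m2 % n) - length) % n
        # shrink L until the two copies are disjoint on the circle
        L = length
        while L >= min_ir_len:
            jj = (n - (m2 % n) - L) % n
            if _circular_disjoint(i, L, jj, L, n):
                j = jj
                break
            L -= 1
        else:
            continue
        a, b = sorted((i, j))
        cand = (L, a, b)
        if best is None or (cand[0], -cand[1], -cand[2]) > (best[0], -best[1], -best[2]):
            best = cand
    if best is None or best[0] < min_ir_len:
        return None
    L, i, j = best
    return _structure_from_pair(s, i, j, L)


def _structure_from_pair(s: str, i: int, j: int, L: int) -> QuadripartiteStructure:
    n = len(s)
    gap_ij = (j - (i + L)) % n  # single-copy gap following copy at i
    gap_ji = (i - (j + L)) % n  # single-copy gap following copy at j
    # the larger gap is the LSC; IRa is the IR copy that follows the LSC
    if gap_ij >= gap_ji:
        lsc = Interval((i + L) % n, gap_ij, n)
        ira = Interval(j, L, n)
        ssc = Interval((j + L) % n, gap_ji, n)
        irb = Interval(i, L, n)
    else:
        lsc = Interval((j + L) % n, gap_ji, n)
        ira = Interval(i, L, n)
        ssc = Interval((i + L) % n, gap_ij, n)
        irb = Interval(j, L, n)
    return QuadripartiteStructure(lsc=lsc, ira=ira, ssc=ssc, irb=irb, ir_len=L, total_len=n)


def canonicalize(record: SeqRecord, structure: QuadripartiteStructure) -> SeqRecord:
    """Rotate/orient a circular plastome into the canonical layout.

    The output always reads LSC, IRa, SSC, IRb from base 1. Among the
    residual symmetries (global reverse complement; SSC orientation) the
    lexicographically smallest sequence is chosen, making the result
    invariant under rotation, strand choice, and SSC flip, and idempotent.
    """
    if structure.total_len != len(record.seq):
        raise StructureError(
            f"structure total_len {structure.total_len} != sequence length {len(record.seq)}"
        )
    s = record.seq
    lsc = structure.lsc.extract(s)
    ira = structure.ira.extract(s)
    ssc = structure.ssc.extract(s)
    irb = structure.irb.extract(s)
    candidates = [
        lsc + ira + ssc + irb,
        lsc + ira + revcomp(ssc) + irb,
        revcomp(lsc) + revcomp(irb) + revcomp(ssc) + revcomp(ira),
        revcomp(lsc) + revcomp(irb) + ssc + revcomp(ira),
    ]
    best = min(candidates)
    return SeqRecord(record.id, best, "circular")
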