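"""Synthetic quadripartite plastomes and controlled assembly defects.

The generator plants an exact inverted-repeat pair in an otherwise random
circular sequence laid out ``LSC . IRa . SSC . IRb``, which makes the planted
structure the unique ground truth for repeat detection and scoring tests.
Single-copy regions are rejection-sampled so that no incidental inverted
repeat of 50 bp or more exists besides the planted pair.

`make_variant` reproduces the structural failure modes commonly seen in real
chloroplast assemblies: rotated start points, reverse-complemented contigs,
flipped SSC orientation, fragmented multi-contig output, tandem duplication
of the whole molecule, and dropped regions (incomplete assemblies).
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

from .formats_io import SeqRecord, revcomp
from .plastome_structure import Interval, QuadripartiteStructure

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: incidental inverted repeats at least this long are rejected during synthesis
INCIDENTAL_IR_LIMIT = 50


@dataclass(frozen=True)
class PlastomeSpec:
    """Region lengths of a synthetic plastome. Total = lsc + ssc + 2*ir."""

    lsc_len: int
    ssc_len: int
    ir_len: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lsc_len > self.ssc_len >= 1):
            raise ValueError("require lsc_len > ssc_len >= 1")
        if self.ir_len < 1:
            raise ValueError("require ir_len >= 1")

    @property
    def total_len(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _has_inverted_repeat(seq: str, limit: int) -> bool:
    """Exact inverted repeat of length >= limit anywhere in seq (incl. palindromes)."""
    k = limit
    if len(seq) < k:
        return False
    seen = set()
    for i in range(len(seq) - k + 1):
        seen.add(seq[i : i + k])
    rc = revcomp(seq)
    return any(rc[i : i + k] in seen for i in range(len(rc) - k + 1))


def make_component(length: int, seed: int) -> SeqRecord:
    """Uniform random A/C/G/T sequence of the given length, linear topology.

    Stands in for nuclear or mitochondrial genome sequence in read mixtures.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return SeqRecord(f"component_{seed}", _random_seq(rng, length), "linear")


def make_plastome(spec: PlastomeSpec) -> tuple[SeqRecord, QuadripartiteStructure]:
    """Generate a circular plastome with an exact planted IR pair.

    Layout is LSC, IRa, SSC, IRb with IRb the exact reverse complement of
    IRa. Deterministic per seed. Single-copy material is re-drawn until it
    contains no incidental inverted repeat of ``INCIDENTAL_IR_LIMIT`` bp, nor
    any such match against the planted IR, so the planted pair is the unique
    maximal inverted repeat.
    """
    rng = np.random.default_rng(spec.seed)
    limit = INCIDENTAL_IR_LIMIT
    for _ in range(100):
        ira = _random_seq(rng, spec.ir_len)
        lsc = _random_seq(rng, spec.lsc_len)
        ssc = _random_seq(rng, spec.ssc_len)
        # check single-copy material on its own and against a single planted
        # IR copy; N spacers (shorter than the probe k-mer, so no all-N
        # k-mer arises) prevent spurious matches across the junctions
        spacer = "N" * (limit - 1)
        if _has_inverted_repeat(lsc + spacer + ssc + spacer + ira, limit):
            continue
        # junction check: the planted IR pair must not extend by even one
        # base (circularly, last LSC base vs first LSC base; first SSC base
        # vs last SSC base), so the maximal IR length is exactly ir_len
        if lsc[-1] == revcomp(lsc[0]) or ssc[0] == revcomp(ssc[-1]):
            continue
        seq = lsc + ira + ssc + revcomp(ira)
        n = spec.total_len
        structure = QuadripartiteStructure(
            lsc=Interval(0, spec.lsc_len, n),
            ira=Interval(spec.lsc_len, spec.ir_len, n),
            ssc=Interval(spec.lsc_len + spec.ir_len, spec.ssc_len, n),
            irb=Interval(spec.lsc_len + spec.ir_len + spec.ssc_len, spec.ir_len, n),
            ir_len=spec.ir_len,
            total_len=n,
        )
        return SeqRecord(f"plastome_{spec.seed}", seq, "circular"), structure
    raise RuntimeError("rejection sampling failed to produce a clean plastome")


def make_variant(
    genome: SeqRecord,
    structure: QuadripartiteStructure | None,
    variant: str,
    **params,
) -> list[SeqRecord]:
    """Derive a controlled "broken" assembly from a plastome.

    variant is one of:

    - ``rotate`` (k): circular sequence restarted at offset k
    - ``revcomp``: global reverse complement
    - ``flip_ssc``: SSC interval reverse-complemented in place (needs structure)
    - ``split`` (n, positions=None): cut into n contigs at given or evenly
      spaced positions
    - ``tandem_duplicate``: two concatenated copies
    - ``drop_region`` (start, end): delete the interval [start, end)

    Coordinates refer to the canonical LSC-first layout of ``genome``.
    """
    s = genome.seq
    n = len(s)
    if variant == "rotate":
        k = params["k"]
        if not 0 <= k < n:
            raise ValueError(f"rotation offset {k} out of range [0, {n})")
        return [SeqRecord(genome.id, s[k:] + s[:k], "circular")]
    if variant == "revcomp":
        return [SeqRecord(genome.id, revcomp(s), "circular")]
    if variant == "flip_ssc":
        if structure is None:
            raise ValueError("flip_ssc requires the quadripartite structure")
        a, b = structure.ssc.start, structure.ssc.end
        if b > n:
            raise ValueError("flip_ssc on a wrapping SSC is not supported; rotate first")
        return [SeqRecord(genome.id, s[:a] + revcomp(s[a:b]) + s[b:], "circular")]
    if variant == "split":
        n_contigs = params["n"]
        if n_contigs < 1:
            raise ValueError("split requires n >= 1")
        cuts = params.get("positions")
        if cuts is None:
            cuts = [round(i * n / n_contigs) for i in range(1, n_contigs)]
        cuts = sorted(cuts)
        if any(not 0 < c < n for c in cuts) or len(cuts) != n_contigs - 1:
            raise ValueError(f"need {n_contigs - 1} cut positions strictly inside (0, {n})")
        bounds = [0, *cuts, n]
        return [
            SeqRecord(f"{genome.id}_part{i + 1}", s[bounds[i] : bounds[i + 1]], "linear")
            for i in range(n_contigs)
        ]
    if variant == "tandem_duplicate":
        return [SeqRecord(genome.id, s + s, "circular")]
    if variant == "drop_region":
        a, b = params["start"], params["end"]
        if not 0 <= a < b <= n:
            raise ValueError(f"drop interval [{a}, {b}) out of bounds")
        if a == 0 and b == n:
            raise ValueError("cannot drop the whole genome")
        return [SeqRecord(genome.id, s[:a] + s[b:], "circular")]
    raise ValueError(f"unknown variant {variant!r}")


def structure_tsv(structure: QuadripartiteStructure) -> str:
    """Region table as TSV text (region, start, end; 0-based half-open)."""
    lines = ["region\tstart\tend"]
    for region, start, end in structure.region_table():
        lines.append(f"{region}\t{start}\t{end}")
    return "\n".join(lines) + "\n"
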