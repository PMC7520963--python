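"""Perfect paired-end read simulation by sliding windows.

Reads are error-free: each fragment of length ``fragment_len`` is an exact
substring of its source component (circularly extended for circular
molecules), the forward read is the fragment's first ``read_len`` bases and
the reverse read is the reverse complement of its last ``read_len`` bases.
Qualities are constant Phred 40.

Fold coverage is controlled by the number of fragments: a component of
length *n* at target coverage *C* receives ``m = round(C*n / (2*read_len))``
fragments whose start positions are evenly spaced over the molecule
(wrapping for circular sequences, confined to valid starts for linear
ones). When *m* exceeds the number of distinct start positions the spacing
drops below one and positions repeat, which is equivalent to running
multiple full sliding-window passes; ``pass_index`` in the pair id
disambiguates the copies. Realized coverage therefore equals the target to
within one fragment's worth of bases.

Mixtures follow the genome:chloroplast weighting convention in which the
nuclear genome is simulated at ``nuclear_cov * g``, the mitochondrion at
``mito_cov * g``, and the plastid at ``nuclear_cov * c`` for a ratio g:c
(so 1:100 means 3,000-fold plastid coverage when nuclear_cov is 30).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .formats_io import SeqRecord, revcomp

PERFECT_QUALITY_CHAR = "I"  # Phred 40

#: coverage mixing ratios studied for organelle-enriched read sets
STANDARD_RATIOS = ((0, 1), (1, 10), (1, 100), (1, 1000))


@dataclass(frozen=True, slots=True)
class ReadPair:
    """A simulated mate pair; pair_id encodes component, fragment start, pass."""

    pair_id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: str
    rev_qual: str

    @property
    def origin(self) -> str:
        """Truth-tagged source component id."""
        return self.pair_id.rsplit(":", 2)[0]

    @property
    def fragment_start(self) -> int:
        return int(self.pair_id.rsplit(":", 2)[1])


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a simulated mixture read set.

    ratio is the genome:chloroplast coverage weighting (g, c); standard
    study values are 0:1, 1:10, 1:100 and 1:1000 with nuclear_cov 30 and
    mito_cov 300 and read lengths 150 or 250 bp.
    """

    read_len: int = 150
    fragment_len: int | None = None  # defaults to 2 * read_len
    nuclear_cov: float = 30.0
    mito_cov: float = 300.0
    ratio: tuple[float, float] = (1, 100)
    subsample_pairs: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.effective_fragment_len < self.read_len:
            raise ValueError("fragment_len must be >= read_len")
        g, c = self.ratio
        if g < 0 or c < 1:
            raise ValueError("ratio requires g >= 0 and c >= 1")
        if self.nuclear_cov < 0 or self.mito_cov < 0:
            raise ValueError("coverages must be >= 0")

    @property
    def effective_fragment_len(self) -> int:
        return self.fragment_len if self.fragment_len is not None else 2 * self.read_len


def _fragment_starts(n: int, fragment_len: int, circular: bool, m: int) -> Iterator[tuple[int, int]]:
    """Yield (start, pass_index) for m evenly spaced fragment starts.

    With m at most the number of valid starts the spacing is span/m >= 1 and
    every start is distinct (one pass); beyond that, full step-1 passes are
    run with the final pass truncated, so exactly m fragments are emitted.
    """
    span = n if circular else n - fragment_len + 1
    if m <= span:
        for i in range(m):
            yield (i * span) // m, 0
    else:
        for i in range(m):
            yield i % span, i // span


def simulate_component(
    seq: SeqRecord, coverage: float, spec: SimulationSpec
) -> Iterator[ReadPair]:
    """Sliding-window perfect read pairs from one component at a target coverage.

    Circular sequences wrap across the origin; linear sequences confine
    fragments to [0, n - fragment_len]. Yields pairs lazily.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    frag = spec.effective_fragment_len
    n = len(seq.seq)
    if n < frag:
        raise ValueError(
            f"component {seq.id!r} (length {n}) shorter than fragment_len {frag}"
        )
    circular = seq.topology == "circular"
    m = round(coverage * n / (2 * spec.read_len))
    source = seq.seq + seq.seq[: frag - 1] if circular else seq.seq
    qual = PERFECT_QUALITY_CHAR * spec.read_len
    rl = spec.read_len
    for pos, pass_idx in _fragment_starts(n, frag, circular, m):
        fragment = source[pos : pos + frag]
        yield ReadPair(
            pair_id=f"{seq.id}:{pos}:{pass_idx}",
            fwd_seq=fragment[:rl],
            rev_seq=revcomp(fragment[-rl:]),
            fwd_qual=qual,
            rev_qual=qual,
        )


def simulate_mixture(
    nuclear: SeqRecord | None,
    mito: SeqRecord | None,
    plastid: SeqRecord,
    spec: SimulationSpec,
) -> list[ReadPair]:
    """Simulate an organelle-enriched mixture at the spec's g:c ratio.

    Components weighted g (nuclear, mitochondrial) are omitted entirely when
    g = 0. The pooled pairs are shuffled deterministically by the spec seed;
    pair ids retain the true origin component.
    """
    g, c = spec.ratio
    pairs: list[ReadPair] = []
    if g > 0:
        if nuclear is not None:
            pairs.extend(simulate_component(nuclear, spec.nuclear_cov * g, spec))
        if mito is not None:
            pairs.extend(simulate_component(mito, spec.mito_cov * g, spec))
    pairs.extend(simulate_component(plastid, spec.nuclear_cov * c, spec))
    if not pairs:
        raise ValueError("mixture produced no read pairs (all coverages zero?)")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def subsample(pairs: Iterable[ReadPair], n: int, seed: int) -> list[ReadPair]:
    """Draw exactly n pairs uniformly without replacement, shuffled.

    Accepts a list or a lazy iterator; iterators are reservoir-sampled so
    multi-million-pair streams never need to be materialized in full.
    Deterministic per seed (list and iterator inputs use different but
    individually reproducible draw sequences).
    """
    rng = np.random.default_rng(seed)
    if isinstance(pairs, Sequence):
        total = len(pairs)
        if n > total:
            raise ValueError(f"requested {n} pairs but only {total} are available")
        idx = rng.choice(total, size=n, replace=False)
        return [pairs[i] for i in idx]
    # reservoir sampling (Algorithm R) for streams
    reservoir: list[ReadPair] = []
    total = 0
    for pair in pairs:
        if total < n:
            reservoir.append(pair)
        else:
            j = int(rng.integers(0, total + 1))
            if j < n:
                reservoir[j] = pair
        total += 1
    if n > total:
        raise ValueError(f"requested {n} pairs but only {total} are available")
    order = rng.permutation(n)
    return [reservoir[i] for i in order]


def coverage_by_origin(
    pairs: Iterable[ReadPair], lengths: dict[str, int], read_len: int
) -> dict[str, float]:
    """Realized fold coverage per origin component: read bases / length."""
    bases: dict[str, int] = {}
    for pair in pairs:
        bases[pair.origin] = bases.get(pair.origin, 0) + 2 * read_len
    return {comp: bases.get(comp, 0) / length for comp, length in lengths.items()}
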