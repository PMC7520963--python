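# Methods

This note documents the models and procedures implemented in plastaudit,
the parameter choices that matter, and what the synthetic test bed does and
does not establish about real data.

## The composite assembly score

An assembly (one or more contigs) is compared against a single reference
sequence by pairwise alignment in both directions, yielding two coverage
fractions:

- `cov_ref` — fraction of reference bases covered by the union of primary
  alignment blocks when the assembly is mapped onto the reference
  (completeness);
- `cov_qry` — fraction of assembly bases covered when the reference is
  mapped onto the assembly, pooled over contigs (correctness).

The score combines these with a repeat-resolution term and a continuity
term, each contributing a quarter:

```
score = 25 · (cov_ref + cov_qry + min{cov_qry/cov_ref, cov_ref/cov_qry} + 1/n_contigs)
```

The min-ratio term penalizes a size mismatch between assembly and
reference in either direction (e.g. an unresolved extra copy of the IR, or
a whole surplus genome copy). When either coverage is zero the ratio is
undefined; it is then taken to be 0 so that a failed mapping still yields
a finite low score and batch medians remain computable. Scores are
reported at two decimals; full precision is kept internally.

Degenerate cases worth knowing: an assembly identical to its reference
scores exactly 100; a tandem duplicate scores 75 (cov_qry = repeat term =
0.5); an assembly split into *n* exact fragments scores 25·(2 + 1 + 1/n).

### Primary-only counting

Coverage uses primary alignments exclusively: each base of the *mapped*
sequence is assigned to at most one alignment block. This is what makes
surplus sequence visible — with secondary alignments counted, a reference
would cover both copies in a duplicated assembly and every fraction would
saturate at 1. When alignments are supplied as PAF, records tagged
`tp:A:S` are excluded (`tp:A:P` / `tp:A:I` and untagged records count as
primary).

### The built-in exact anchor aligner

For synthetic evaluations the package aligns internally: maximal exact
match blocks between query and target are seeded on shared k-mers
(default k = 15), merged per diagonal, maximally extended, and then
greedily assigned under the primary-only constraint. The greedy selection
picks, at each step, the candidate block contributing the most *new target
coverage* (block length breaking ties, then fixed coordinate order). This
matters for plastomes specifically: an assembly's IR copy matches both
reference IR copies equally well, and a placement chosen by length alone
can orphan one reference IR copy and spuriously lose completeness on
rotated or SSC-flipped assemblies. Preferring new target coverage mimics
the placement a colinear chaining aligner converges to, and is what makes
rotation, strand choice and SSC flips score-neutral.

The exact aligner is complete for assemblies that are exact substrings,
rearrangements, rotations, or reverse complements of the reference — i.e.
for everything the synthetic generator produces. It does not model
mismatches or gaps; real, diverged assemblies should be aligned externally
(any PAF producer works) and passed in per direction.

References are treated as linear during coverage: an assembly starting at
a different origin of the circle aligns as two blocks whose union still
covers everything, so rotation costs nothing without any explicit
circular handling.

## Inverted-repeat detection and canonical orientation

The IR search finds the maximal-length pair of disjoint blocks (i, j, L)
on a circular contig such that the sequence over block i equals the
reverse complement of the sequence over block j. Candidates are seeded by
shared k-mers (default k = 11) between the doubled sequence and its
doubled reverse complement — doubling makes the search independent of
where the origin cuts the circle — chained per diagonal, maximally
extended, reduced modulo the sequence length, and shrunk minimally where
needed to enforce disjointness of the two copies. Candidates longer than
the sequence itself are clipped. The search is exact (mismatch-free); IR
identity in real plastomes is near-perfect, and exactness is what lets
the planted-structure tests assert equality rather than tolerance. Ties
between equal-length candidates break on the smallest start coordinate.

The two single-copy gaps between the IR copies become the LSC (larger)
and SSC (smaller). `canonicalize` rotates the molecule to the layout LSC,
IRa, SSC, IRb starting at LSC base 1. Because the strand choice and the
SSC orientation remain free even after fixing that layout, the
lexicographically smallest of the four residual candidates (± global
reverse complement × ± SSC flip) is emitted. Lexicographic choice is a
deterministic stand-in for a field convention that has no crisp published
definition; it guarantees that all members of a molecule's symmetry orbit
(rotations × strand × SSC orientation) canonicalize to the same string,
and that the map is idempotent.

## Success classification

Two rules are implemented, both with inclusive bounds:

- **reference mode**: success iff score ≥ 99;
- **novel mode** (no reference): success iff the assembly is a single
  contig, its total length is ≥ 130,000 bp, and an IR of ≥ 17,000 bp is
  present (the largest contig is probed as a circular molecule).

`select_cutoffs` re-derives novel-mode thresholds from a labeled set by
exhaustive grid search maximizing F1, with per-assembly features
(contig count, total length, longest IR) computed once so grid points are
pure threshold comparisons. Default grids are 100–160 kbp in 1 kbp steps
and 10–30 kbp in 0.5 kbp steps, bracketing typical plastome and IR sizes;
ties break toward the smallest length cutoff, then the smallest IR
cutoff. Precision and recall are defined as 0 when their denominators are
0.

## Synthetic plastomes

`make_plastome` lays out LSC · IRa · SSC · IRb with IRb the exact reverse
complement of IRa and all other material uniform random A/C/G/T. Two
rejection rules make the planted structure the *unique, exact* answer:

1. no incidental inverted repeat of ≥ 50 bp may occur within or between
   the single-copy regions and a planted IR copy (checked with a 50-mer
   table; for random sequence this essentially never triggers, but the
   guarantee is what the equality assertions in tests rest on);
2. the bases flanking the IR junctions must not extend the planted pair by
   even one base (each side has probability 1/4 per draw), so the maximal
   IR length equals `ir_len` exactly.

The default fixture (LSC 80 kb, SSC 15 kb, IR 20 kb; 135 kb total) sits
above both novel-mode cutoffs so boundary tests can perturb downward.
The generator makes no attempt at biological realism beyond structure: no
gene content, no codon structure, no GC skew, no heteroplasmy.

## Read simulation

Reads are perfect: every fragment is an exact substring of its source
(circularly extended for circular molecules), the forward read is the
fragment's first `read_len` bases, the reverse read the reverse
complement of its last `read_len` bases, and qualities are a constant
Phred 40. Defaults: `read_len` 150 (250 also standard), `fragment_len`
2·`read_len` (adjacent, non-overlapping mates).

Coverage is met by fragment count rather than by an integer step: a
component of length n at coverage C receives m = round(C·n / (2·read_len))
fragments at evenly spaced start positions. On circular molecules with
divisible parameters this reduces to a classic integer-step sliding
window (10 kb at 30× with 300 bp fragments → step 10); on linear
molecules the spacing compresses slightly so edge exclusion does not
erode coverage; above saturating coverage the positions wrap into full
step-1 passes plus a truncated final pass, with a pass index in the read
name disambiguating repeats. Realized coverage therefore always lands
within one fragment's worth of bases of the target, on every topology.

Mixtures interpret the genome:chloroplast ratio g:c as a coverage
weighting with the nuclear genome fixed at 30×: nuclear gets
`nuclear_cov·g`, mitochondrial `mito_cov·g` (default 300×), plastid
`nuclear_cov·c` — so 1:100 means 3,000× plastid, and 0:1 omits nuclear
and mitochondrial reads entirely. An alternative reading of g:c as a
read-count ratio exists; the coverage reading is the package's default
and the only one implemented, since the stated fixed 30×/300× coverages
imply it. Read names encode (component, fragment start, pass), so
per-origin coverage accounting and mapping-free truth evaluation need no
alignment step. Pairs are pooled and shuffled deterministically by seed.

Subsampling draws exactly n pairs uniformly without replacement
(index sampling for in-memory lists, single-pass reservoir sampling for
lazy streams, so multi-million-pair draws never materialize the full
stream) and shuffles the result; both paths are deterministic per seed.

No sequencing-error model, quality distribution, insert-size
distribution, or long-read mode is provided.

## What the synthetic test bed shows — and what it does not

All structural claims (score neutrality of rotation/strand/SSC-flip, the
75-point tandem duplicate, exact IR recovery, canonical-orientation
invariance) are established on exact synthetic sequence. Real data adds
sequence divergence, ambiguity codes, sequencing error, and IRs with
small internal differences; there the built-in exact aligner understates
coverage and an external aligner's PAF should be used, and IR detection
reports the longest *exact* copy, a conservative length under the 17 kbp
rule. Passing the synthetic suite demonstrates correctness of the scoring
arithmetic, interval logic, structure detection and symmetry handling —
not robustness to divergence.

## Numerical and procedural choices

- Coordinates are uniformly 0-based half-open; circular intervals may wrap
  and are reduced modulo length.
- Sequence alphabet is {A, C, G, T, N}; lowercase and U are normalized,
  other IUPAC codes degrade to N with a warning. N never matches anything
  in the exact aligner (k-mers containing N simply find no partner).
- FASTQ mate pairing is positional: record i of forward.fq mates record i
  of reverse.fq, regardless of name suffixes.
- Anchor k defaults: 15 for assembly/reference alignment (spurious exact
  15-mers between 135 kb random sequences are rare and at worst add
  ~15 bp of stray coverage), 11 for IR detection (matching the brute-force
  oracle's resolution in tests).
- Run-to-run score comparisons treat differences ≤ 0.01 (one reporting
  unit, inclusive up to floating-point epsilon) as identical.
- Problem sizes in the test suite are chosen at 1/10 scale (13.5 kb
  plastomes) where full scale adds nothing, and at full 135 kb scale for
  the end-to-end score, structure, and simulator checks.
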