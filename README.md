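# plastaudit

An evaluation toolkit for chloroplast (plastid) genome assemblies, for
anyone who runs organelle assemblers and needs to decide — reproducibly,
and at scale — whether what came out is a finished plastome.

Chloroplast genomes are circular molecules of roughly 120–160 kbp with a
quadripartite layout: a large and a small single-copy region (LSC, SSC)
separated by two identical, oppositely oriented inverted repeats (IRa,
IRb). Assemblies of the same molecule can legitimately differ by start
point, strand, and SSC orientation, and they fail in characteristic ways:
fragmentation, surplus genome copies, or missing regions. plastaudit
provides the pieces needed to evaluate all of this without manual
inspection:

- **Composite score (0–100).** An assembly is compared to a reference by
  pairwise alignment in both directions and scored as

  ```
  score = 1/4 · (cov_ref + cov_qry + min{cov_qry/cov_ref, cov_ref/cov_qry} + 1/n_contigs) · 100
  ```

  where *cov_ref* is the fraction of the reference covered by the assembly
  (completeness), *cov_qry* the fraction of the assembly covered by the
  reference (correctness), the min-ratio term measures repeat resolution /
  size agreement, and 1/*n*_contigs rewards continuity. A perfect
  single-contig assembly scores exactly 100; rotations, the reverse
  complement, and an SSC flip — biologically valid representations — also
  score 100, while a tandem-duplicated assembly scores 75.
- **Success classification.** With a reference: success = score ≥ 99.
  Without one ("novel mode"): success = a single contig of ≥ 130 kbp
  carrying an inverted repeat of ≥ 17 kbp. The novel-mode cutoffs can be
  re-calibrated by F1-maximizing grid search against a labeled collection.
- **Structure detection and canonical orientation.** Exact inverted-repeat
  detection on circular contigs, LSC/IRa/SSC/IRb partitioning, and a
  deterministic canonical rotation (LSC first, lexicographically smallest
  among the residual symmetries).
- **Synthetic data.** A generator for quadripartite plastomes with planted
  IRs plus controlled defect variants (rotate, revcomp, SSC flip, split,
  tandem duplicate, dropped region), and a perfect paired-end read
  simulator producing `forward.fq` / `reverse.fq` mixtures at chosen
  genome:chloroplast ratios (0:1, 1:10, 1:100, 1:1000) with truth-tagged
  read names, optionally subsampled to an exact pair count.

Alignments come either from the built-in exact-match anchor aligner
(complete for rearranged/rotated/reverse-complemented exact sequence) or
from external PAF files (e.g. minimap2) for real, diverged data.

## Worked example

Generate a synthetic 135 kbp plastome (80 kb LSC, 20 kb IRs, 15 kb SSC),
score it against itself, detect its structure, and classify it:

```console
$ plastaudit synth --lsc 80000 --ssc 15000 --ir 20000 --seed 7 --out-dir demo
$ plastaudit score demo/plastome.fa demo/plastome.fa
cov_ref	cov_qry	repeat_term	n_contigs	score
1.00	1.00	1.00	1	100.00
$ plastaudit structure demo/plastome.fa --min-ir 17000
region	start	end
LSC	0	80000
IRa	80000	100000
SSC	100000	115000
IRb	115000	135000
$ plastaudit classify --mode novel demo/plastome.fa
mode	success	reasons
novel	true	
```

The score row reads: the assembly covers the whole reference
(`cov_ref = 1.00`), the reference covers the whole assembly
(`cov_qry = 1.00`), their sizes agree (`repeat_term = 1.00`), and it is a
single contig — a perfect 100.00. The structure table gives the 0-based
half-open coordinates of the four regions, and the novel-mode call
succeeds because the single contig exceeds 130 kbp with a 20 kbp IR.

Simulating an organelle-enriched read set at a 1:10 genome:chloroplast
ratio (nuclear 30×, mitochondrial 300×, plastid 300×):

```console
$ plastaudit simulate --plastid demo/plastome.fa --nuclear-len 200000 \
      --mito-len 50000 --ratio 1:10 --seed 7 --out-dir demo/reads
demo/reads/forward.fq	demo/reads/reverse.fq	205000 pairs
```

The emitted manifest (`demo/reads/simulate.manifest.json`) records the
realized coverages — here exactly 30.0× nuclear, 300.0× mitochondrial and
300.0× plastid — which can be verified independently from the truth-tagged
read names.

## Layout

| module | contents |
| --- | --- |
| `plastaudit.formats_io` | FASTA / paired FASTQ / PAF reading and writing, validation |
| `plastaudit.genome_synth` | synthetic plastomes and defect variants |
| `plastaudit.read_simulator` | perfect paired-end reads, mixtures, subsampling |
| `plastaudit.alignment_coverage` | exact anchor aligner, interval-union coverage |
| `plastaudit.assembly_score` | composite score, run-to-run consistency |
| `plastaudit.plastome_structure` | IR detection, quadripartite partition, canonical rotation |
| `plastaudit.success_classify` | success rules, precision/recall/F1, cutoff calibration |
| `plastaudit.cli` | the `plastaudit` command |

See `docs/methods.md` for the underlying model, parameter choices, and
limitations.
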