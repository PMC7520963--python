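"""Readers and writers for the formats the toolkit touches: FASTA, paired
FASTQ, and PAF.

All coordinates are 0-based half-open throughout the package (the native PAF
convention). Sequences are normalized on ingest to the 5-letter alphabet
``{A, C, G, T, N}``: lowercase is upper-cased, ``U`` becomes ``T``, and other
IUPAC ambiguity codes collapse to ``N`` with a warning. Paired FASTQ files
follow the fixed two-file contract (``forward.fq`` / ``reverse.fq``) with
positional mate pairing: record *i* of the forward file mates record *i* of
the reverse file, regardless of ``/1`` / ``/2`` name suffixes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC ambiguity codes other than N that we degrade to N on ingest
_AMBIGUOUS = set("RYSWKMBDHV")


class FormatError(ValueError):
    """Malformed or inconsistent input data."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence with linear or circular topology."""

    id: str
    seq: str
    topology: str = "linear"  # "linear" | "circular"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id: {self.id!r}")
        if len(self.seq) < 1:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        if self.topology not in ("linear", "circular"):
            raise FormatError(f"unknown topology {self.topology!r}")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains illegal characters: "
                + ", ".join(sorted(map(repr, bad)))
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, id: str | None = None) -> "SeqRecord":
        return SeqRecord(id or self.id, revcomp(self.seq), self.topology)


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise alignment block with PAF semantics.

    Intervals are 0-based half-open on both sides; ``n_matches`` counts
    matching bases within ``block_len`` aligned columns.
    """

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str  # "+" | "-"
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    n_matches: int
    block_len: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        for side in ("query", "target"):
            start = getattr(self, f"{side}_start")
            end = getattr(self, f"{side}_end")
            length = getattr(self, f"{side}_len")
            if not (0 <= start < end <= length):
                raise FormatError(
                    f"{side} interval [{start}, {end}) out of bounds "
                    f"for length {length}"
                )
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")
        if self.n_matches > self.block_len:
            raise FormatError("n_matches exceeds block_len")


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Upper-case, map U->T, degrade non-N ambiguity codes to N.

    Raises :class:`FormatError` on characters outside the IUPAC nucleotide
    alphabet (naming the offending character).
    """
    seq = raw.upper().replace("U", "T")
    present = set(seq)
    amb = present & _AMBIGUOUS
    if amb:
        warnings.warn(
            f"record {record_id!r}: ambiguity codes {sorted(amb)} mapped to N",
            stacklevel=2,
        )
        seq = seq.translate(str.maketrans({c: "N" for c in amb}))
    bad = set(seq) - ALPHABET
    if bad:
        raise FormatError(
            f"record {record_id!r} contains illegal character(s): "
            + ", ".join(sorted(map(repr, bad)))
        )
    return seq


def read_fasta(path: str | Path, topology: str = "linear") -> list[SeqRecord]:
    """Read a FASTA file into validated, case-normalized records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), rec.id)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        records.append(SeqRecord(rec.id, seq, topology))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Sequence[SeqRecord], path: str | Path, line_width: int = 60
) -> Path:
    """Write records as wrapped FASTA; round-trips ids and sequences."""
    if not records:
        raise FormatError("refusing to write an empty FASTA file")
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i : i + line_width] + "\n")
    return path


def _fastq_records(pairs: Iterable, which: str) -> Iterable[_BioSeqRecord]:
    for pair in pairs:
        seq = pair.fwd_seq if which == "fwd" else pair.rev_seq
        qual = pair.fwd_qual if which == "fwd" else pair.rev_qual
        if len(qual) != len(seq):
            raise FormatError(
                f"pair {pair.pair_id!r}: quality length {len(qual)} "
                f"!= sequence length {len(seq)}"
            )
        rec = _BioSeqRecord(Seq(seq), id=pair.pair_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        yield rec


def write_paired_fastq(
    pairs: Sequence, fwd_path: str | Path, rev_path: str | Path
) -> tuple[Path, Path]:
    """Write mate pairs to forward/reverse FASTQ files (Phred+33)."""
    fwd_path, rev_path = Path(fwd_path), Path(rev_path)
    SeqIO.write(_fastq_records(pairs, "fwd"), str(fwd_path), "fastq")
    SeqIO.write(_fastq_records(pairs, "rev"), str(rev_path), "fastq")
    return fwd_path, rev_path


def read_paired_fastq(fwd_path: str | Path, rev_path: str | Path) -> list:
    """Read positionally-paired FASTQ files back into ReadPair objects."""
    from .read_simulator import ReadPair  # local import avoids a cycle

    def _load(p: Path) -> list[_BioSeqRecord]:
        return list(SeqIO.parse(str(p), "fastq"))

    fwd = _load(Path(fwd_path))
    rev = _load(Path(rev_path))
    if len(fwd) != len(rev):
        raise FormatError(
            f"mate-count mismatch: {len(fwd)} forward vs {len(rev)} reverse records"
        )
    pairs = []
    for f, r in zip(fwd, rev):
        pairs.append(
            ReadPair(
                pair_id=f.id,
                fwd_seq=str(f.seq).upper(),
                rev_seq=str(r.seq).upper(),
                fwd_qual="".join(
                    chr(q + 33) for q in f.letter_annotations["phred_quality"]
                ),
                rev_qual="".join(
                    chr(q + 33) for q in r.letter_annotations["phred_quality"]
                ),
            )
        )
    return pairs


def parse_paf(path: str | Path) -> list[AlignmentRecord]:
    """Parse a PAF file (12 mandatory columns plus optional SAM-style tags).

    ``tp:A:P`` and ``tp:A:I`` mark primary alignments, ``tp:A:S`` secondary;
    records without a ``tp`` tag default to primary.
    """
    path = Path(path)
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 12 PAF columns, got {len(fields)}"
                )
            try:
                (qid, qlen, qs, qe, strand, tid, tlen, ts, te, nm, bl) = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    int(fields[3]),
                    fields[4],
                    fields[5],
                    int(fields[6]),
                    int(fields[7]),
                    int(fields[8]),
                    int(fields[9]),
                    int(fields[10]),
                )
                int(fields[11])  # mapping quality; parsed for validation only
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            is_primary = True
            for tag in fields[12:]:
                if tag.startswith("tp:A:"):
                    is_primary = tag[5] in ("P", "I")
            try:
                records.append(
                    AlignmentRecord(
                        qid, qlen, qs, qe, strand, tid, tlen, ts, te, nm, bl,
                        is_primary,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_paf(records: Sequence[AlignmentRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in records:
            tag = "tp:A:P" if r.is_primary else "tp:A:S"
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            r.query_id, r.query_len, r.query_start, r.query_end,
                            r.strand, r.target_id, r.target_len, r.target_start,
                            r.target_end, r.n_matches, r.block_len, 60, tag,
                        ],
                    )
                )
                + "\n"
            )
    return path
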