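"""File formats, an exact-match short-read mapper, and read-level filters.

Conventions used throughout the package:

* genomic coordinates are 0-based half-open everywhere in memory; BED output
  is native, GFF3 is converted to 1-based closed at write time;
* sequences are DNA (``T``) on disk and in genome space, and RNA (``U``) in
  the folding/duplex logic — conversion happens at the module boundary;
* a "collapsed" read is a distinct sequence with an abundance count.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: (chrom, start, end, strand) with 0-based half-open interval.
Locus = tuple[str, int, int, str]

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


class ParseError(ValueError):
    """An input file does not conform to its format."""


class ValidationError(ValueError):
    """A parsed record violates a structural invariant."""


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class AlignedRead:
    """A collapsed sRNA sequence with its abundance and genomic loci.

    ``seq`` is stored in DNA alphabet.  ``loci`` holds every retained
    exact-match placement; ``n_loci`` is always ``len(loci)``.
    """

    seq: str
    abundance: int
    loci: list[Locus] = field(default_factory=list)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def validate(self) -> None:
        if self.abundance < 1:
            raise ValidationError(f"abundance must be >= 1, got {self.abundance}")
        for chrom, start, end, strand in self.loci:
            if end - start != len(self.seq):
                raise ValidationError(
                    f"locus {chrom}:{start}-{end} length {end - start} != "
                    f"read length {len(self.seq)}"
                )
            if strand not in ("+", "-"):
                raise ValidationError(f"bad strand {strand!r}")


@dataclass
class ExclusionAnnotation:
    """Genomic intervals to purge (organellar genomes, structural ncRNAs)."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValidationError(f"empty interval {chrom}:{start}-{end}")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` (uppercased)."""
    try:
        return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    except ValueError as exc:  # pragma: no cover - biopython formats message
        raise ParseError(f"{path}: {exc}") from exc


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTQ into ``[(id, sequence, quality), ...]``.

    A hand-stepped 4-line reader so malformed records can be reported with
    their exact line number.
    """
    records: list[tuple[str, str, str]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ParseError(f"{path}: truncated FASTQ record at line {len(lines) + 1}")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise ParseError(f"{path}: line {i + 1}: header must start with '@'")
        if not plus.startswith("+"):
            raise ParseError(f"{path}: line {i + 3}: separator must start with '+'")
        if len(qual) != len(seq):
            raise ParseError(
                f"{path}: line {i + 4}: quality length {len(qual)} != "
                f"sequence length {len(seq)}"
            )
        records.append((head[1:].split()[0], seq.upper(), qual))
    return records


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Alignment tables
# ---------------------------------------------------------------------------

ALIGNMENT_COLUMNS = ("read_seq", "chrom", "start", "end", "strand", "abundance", "n_loci")


def write_alignment_table(reads: Iterable[AlignedRead], path: str | Path) -> None:
    """Write one TSV row per (read, locus); coordinates 0-based half-open."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ALIGNMENT_COLUMNS)
        for read in reads:
            for chrom, start, end, strand in read.loci:
                w.writerow([read.seq, chrom, start, end, strand, read.abundance, read.n_loci])


def read_alignment_table(path: str | Path) -> list[AlignedRead]:
    """Read an alignment TSV back into validated :class:`AlignedRead`s."""
    rows: dict[str, AlignedRead] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != ALIGNMENT_COLUMNS:
            raise ParseError(f"{path}: line 1: expected header {ALIGNMENT_COLUMNS}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(ALIGNMENT_COLUMNS):
                raise ParseError(f"{path}: line {lineno}: expected {len(ALIGNMENT_COLUMNS)} fields")
            seq, chrom, start, end, strand, abundance, n_loci = row
            start, end, abundance, n_loci = int(start), int(end), int(abundance), int(n_loci)
            if end - start != len(seq):
                raise ValidationError(
                    f"{path}: line {lineno}: end-start={end - start} != len(seq)={len(seq)}"
                )
            read = rows.setdefault(seq, AlignedRead(seq=seq.upper(), abundance=abundance))
            if read.abundance != abundance:
                raise ValidationError(f"{path}: line {lineno}: inconsistent abundance for {seq}")
            read.loci.append((chrom, start, end, strand))
    out = []
    for seq, read in rows.items():
        read.loci.sort()
        read.validate()
        out.append(read)
    out.sort(key=lambda r: r.seq)
    return out


# ---------------------------------------------------------------------------
# BED / GFF3 / TSV
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write BED6 rows.  Each interval is (chrom, start, end[, name[, score[, strand]]])."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for iv in intervals:
            chrom, start, end = iv[:3]
            name = iv[3] if len(iv) > 3 else "."
            score = iv[4] if len(iv) > 4 else 0
            strand = iv[5] if len(iv) > 5 else "."
            w.writerow([chrom, start, end, name, score, strand])


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, str, str]]:
    out = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith(("#", "track")):
                continue
            if len(row) < 3:
                raise ParseError(f"{path}: line {lineno}: BED needs >=3 fields")
            chrom, start, end = row[0], int(row[1]), int(row[2])
            name = row[3] if len(row) > 3 else "."
            score = row[4] if len(row) > 4 else "0"
            strand = row[5] if len(row) > 5 else "."
            out.append((chrom, start, end, name, score, strand))
    return out


def write_gff3(features: Iterable[tuple], path: str | Path, source: str = "chlamirna") -> None:
    """Write GFF3; features are (chrom, start, end, feature_id, strand[, type[, attrs]]).

    Internal 0-based half-open coordinates are converted to GFF3's 1-based
    closed convention here and nowhere else.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            chrom, start, end, fid, strand = feat[:5]
            ftype = feat[5] if len(feat) > 5 else "miRNA"
            attrs = feat[6] if len(feat) > 6 else {}
            attr_str = ";".join([f"ID={fid}"] + [f"{k}={v}" for k, v in attrs.items()])
            fh.write(
                f"{chrom}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_str}\n"
            )


def write_tsv(table, path: str | Path) -> None:
    """Write a pandas DataFrame, or an iterable of rows, as TSV."""
    if hasattr(table, "to_csv"):
        table.to_csv(path, sep="\t", index=False)
        return
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for row in table:
            w.writerow(row)


# ---------------------------------------------------------------------------
# Exact-match mapping and filtering
# ---------------------------------------------------------------------------

def map_exact(
    reads: Mapping[str, int] | Iterable[tuple[str, int]],
    genome: Mapping[str, str],
    max_loci: int = 5,
) -> list[AlignedRead]:
    """Place collapsed reads at every exact-match locus on either strand.

    Reads mapping nowhere, or to more than ``max_loci`` locations, are
    dropped (the multi-mapper removal rule; the boundary is inclusive, a
    read at exactly ``max_loci`` loci is retained).
    """
    if not genome:
        raise ValueError("genome is empty")
    if not isinstance(reads, Mapping):
        collapsed: dict[str, int] = {}
        for seq, abundance in reads:
            key = to_dna(seq)
            collapsed[key] = collapsed.get(key, 0) + abundance
    else:
        collapsed = {}
        for seq, abundance in reads.items():
            key = to_dna(seq)
            collapsed[key] = collapsed.get(key, 0) + abundance

    lengths = sorted({len(s) for s in collapsed})
    index: dict[int, dict[str, list[tuple[str, int]]]] = {L: {} for L in lengths}
    for chrom in sorted(genome):
        cseq = genome[chrom].upper()
        for L in lengths:
            idx = index[L]
            for i in range(len(cseq) - L + 1):
                idx.setdefault(cseq[i : i + L], []).append((chrom, i))

    out: list[AlignedRead] = []
    for seq in sorted(collapsed):
        L = len(seq)
        loci: set[Locus] = set()
        for chrom, i in index[L].get(seq, ()):  # plus strand
            loci.add((chrom, i, i + L, "+"))
        for chrom, i in index[L].get(revcomp_dna(seq), ()):  # minus strand
            loci.add((chrom, i, i + L, "-"))
        if 0 < len(loci) <= max_loci:
            out.append(AlignedRead(seq=seq, abundance=collapsed[seq], loci=sorted(loci)))
    return out


def filter_excluded(
    reads: Iterable[AlignedRead], excl: ExclusionAnnotation
) -> list[AlignedRead]:
    """Remove reads with any locus overlapping an exclusion interval (>=1 bp).

    Idempotent: a read is either removed entirely or untouched.
    """
    excl.validate()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in excl.intervals:
        by_chrom.setdefault(chrom, []).append((start, end))

    def hit(read: AlignedRead) -> bool:
        for chrom, start, end, _strand in read.loci:
            for es, ee in by_chrom.get(chrom, ()):
                if start < ee and es < end:
                    return True
        return False

    return [r for r in reads if not hit(r)]


def read_sam_alignments(path: str | Path) -> list[AlignedRead]:
    """Map SAM records onto the alignment-table schema.

    Collapses by original read sequence (reverse-complementing
    minus-strand records back to read orientation); ``n_loci`` is the
    number of distinct mapped loci per sequence (the NH tag, when present,
    is checked for consistency but the loci themselves are authoritative).
    """
    import pysam

    by_seq: dict[str, set[Locus]] = {}
    abundance: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            seq = aln.query_sequence.upper()
            if aln.is_reverse:
                seq = revcomp_dna(seq)
            strand = "-" if aln.is_reverse else "+"
            locus = (aln.reference_name, aln.reference_start, aln.reference_end, strand)
            first = seq not in by_seq
            by_seq.setdefault(seq, set()).add(locus)
            if first:
                abundance[seq] = _abundance_from_name(aln.query_name)
    out = []
    for seq in sorted(by_seq):
        read = AlignedRead(seq=seq, abundance=abundance[seq], loci=sorted(by_seq[seq]))
        read.validate()
        out.append(read)
    return out


def _abundance_from_name(name: str) -> int:
    """Recover an abundance from collapsed-read ids like ``read12_x53``."""
    if "_x" in name:
        tail = name.rsplit("_x", 1)[1]
        if tail.isdigit():
            return int(tail)
    return 1
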