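"""Genomic clustering of mapped sRNA reads and cluster sequence extraction.

Reads are grouped by genomic proximity regardless of strand: walking loci
in coordinate order, a new cluster opens whenever the end-to-start gap to
the previous locus exceeds ``max_gap`` (200 nt by default).  Each cluster
is later folded on both strands to look for a hairpin precursor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .seqio import AlignedRead, revcomp_dna


@dataclass
class ReadCluster:
    """A strand-agnostic genomic grouping of read loci.

    ``members`` holds ``(read, locus_index)`` pairs so a multi-mapping read
    contributes at each of its clusters.  Sequence fields are populated by
    :func:`extract_cluster_sequences`; ``extract_interval`` records the
    genomic interval (including flank) the sequences were taken from, which
    is needed to map read loci into folded-sequence offsets.
    """

    id: str
    chrom: str
    span: tuple[int, int]
    members: list[tuple[AlignedRead, int]] = field(default_factory=list)
    genomic_seq_plus: str | None = None
    genomic_seq_minus: str | None = None
    has_ambiguous_bases: bool = False
    extract_interval: tuple[int, int] | None = None

    @property
    def total_abundance(self) -> int:
        """Abundance of locally mapped reads.

        A read appearing at several loci within the same cluster (e.g. a
        mature read that also matches the star arm exactly) represents one
        molecule population and is counted once.
        """
        distinct = {read.seq: read.abundance for read, _ in self.members}
        return sum(distinct.values())


def cluster_reads(reads: Iterable[AlignedRead], max_gap: int = 200) -> list[ReadCluster]:
    """Partition read loci into clusters; strand is ignored for membership.

    Every locus of every read lands in exactly one cluster; the result is
    invariant under permutation of the input because loci are coordinate
    sorted first.
    """
    entries: list[tuple[str, int, int, AlignedRead, int]] = []
    for read in reads:
        if not read.loci:
            raise ValueError(f"read {read.seq} has no loci")
        for locus_index, (chrom, start, end, _strand) in enumerate(read.loci):
            entries.append((chrom, start, end, read, locus_index))
    entries.sort(key=lambda e: (e[0], e[1], e[2], e[3].seq))

    clusters: list[ReadCluster] = []
    current: ReadCluster | None = None
    for chrom, start, end, read, locus_index in entries:
        if (
            current is None
            or chrom != current.chrom
            or start - current.span[1] > max_gap
        ):
            current = ReadCluster(
                id=f"cluster_{len(clusters) + 1:04d}",
                chrom=chrom,
                span=(start, end),
            )
            clusters.append(current)
        current.members.append((read, locus_index))
        current.span = (current.span[0], max(current.span[1], end))
    return clusters


def extract_cluster_sequences(
    cluster: ReadCluster, genome: Mapping[str, str], flank: int = 20
) -> ReadCluster:
    """Attach the (flanked) genomic sequence of both strands to a cluster.

    The minus-strand sequence is the reverse complement of the plus-strand
    sequence.  Any non-ACGT base in the extracted region (an unsequenced
    gap) sets ``has_ambiguous_bases``, which disqualifies the cluster from
    structure-based calling.  The flank is truncated at chromosome edges.
    """
    if cluster.chrom not in genome:
        raise KeyError(f"chromosome {cluster.chrom!r} absent from genome")
    chrom_seq = genome[cluster.chrom].upper()
    start = max(0, cluster.span[0] - flank)
    end = min(len(chrom_seq), cluster.span[1] + flank)
    plus = chrom_seq[start:end]
    cluster.genomic_seq_plus = plus
    cluster.genomic_seq_minus = revcomp_dna(plus)
    cluster.has_ambiguous_bases = any(base not in "ACGT" for base in plus)
    cluster.extract_interval = (start, end)
    return cluster


def locus_to_fold_offsets(
    cluster: ReadCluster, locus: tuple[str, int, int, str]
) -> tuple[int, int]:
    """Map a genomic locus to offsets within the cluster's folded sequence.

    For a minus-strand locus the offsets are into ``genomic_seq_minus``
    (which runs 5'->3' on the minus strand).
    """
    if cluster.extract_interval is None:
        raise ValueError("cluster sequences not extracted yet")
    es, ee = cluster.extract_interval
    _chrom, start, end, strand = locus
    if strand == "+":
        return (start - es, end - es)
    return (ee - end, ee - start)
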