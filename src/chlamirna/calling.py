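"""Canonical miRNA calling, CPM quantification and condition set logic.

A cluster is accepted as a miRNA precursor when, in order of evaluation:

1. its genomic sequence contains no ambiguous bases (``AMBIGUOUS_SEQUENCE``);
2. the strand of the most abundant ("main") read folds into a single
   stem-loop that contains the main read within one arm (``NOT_HAIRPIN``);
3. at most ``max_5p_sites`` 5' processing sites each hold at least
   ``min_site_fraction`` of the cluster's read abundance
   (``TOO_MANY_5P_SITES``);
4. the main read represents at least ``predominance_min`` of the locally
   mapped read abundance (``LOW_PREDOMINANCE``);
5. the main read has at most ``max_star_mismatches`` unmatched positions
   against the complementary arm of the hairpin (``STAR_MISMATCHES``).

The first two checks short-circuit (later criteria are undefined without a
hairpin); the remaining checks all run, so a rejection carries every
failing reason.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .cluster import ReadCluster, locus_to_fold_offsets
from .fold import (
    FoldResult,
    HairpinCandidate,
    detect_hairpin,
    mature_arm,
    star_mismatch_count,
)
from .seqio import Locus, to_dna, to_rna


class RejectionReason(str, enum.Enum):
    NOT_HAIRPIN = "NOT_HAIRPIN"
    TOO_MANY_5P_SITES = "TOO_MANY_5P_SITES"
    LOW_PREDOMINANCE = "LOW_PREDOMINANCE"
    STAR_MISMATCHES = "STAR_MISMATCHES"
    AMBIGUOUS_SEQUENCE = "AMBIGUOUS_SEQUENCE"


@dataclass
class MirnaCandidate:
    """A called (or rejected-with-reasons) miRNA for one cluster."""

    id: str
    cluster_id: str
    mature_seq: str | None  # RNA alphabet
    mature_locus: Locus | None
    arm: str | None  # 5p | 3p, relative to the folded strand
    predominance: float | None
    n_predominant_5p_sites: int | None
    star_mismatches: int | None
    status: str  # accepted | rejected
    rejection_reasons: list[RejectionReason] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    @property
    def primary_reason(self) -> RejectionReason | None:
        """First failing criterion in evaluation order (None when accepted)."""
        return self.rejection_reasons[0] if self.rejection_reasons else None


def predominant_5p_sites(
    cluster: ReadCluster, min_site_fraction: float = 0.10
) -> list[tuple[tuple[str, int], float]]:
    """5' processing sites holding >= ``min_site_fraction`` of abundance.

    The 5' coordinate is strand aware (locus start on '+', end-1 on '-');
    sites are returned sorted by descending abundance fraction.
    """
    if not cluster.members:
        raise ValueError(f"cluster {cluster.id} is empty")
    total = cluster.total_abundance
    by_site: dict[tuple[str, int], int] = {}
    for read, locus_index in cluster.members:
        _chrom, start, end, strand = read.loci[locus_index]
        pos = start if strand == "+" else end - 1
        key = (strand, pos)
        by_site[key] = by_site.get(key, 0) + read.abundance
    sites = [
        (key, abundance / total)
        for key, abundance in by_site.items()
        if abundance / total >= min_site_fraction
    ]
    sites.sort(key=lambda item: (-item[1], item[0]))
    return sites


def _main_read(cluster: ReadCluster):
    """Highest-abundance member; ties broken by lexicographically smallest seq."""
    return min(cluster.members, key=lambda m: (-m[0].abundance, m[0].seq))


def call_mirna(
    cluster: ReadCluster,
    folds: Mapping[str, FoldResult],
    predominance_min: float = 0.90,
    max_5p_sites: int = 2,
    max_star_mismatches: int = 4,
    min_site_fraction: float = 0.10,
    min_stem_pairs: int = 15,
) -> MirnaCandidate:
    """Evaluate the canonical miRNA criteria on one cluster.

    ``folds`` maps strand ('+'/'-') to the fold of that strand's cluster
    sequence; only the main read's strand is consulted.  Rejections are
    data, not errors.
    """
    candidate_id = f"mir_{cluster.id}"
    if cluster.has_ambiguous_bases:
        return MirnaCandidate(
            id=candidate_id,
            cluster_id=cluster.id,
            mature_seq=None,
            mature_locus=None,
            arm=None,
            predominance=None,
            n_predominant_5p_sites=None,
            star_mismatches=None,
            status="rejected",
            rejection_reasons=[RejectionReason.AMBIGUOUS_SEQUENCE],
        )

    main, main_locus_index = _main_read(cluster)
    main_locus = main.loci[main_locus_index]
    strand = main_locus[3]
    mature_offsets = locus_to_fold_offsets(cluster, main_locus)

    hairpin: HairpinCandidate | None = None
    fold = folds.get(strand)
    if fold is not None:
        hairpin = detect_hairpin(
            fold, min_stem_pairs=min_stem_pairs, cluster_id=cluster.id, strand=strand
        )
    arm = None
    if hairpin is not None:
        arm = mature_arm(hairpin, mature_offsets)
    if hairpin is None or arm is None:
        return MirnaCandidate(
            id=candidate_id,
            cluster_id=cluster.id,
            mature_seq=to_rna(main.seq),
            mature_locus=main_locus,
            arm=None,
            predominance=None,
            n_predominant_5p_sites=None,
            star_mismatches=None,
            status="rejected",
            rejection_reasons=[RejectionReason.NOT_HAIRPIN],
        )

    reasons: list[RejectionReason] = []
    sites = predominant_5p_sites(cluster, min_site_fraction=min_site_fraction)
    if len(sites) > max_5p_sites:
        reasons.append(RejectionReason.TOO_MANY_5P_SITES)
    predominance = main.abundance / cluster.total_abundance
    if predominance < predominance_min:
        reasons.append(RejectionReason.LOW_PREDOMINANCE)
    mismatches = star_mismatch_count(hairpin, mature_offsets)
    if mismatches > max_star_mismatches:
        reasons.append(RejectionReason.STAR_MISMATCHES)

    return MirnaCandidate(
        id=candidate_id,
        cluster_id=cluster.id,
        mature_seq=to_rna(main.seq),
        mature_locus=main_locus,
        arm=arm,
        predominance=predominance,
        n_predominant_5p_sites=len(sites),
        star_mismatches=mismatches,
        status="accepted" if not reasons else "rejected",
        rejection_reasons=reasons,
    )


def compute_cpm(c: float, n: float) -> float:
    """Counts per million mapped reads: 1e6 * C / N."""
    if n <= 0:
        raise ValueError(f"library total must be positive, got {n}")
    if c < 0:
        raise ValueError(f"count must be non-negative, got {c}")
    return 1e6 * c / n


def expression_records(
    mirnas: Iterable[MirnaCandidate],
    library_abundances: Mapping[str, Mapping[str, int]],
    library_totals: Mapping[str, int],
    cpm_cutoff: float = 500.0,
) -> pd.DataFrame:
    """Per-miRNA CPM per library, mean CPM, and the low/high expression class.

    ``library_abundances`` maps library name to {DNA read sequence:
    abundance}; the count C for a miRNA in a library is the abundance of
    its exact mature sequence there.  The expression class is 'high' iff
    mean CPM >= ``cpm_cutoff`` (the cutoff is inclusive).
    """
    libraries = sorted(library_totals)
    rows = []
    for mirna in mirnas:
        if not mirna.accepted or mirna.mature_seq is None:
            continue
        mature_dna = to_dna(mirna.mature_seq)
        cpms = {
            lib: compute_cpm(
                library_abundances.get(lib, {}).get(mature_dna, 0),
                library_totals[lib],
            )
            for lib in libraries
        }
        mean_cpm = sum(cpms.values()) / len(libraries)
        rows.append(
            {
                "mirna_id": mirna.id,
                **{f"cpm_{lib}": cpms[lib] for lib in libraries},
                "mean_cpm": mean_cpm,
                "expression_class": "high" if mean_cpm >= cpm_cutoff else "low",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mirna_id"]
        + [f"cpm_{lib}" for lib in libraries]
        + ["mean_cpm", "expression_class"],
    )


@dataclass
class ConditionSets:
    """Per-condition identified miRNA sets, with prevalence/Venn summaries.

    MicroRNAs are matched across libraries by exact mature genomic locus,
    so keys are ``(chrom, start, end, strand)`` tuples.
    """

    identified: dict[str, set[Locus]]

    @property
    def union(self) -> set[Locus]:
        out: set[Locus] = set()
        for s in self.identified.values():
            out |= s
        return out

    def prevalent(self) -> dict[str, set[Locus]]:
        """miRNAs identified in exactly one condition (disjoint by construction)."""
        out = {}
        for cond, members in self.identified.items():
            others: set[Locus] = set()
            for other, s in self.identified.items():
                if other != cond:
                    others |= s
            out[cond] = members - others
        return out

    def venn_counts(self) -> dict[frozenset, int]:
        """Exact-region counts; values sum to the size of the union."""
        regions: dict[frozenset, int] = {}
        for key in self.union:
            membership = frozenset(
                cond for cond, s in self.identified.items() if key in s
            )
            regions[membership] = regions.get(membership, 0) + 1
        return regions


def assign_condition_sets(
    calls_by_library: Mapping[str, Iterable[MirnaCandidate]],
    condition_of: Mapping[str, str],
) -> ConditionSets:
    """A miRNA is identified in a condition iff accepted in >=1 of its libraries."""
    missing = set(calls_by_library) - set(condition_of)
    if missing:
        raise ValueError(f"libraries without a condition: {sorted(missing)}")
    identified: dict[str, set[Locus]] = {
        cond: set() for cond in dict.fromkeys(condition_of.values())
    }
    for library, calls in calls_by_library.items():
        cond = condition_of[library]
        for call in calls:
            if call.accepted and call.mature_locus is not None:
                identified[cond].add(call.mature_locus)
    return ConditionSets(identified=identified)


def call_library(
    reads,
    genome: Mapping[str, str],
    *,
    max_gap: int = 200,
    flank: int = 20,
    backend: str = "builtin",
    predominance_min: float = 0.90,
    max_5p_sites: int = 2,
    max_star_mismatches: int = 4,
    min_site_fraction: float = 0.10,
    min_stem_pairs: int = 15,
) -> tuple[list[MirnaCandidate], list[ReadCluster]]:
    """Cluster, fold and call one library's aligned reads end to end."""
    from .cluster import cluster_reads, extract_cluster_sequences
    from .fold import fold_hairpin, fold_sequence

    clusters = cluster_reads(reads, max_gap=max_gap)
    calls = []
    for cl in clusters:
        extract_cluster_sequences(cl, genome, flank=flank)
        folds = {}
        if not cl.has_ambiguous_bases and len(cl.genomic_seq_plus or "") >= 10:
            if backend == "external":
                folds["+"] = fold_sequence(cl.genomic_seq_plus, backend="external")
                folds["-"] = fold_sequence(cl.genomic_seq_minus, backend="external")
            else:
                folds["+"] = fold_hairpin(cl.genomic_seq_plus)
                folds["-"] = fold_hairpin(cl.genomic_seq_minus)
        calls.append(
            call_mirna(
                cl,
                folds,
                predominance_min=predominance_min,
                max_5p_sites=max_5p_sites,
                max_star_mismatches=max_star_mismatches,
                min_site_fraction=min_site_fraction,
                min_stem_pairs=min_stem_pairs,
            )
        )
    return calls, clusters
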