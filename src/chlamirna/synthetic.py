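"""Synthetic genomes, sRNA libraries and transcriptomes with planted truth.

The generator builds the conditions the calling criteria are designed
for: hairpin precursor loci whose mature arm is reverse-complemented by a
star arm with a configurable number of mismatches; read populations
concentrated at one predominant 5' processing site (with configurable
predominance, 5'-jittered minor reads and a small miRNA* fraction);
abundant unstructured background/degradation reads in the spacer regions
between loci; and transcripts carrying target windows that satisfy or
violate the cleavage/translational grammar.  Every construct is recorded
in a machine-readable truth object so downstream stages can be scored
exactly.

Construction notes, all deliberate:

* spacers (and decoy loci) are drawn from an A/C alphabet, which cannot
  base-pair with itself, so non-precursor clusters never fold into stems
  and the planted hairpins are the only hairpins in the genome;
* the terminal loop is poly-C and star-arm mutations are placed at
  interior, non-adjacent stem positions with substitutes that can pair
  neither their mature partner (no Watson-Crick, no G:U) nor the loop, so
  a maximum-pairing fold leaves exactly the planted positions unmatched;
* jittered reads shift the 5' end with the 3' end co-shifting (constant
  length), since the calling criteria concern 5' processing sites;
* background reads keep a >200-nt distance from precursor reads so they
  can never merge into a precursor cluster under the clustering rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import (
    AlignedRead,
    Locus,
    map_exact,
    revcomp_rna,
    to_dna,
    to_rna,
    write_alignment_table,
    write_bed,
    write_fasta,
    write_fastq,
    write_tsv,
)

RNA_BASES = "ACGU"

#: substitute that can pair neither the given mature base nor a loop C
_MISMATCH_SUBSTITUTE = {"A": "C", "C": "A", "G": "A", "U": "C"}

#: minimum distance kept between background reads and spacer edges
BACKGROUND_MARGIN = 210


class InvalidAlphabetError(ValueError):
    """A sequence contains characters outside the expected alphabet."""


@dataclass
class PlantedPrecursor:
    """A hairpin precursor construct with known mature/star geometry."""

    id: str
    mature_seq: str  # RNA
    arm: str  # 5p | 3p
    loop_len: int
    star_mismatch_count: int
    full_seq: str  # DNA
    mature_offset: int  # offset of the mature within full_seq
    star_offset: int
    intended_valid: bool
    defect: str | None = None  # planted rejection reason, if any

    @property
    def length(self) -> int:
        return len(self.full_seq)


@dataclass
class SyntheticTruth:
    """Ground truth for one planted genome."""

    precursors: list[PlantedPrecursor]
    placements: dict[str, Locus]
    spacer_intervals: list[tuple[int, int]]
    expression_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    predominance_target: float = 0.95
    planted_sites: list[tuple[str, tuple[int, int], str, str]] = field(
        default_factory=list
    )
    read_profiles: dict[str, dict] = field(default_factory=dict)
    reserved_spacers: set[int] = field(default_factory=set)
    extra_copies: list[Locus] = field(default_factory=list)

    def precursor(self, pid: str) -> PlantedPrecursor:
        for p in self.precursors:
            if p.id == pid:
                return p
        raise KeyError(pid)


def _check_rna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq or set(seq) - set(RNA_BASES):
        raise InvalidAlphabetError(f"{what} must be non-empty RNA (ACGU): {seq!r}")
    return seq


def _random_rna(rng: np.random.Generator, length: int, alphabet: str = RNA_BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _unique_ac_sequence(rng: np.random.Generator, length: int, k: int = 18) -> str:
    """Random A/C sequence in which every k-mer occurs exactly once.

    Spacer reads are substrings of this stream, so they map back to
    exactly one genomic locus: without the uniqueness guarantee,
    low-complexity background reads would multi-map across spacers and
    bridge otherwise well-separated read clusters.
    """
    if length > 2 ** (k - 2):  # stay far from k-mer exhaustion
        raise ValueError(f"cannot build {length} nt of unique {k}-mers")
    seen: set[str] = set()
    chars: list[str] = []
    while len(chars) < length:
        for base in ("AC" if rng.random() < 0.5 else "CA"):
            candidate = chars + [base]
            if len(candidate) < k or "".join(candidate[-k:]) not in seen:
                chars.append(base)
                if len(chars) >= k:
                    seen.add("".join(chars[-k:]))
                break
        else:  # both extensions collide: back up one step and retry
            if len(chars) >= k:
                seen.discard("".join(chars[-k:]))
            chars.pop()
    return "".join(chars)


def _choose_mismatches(
    rng: np.random.Generator, mature: str, k: int
) -> list[tuple[int, str]]:
    """Select star positions and substitute bases for k planted mismatches.

    Positions sit >= 2 pairs away from both stem ends and >= 2 apart, so a
    gap-penalized stem fold never truncates the stem at a mismatch.  The
    substitute base pairs neither its mature partner nor the partner's
    neighbours (no Watson-Crick, no G:U), so the fold cannot absorb a
    planted mismatch through a one-base register shift; positions where no
    such base exists are skipped while alternatives remain.
    """
    length = len(mature)
    safe: list[tuple[int, str]] = []
    risky: list[tuple[int, str]] = []
    for pos in range(2, length - 2, 2):
        i = length - 1 - pos  # facing mature index
        neighbourhood = mature[max(0, i - 1) : i + 2]
        for base, forbidden in (("A", "U"), ("C", "G")):
            if forbidden not in neighbourhood:
                safe.append((pos, base))
                break
        else:
            risky.append((pos, _MISMATCH_SUBSTITUTE[mature[i]]))
    pool = safe + risky
    if k <= len(pool):
        ordered = safe if k <= len(safe) else pool
        chosen = rng.choice(len(ordered), size=min(k, len(ordered)), replace=False)
        picks = [ordered[i] for i in chosen]
        if len(picks) < k:
            extra = [p for p in pool if p not in picks]
            picks += extra[: k - len(picks)]
    else:
        leftover = [
            (pos, _MISMATCH_SUBSTITUTE[mature[length - 1 - pos]])
            for pos in range(length)
            if pos not in {p for p, _ in pool}
        ]
        picks = pool + leftover[: k - len(pool)]
    return sorted(picks[:k])


def make_precursor(
    mature_seq: str,
    arm: str = "5p",
    loop_len: int = 4,
    star_mismatches: int = 0,
    rng_seed: int = 0,
    precursor_id: str | None = None,
) -> PlantedPrecursor:
    """Build a hairpin precursor around a mature sequence.

    The star arm is the reverse complement of the mature arm except at
    exactly ``star_mismatches`` positions.  A precursor is intended to
    pass the calling criteria iff ``star_mismatches <= 4``.
    """
    mature = _check_rna(mature_seq, "mature sequence")
    if not 18 <= len(mature) <= 26:
        raise ValueError(f"mature length must be 18..26 nt, got {len(mature)}")
    if loop_len < 3:
        raise ValueError(f"terminal loop must be >= 3 nt, got {loop_len}")
    if not 0 <= star_mismatches <= len(mature):
        raise ValueError("star_mismatches out of range")
    if arm not in ("5p", "3p"):
        raise ValueError(f"arm must be 5p or 3p, got {arm!r}")

    from .fold import detect_hairpin, fold_hairpin, mature_arm, star_mismatch_count

    rng = np.random.default_rng(rng_seed)
    length = len(mature)
    loop = "C" * loop_len

    # try mismatch position/base assignments until the stem fold counts
    # exactly the planted number (a rare assignment lets the fold absorb
    # or overshoot a mismatch through register shifts); keep the last
    # attempt if none verifies
    for _attempt in range(30):
        star = list(revcomp_rna(mature))
        for pos, base in _choose_mismatches(rng, mature, star_mismatches):
            star[pos] = base
        star_seq = "".join(star)
        if arm == "5p":
            full = mature + loop + star_seq
            mature_offset, star_offset = 0, length + loop_len
        else:
            full = star_seq + loop + mature
            star_offset, mature_offset = 0, length + loop_len
        if star_mismatches == 0:
            break
        hairpin = detect_hairpin(fold_hairpin(full), min_stem_pairs=1)
        if hairpin is not None:
            interval = (mature_offset, mature_offset + length)
            if (
                mature_arm(hairpin, interval) is not None
                and star_mismatch_count(hairpin, interval) == star_mismatches
            ):
                break
    return PlantedPrecursor(
        id=precursor_id or f"pre_{abs(hash((mature, arm, star_mismatches))) % 10**6}",
        mature_seq=mature,
        arm=arm,
        loop_len=loop_len,
        star_mismatch_count=star_mismatches,
        full_seq=to_dna(full),
        mature_offset=mature_offset,
        star_offset=star_offset,
        intended_valid=star_mismatches <= 4,
        defect="STAR_MISMATCHES" if star_mismatches > 4 else None,
    )


def with_ambiguous_loop(precursor: PlantedPrecursor) -> PlantedPrecursor:
    """Copy of a precursor with an unsequenced base (N) in its terminal loop."""
    loop_start = min(
        p for p in (precursor.mature_offset, precursor.star_offset) if p > 0
    ) - precursor.loop_len
    pos = loop_start + precursor.loop_len // 2
    full = precursor.full_seq[:pos] + "N" + precursor.full_seq[pos + 1 :]
    return dataclasses.replace(
        precursor,
        full_seq=full,
        intended_valid=False,
        defect="AMBIGUOUS_SEQUENCE",
    )


def make_nonhairpin_locus(
    rng_seed: int = 0,
    mature_len: int = 21,
    loop_len: int = 4,
    precursor_id: str | None = None,
    sequence: str | None = None,
) -> PlantedPrecursor:
    """A locus that expresses reads but cannot fold (A/C alphabet, no pairs).

    Stands in for a degradation hotspot; shaped like a precursor for
    uniform plumbing, but its "star arm" is unrelated sequence.  When
    planting alongside A/C spacers, pass a slice of the same
    unique-k-mer stream as ``sequence`` so the locus reads cannot
    multi-map into the spacers.
    """
    total = 2 * mature_len + loop_len
    if sequence is None:
        rng = np.random.default_rng(rng_seed)
        sequence = to_dna(_unique_ac_sequence(rng, total))
    if len(sequence) != total or set(sequence) - {"A", "C"}:
        raise ValueError("sequence must be A/C of length 2*mature_len + loop_len")
    return PlantedPrecursor(
        id=precursor_id or f"flat_{rng_seed}",
        mature_seq=to_rna(sequence[:mature_len]),
        arm="5p",
        loop_len=loop_len,
        star_mismatch_count=mature_len,
        full_seq=sequence,
        mature_offset=0,
        star_offset=mature_len + loop_len,
        intended_valid=False,
        defect="NOT_HAIRPIN",
    )


def plant_genome(
    precursors: Sequence[PlantedPrecursor],
    spacer_len: int = 500,
    rng_seed: int = 0,
    chrom: str = "chr1",
) -> tuple[dict[str, str], SyntheticTruth]:
    """Lay precursors on one chromosome separated by non-pairing spacers.

    ``spacer_len`` must exceed the 200-nt clustering gap so distinct loci
    can never co-cluster.  Genome length is the sum of precursor lengths
    plus ``(n + 1) * spacer_len``.
    """
    if not precursors:
        raise ValueError("need at least one precursor to plant")
    if spacer_len <= 200:
        raise ValueError(f"spacer_len must exceed 200 nt, got {spacer_len}")
    rng = np.random.default_rng(rng_seed)
    stream = to_dna(_unique_ac_sequence(rng, spacer_len * (len(precursors) + 1)))
    parts: list[str] = []
    placements: dict[str, Locus] = {}
    spacers: list[tuple[int, int]] = []
    cursor = 0
    for i, precursor in enumerate(precursors):
        parts.append(stream[i * spacer_len : (i + 1) * spacer_len])
        spacers.append((cursor, cursor + spacer_len))
        cursor += spacer_len
        parts.append(precursor.full_seq)
        placements[precursor.id] = (chrom, cursor, cursor + precursor.length, "+")
        cursor += precursor.length
    parts.append(stream[len(precursors) * spacer_len :])
    spacers.append((cursor, cursor + spacer_len))
    genome = {chrom: "".join(parts)}
    truth = SyntheticTruth(
        precursors=list(precursors),
        placements=placements,
        spacer_intervals=spacers,
    )
    return genome, truth


def embed_multimap_copy(
    genome: dict[str, str],
    truth: SyntheticTruth,
    precursor_id: str,
    spacer_index: int = 0,
) -> None:
    """Plant an extra exact copy of a mature sequence inside a spacer.

    Gives that mature read a second genomic locus (a multi-mapper); the
    copy sits in the background-free band of the spacer, far enough from
    everything to form its own (non-hairpin) cluster.
    """
    precursor = truth.precursor(precursor_id)
    chrom, pstart, _pend, _ = truth.placements[precursor_id]
    s, e = truth.spacer_intervals[spacer_index]
    mature_dna = to_dna(precursor.mature_seq)
    offset = s + (e - s) // 2 - len(mature_dna) // 2
    if offset - s <= 200 or e - (offset + len(mature_dna)) <= 200:
        raise ValueError("spacer too short to host a distant copy")
    g = genome[chrom]
    genome[chrom] = g[:offset] + mature_dna + g[offset + len(mature_dna) :]
    # keep background reads out of this spacer: substrings of the copy
    # would otherwise multi-map into the true precursor cluster
    truth.reserved_spacers.add(spacer_index)
    truth.extra_copies.append((chrom, offset, offset + len(mature_dna), "+"))


@dataclass
class SimulatedLibrary:
    """One library's collapsed reads and their alignments."""

    name: str
    counts: dict[str, int]  # DNA sequence -> abundance
    aligned: list[AlignedRead]
    total_reads: int  # abundance-weighted, equals the requested size

    @property
    def total_mapped(self) -> int:
        return sum(read.abundance for read in self.aligned)

    def fastq_records(self) -> list[tuple[str, str, str]]:
        return [
            (f"{self.name}_r{i}_x{count}", seq, "I" * len(seq))
            for i, (seq, count) in enumerate(sorted(self.counts.items()))
        ]


def _largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    """Integer apportionment of ``total`` by weight, exact by construction."""
    wsum = float(sum(weights))
    if wsum <= 0:
        raise ValueError("weights must sum to a positive value")
    shares = [total * w / wsum for w in weights]
    counts = [int(s) for s in shares]
    deficit = total - sum(counts)
    order = sorted(
        range(len(shares)), key=lambda i: (-(shares[i] - counts[i]), i)
    )
    for i in order[:deficit]:
        counts[i] += 1
    return counts


def _junction_ac_kmers(
    chrom_seq: str, truth: SyntheticTruth, lengths=range(18, 27)
) -> set[str]:
    """All-A/C k-mers that cross a spacer/locus junction.

    A background read carrying such a sequence would map both to its
    spacer position and to the junction, dragging it into (or towards) a
    precursor cluster; the simulator avoids sampling them.
    """
    boundaries: list[int] = []
    for _chrom, ps, pe, _strand in list(truth.placements.values()) + truth.extra_copies:
        boundaries += [ps, pe]
    kmers: set[str] = set()
    for b in boundaries:
        for L in lengths:
            for start in range(max(0, b - L + 1), b):
                kmer = chrom_seq[start : start + L]
                if len(kmer) == L and not (set(kmer) - {"A", "C"}):
                    kmers.add(kmer)
    return kmers


def _default_profile(
    predominance: float, offset_jitter: int, star_fraction: float
) -> dict:
    star = min(star_fraction, 1.0 - predominance)
    jitter_offsets = [o for o in range(-offset_jitter, offset_jitter + 1) if o != 0]
    leftover = 1.0 - predominance - star
    sites = [(0, predominance)]
    if jitter_offsets and leftover > 0:
        sites += [(o, leftover / len(jitter_offsets)) for o in jitter_offsets]
    else:
        sites[0] = (0, predominance + leftover)
    return {"sites": sites, "star": star}


def simulate_reads(
    truth: SyntheticTruth,
    genome: Mapping[str, str],
    library_sizes: Mapping[str, int],
    predominance: float = 0.95,
    offset_jitter: int = 2,
    background_fraction: float = 0.02,
    star_fraction: float = 0.02,
    rng_seed: int = 0,
    max_loci: int = 5,
) -> dict[str, SimulatedLibrary]:
    """Simulate collapsed sRNA libraries from a planted genome.

    Per expressed precursor, a fraction ``predominance`` of reads is the
    exact mature sequence, a small ``star_fraction`` comes from the star
    arm, and the rest are 5'-jittered copies of the mature (up to
    ``offset_jitter`` nt, constant length).  ``truth.read_profiles`` can
    override the per-precursor site layout; ``truth.expression_weights``
    gives relative per-library precursor expression.  Background reads
    are spacer substrings (18-26 nt).  Abundance-weighted read totals
    equal the requested library sizes exactly.
    """
    if not 0 < predominance <= 1:
        raise ValueError(f"predominance must be in (0, 1], got {predominance}")
    if offset_jitter < 0:
        raise ValueError("offset_jitter must be >= 0")
    if not 0 <= background_fraction < 1:
        raise ValueError("background_fraction must be in [0, 1)")
    if predominance + star_fraction > 1 + 1e-9:
        star_fraction = 1.0 - predominance

    rng = np.random.default_rng(rng_seed)
    chrom = next(iter(truth.placements.values()))[0]
    chrom_seq = genome[chrom]
    libraries: dict[str, SimulatedLibrary] = {}

    for lib in sorted(library_sizes):
        size = int(library_sizes[lib])
        weights = truth.expression_weights.get(lib)
        if weights is None:
            weights = {p.id: 1.0 for p in truth.precursors}
        expressed = [(pid, w) for pid, w in sorted(weights.items()) if w > 0]
        n_background = int(round(background_fraction * size))
        pool = size - n_background
        depths = _largest_remainder(pool, [w for _, w in expressed])

        counts: dict[str, int] = {}

        def add(seq: str, n: int) -> None:
            if n > 0:
                counts[seq] = counts.get(seq, 0) + n

        for (pid, _w), depth in zip(expressed, depths):
            if depth == 0:
                continue
            precursor = truth.precursor(pid)
            _c, pstart, _pend, _strand = truth.placements[pid]
            mstart = pstart + precursor.mature_offset
            mlen = len(precursor.mature_seq)
            profile = truth.read_profiles.get(
                pid, _default_profile(predominance, offset_jitter, star_fraction)
            )
            entries = [("site", off, frac) for off, frac in profile["sites"]]
            entries.append(("star", 0, profile.get("star", 0.0)))
            entries = [e for e in entries if e[2] > 0]
            alloc = _largest_remainder(depth, [e[2] for e in entries])
            # guarantee at least one star read so the cluster spans both arms
            star_idx = next(
                (i for i, e in enumerate(entries) if e[0] == "star"), None
            )
            if star_idx is not None and alloc[star_idx] == 0:
                main_idx = max(range(len(alloc)), key=lambda i: alloc[i])
                alloc[main_idx] -= 1
                alloc[star_idx] += 1
            for (kind, off, _frac), n in zip(entries, alloc):
                if kind == "star":
                    sstart = pstart + precursor.star_offset
                    add(chrom_seq[sstart : sstart + mlen], n)
                else:
                    add(chrom_seq[mstart + off : mstart + off + mlen], n)

        if n_background:
            usable = [
                (s, e)
                for idx, (s, e) in enumerate(truth.spacer_intervals)
                if e - s >= 2 * BACKGROUND_MARGIN + 26
                and idx not in truth.reserved_spacers
            ]
            if not usable:
                raise ValueError(
                    "spacers too short for background reads; need "
                    f">= {2 * BACKGROUND_MARGIN + 26} nt"
                )
            forbidden = _junction_ac_kmers(chrom_seq, truth)
            which = rng.integers(0, len(usable), size=n_background)
            lens = rng.integers(18, 27, size=n_background)
            fracs = rng.random(size=n_background)
            from collections import Counter

            combos = Counter()
            for w, L, f in zip(which, lens, fracs):
                s, e = usable[w]
                lo = s + BACKGROUND_MARGIN
                hi = e - BACKGROUND_MARGIN - int(L)
                start = lo + int(f * (hi - lo + 1))
                # skip the rare position whose sequence also occurs at a
                # spacer/locus junction (it would multi-map there)
                while chrom_seq[start : start + int(L)] in forbidden:
                    start = lo + (start - lo + 1) % (hi - lo + 1)
                combos[(start, int(L))] += 1
            for (start, L), n in combos.items():
                add(chrom_seq[start : start + L], n)

        aligned = map_exact(counts, genome, max_loci=max_loci)
        libraries[lib] = SimulatedLibrary(
            name=lib,
            counts=counts,
            aligned=aligned,
            total_reads=sum(counts.values()),
        )
    return libraries


def write_library(sim: SimulatedLibrary, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fastq(sim.fastq_records(), outdir / f"{sim.name}.fastq")
    write_alignment_table(sim.aligned, outdir / f"{sim.name}.alignments.tsv")


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> None:
    """Persist the truth: precursor BED6, expression TSV, planted-site TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(
        [
            (
                chrom,
                start,
                end,
                pid,
                0 if truth.precursor(pid).intended_valid else 1,
                strand,
            )
            for pid, (chrom, start, end, strand) in truth.placements.items()
        ],
        outdir / "truth_precursors.bed",
    )
    libs = sorted(truth.expression_weights)
    rows = [["precursor", "intended_valid", "defect"] + [f"weight_{l}" for l in libs]]
    for p in truth.precursors:
        rows.append(
            [p.id, int(p.intended_valid), p.defect or "."]
            + [truth.expression_weights[l].get(p.id, 0.0) for l in libs]
        )
    write_tsv(rows, outdir / "truth_expression.tsv")
    site_rows = [["transcript", "start", "end", "mirna", "site_class"]]
    for tid, (s, e), mid, cls in truth.planted_sites:
        site_rows.append([tid, s, e, mid, cls])
    write_tsv(site_rows, outdir / "truth_sites.tsv")


# ---------------------------------------------------------------------------
# Target-site planting
# ---------------------------------------------------------------------------

def _engineer_position(
    window: list[str], mirna: str, position: int, kind: str, rng: np.random.Generator
) -> None:
    """Break/wobble the pairing of one miRNA position inside a window.

    ``position`` is 1-based from the miRNA 5' end; the facing target base
    sits at window index ``len(mirna) - position``.
    """
    m = mirna[position - 1]
    idx = len(mirna) - position
    if kind == "wobble" and m in "GU":
        window[idx] = "U" if m == "G" else "G"
    elif kind == "wobble":
        raise ValueError(f"no G:U wobble possible opposite miRNA base {m}")
    else:  # mismatch: the same base never pairs with itself
        window[idx] = m


def plant_targets(
    mirnas: Sequence[tuple[str, str]],
    transcripts_per_mirna: int | Mapping[str, int] = 3,
    site_class: str = "cleavage",
    rng_seed: int = 0,
    transcript_len: int = 300,
    catalytic_imperfections: int = 1,
    max_remainder_noise: int = 2,
) -> tuple[list[tuple[str, str]], list[tuple[str, tuple[int, int], str, str]]]:
    """Build transcripts each carrying one engineered window for one miRNA.

    ``cleavage`` windows pair perfectly over miRNA positions 1-12 with up
    to ``max_remainder_noise`` wobbles/mismatches in the remainder;
    ``translational`` windows additionally carry
    ``catalytic_imperfections`` wobbles/mismatches in positions 9-12;
    ``decoy`` windows violate the seed.  ``transcripts_per_mirna`` may be
    a single count or a per-miRNA-id mapping.  Transcript backgrounds are
    redrawn until they contain no accidental site for *any* given miRNA,
    so the truth table is exhaustive for the whole set.
    """
    from .targets import scan_transcriptome

    if site_class not in ("cleavage", "translational", "decoy"):
        raise ValueError(f"unknown site class {site_class!r}")
    rng = np.random.default_rng(rng_seed)
    all_mirnas = [(mid, _check_rna(mseq, f"miRNA {mid}")) for mid, mseq in mirnas]
    transcripts: list[tuple[str, str]] = []
    planted: list[tuple[str, tuple[int, int], str, str]] = []
    for mirna_id, m in all_mirnas:
        L = len(m)
        if isinstance(transcripts_per_mirna, Mapping):
            n_transcripts = int(transcripts_per_mirna.get(mirna_id, 0))
        else:
            n_transcripts = int(transcripts_per_mirna)
        for t in range(n_transcripts):
            tid = f"{mirna_id}_{site_class}_t{t}"
            window = list(revcomp_rna(m))
            if site_class in ("cleavage", "translational"):
                n_noise = int(rng.integers(0, max_remainder_noise + 1))
                # positions >= 14 stay in the remainder even when a 1-nt
                # bulge shifts the register of an overlapping window
                noise_pool = list(range(14, L))
                for position in rng.choice(
                    noise_pool, size=min(n_noise, len(noise_pool)), replace=False
                ):
                    kind = (
                        "wobble"
                        if m[position - 1] in "GU" and rng.random() < 0.5
                        else "mismatch"
                    )
                    _engineer_position(window, m, int(position), kind, rng)
            if site_class == "translational":
                if not 1 <= catalytic_imperfections <= 2:
                    raise ValueError("catalytic_imperfections must be 1 or 2")
                # only 10 and 11 remain catalytic under a +-1 register shift
                positions = rng.choice(
                    [10, 11], size=catalytic_imperfections, replace=False
                )
                for position in positions:
                    kind = "wobble" if m[int(position) - 1] in "GU" else "mismatch"
                    _engineer_position(window, m, int(position), kind, rng)
            if site_class == "decoy":
                # positions 4 and 6 stay inside the seed under +-1 shifts
                for position in (4, 6):
                    _engineer_position(window, m, position, "mismatch", rng)
            wseq = "".join(window)
            start = int(rng.integers(20, transcript_len - L - 20))
            for _attempt in range(50):
                background = _random_rna(rng, transcript_len)
                tseq = background[:start] + wseq + background[start + L :]
                found = scan_transcriptome(all_mirnas, [(tid, tseq)])
                if site_class == "decoy":
                    accidental = found
                else:
                    # windows overlapping the planted duplex for its own
                    # miRNA are satellite representations of the same
                    # site, not accidents
                    accidental = [
                        s
                        for s in found
                        if s.mirna_id != mirna_id
                        or not (s.start < start + L and start < s.end)
                    ]
                if not accidental:
                    break
            else:  # pragma: no cover - vanishingly unlikely
                raise RuntimeError("could not draw a clean transcript background")
            transcripts.append((tid, tseq))
            if site_class != "decoy":
                planted.append((tid, (start, start + L), mirna_id, site_class))
    return transcripts, planted


# ---------------------------------------------------------------------------
# Two-group target-count distributions for the statistics stage
# ---------------------------------------------------------------------------

def simulate_target_counts(
    n_low: int = 47,
    n_high: int = 18,
    mean_low: float = 5.11,
    mean_high: float = 1.78,
    dispersion_low: float = 0.35,
    dispersion_high: float = 0.7,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-miRNA target counts for a low- and a high-expression group.

    Counts are 1 + negative-binomial (every included miRNA has at least
    one target, since no-target miRNAs are excluded upstream).  The
    defaults emulate the observed AGO3-library contrast: 47 lowly
    expressed condition-prevalent miRNAs averaging ~5.1 cleavage targets
    with a heavy right tail, against 18 highly expressed shared miRNAs
    averaging ~1.8; the low-group dispersion is set so the expected
    pooled-SD effect size is ~0.54.
    """
    if mean_low < 1 or mean_high < 1:
        raise ValueError("group means must be >= 1 (no-target miRNAs are excluded)")
    rng = np.random.default_rng(rng_seed)
    return (
        shifted_nb_counts(rng, n_low, mean_low, dispersion_low),
        shifted_nb_counts(rng, n_high, mean_high, dispersion_high),
    )


def shifted_nb_counts(
    rng: np.random.Generator, n: int, mean: float, dispersion: float
) -> np.ndarray:
    """1 + negative-binomial counts with the given mean and dispersion r."""
    mu = mean - 1.0
    if mu <= 0:
        return np.ones(n, dtype=int)
    p = dispersion / (dispersion + mu)
    return 1 + rng.negative_binomial(dispersion, p, size=n)


# ---------------------------------------------------------------------------
# The standard planted benchmark
# ---------------------------------------------------------------------------

def _verified_precursor(
    rng: np.random.Generator,
    length: int,
    arm: str,
    loop_len: int,
    star_mismatches: int,
    precursor_id: str,
    flanks: tuple[str, str] = ("", ""),
    min_stem_pairs: int = 15,
    max_tries: int = 200,
) -> PlantedPrecursor:
    """Draw a precursor whose fold round-trips its planted geometry.

    Construction postcondition, checked here: the stem fold of the bare
    precursor - and of the precursor embedded in its future genomic
    flanks, over the window sizes the caller will see - is a detected
    hairpin containing the mature in one arm whose counted star-arm
    mismatches equal the planted number.  (Flanking spacer bases can
    occasionally absorb a planted mismatch through a register shift;
    redrawing the mature sequence removes such constructs.)
    """
    from .fold import detect_hairpin, fold_hairpin, mature_arm, star_mismatch_count

    left, right = flanks
    for _ in range(max_tries):
        precursor = make_precursor(
            _random_rna(rng, length),
            arm=arm,
            loop_len=loop_len,
            star_mismatches=star_mismatches,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
            precursor_id=precursor_id,
        )
        windows = [("", "")] + [
            (left[len(left) - f :] if f else "", right[:f]) for f in (18, 20, 22) if left
        ]
        for lf, rf in windows:
            fold = fold_hairpin(lf + precursor.full_seq + rf)
            hairpin = detect_hairpin(fold, min_stem_pairs=min_stem_pairs)
            if hairpin is None:
                break
            interval = (
                len(lf) + precursor.mature_offset,
                len(lf) + precursor.mature_offset + len(precursor.mature_seq),
            )
            if mature_arm(hairpin, interval) is None:
                break
            if star_mismatch_count(hairpin, interval) != star_mismatches:
                break
        else:
            return precursor
    raise RuntimeError(
        f"could not construct a verifiable precursor ({star_mismatches} mismatches)"
    )


DEFECT_KINDS = (
    "STAR_MISMATCHES",
    "TOO_MANY_5P_SITES",
    "LOW_PREDOMINANCE",
    "AMBIGUOUS_SEQUENCE",
    "NOT_HAIRPIN",
)


def benchmark_truth(
    rng_seed: int = 0,
    n_valid: int = 20,
    defects_per_kind: int = 2,
    libraries: Sequence[str] = ("TAP", "HSplusN", "HSminusN"),
    spacer_len: int = 500,
    plant_multimapper: bool = True,
) -> tuple[dict[str, str], SyntheticTruth]:
    """The standard planted-genome scenario used by tests and reporting.

    ``n_valid`` precursors that must be accepted (star mismatches cycling
    1..4; mature lengths cycling 20-22) plus ``defects_per_kind``
    precursors per planted defect kind, each carrying exactly one defect:
    five star mismatches; three predominant 5' sites; 0.85 predominance;
    an N in the loop; an unfoldable locus.  With several libraries, a
    block of valid precursors is expressed everywhere and the rest are
    condition-exclusive, giving non-trivial prevalence/Venn structure.
    """
    rng = np.random.default_rng(rng_seed)

    # plan: (id, mature_len, arm, loop_len, star_mismatches, defect kind)
    plan: list[tuple[str, int, str, int, int, str | None]] = []
    for i in range(n_valid):
        plan.append(
            (
                f"valid_{i:02d}",
                20 + i % 3,
                "5p" if i % 2 == 0 else "3p",
                4 + i % 3,
                1 + i % 4,
                None,
            )
        )
    for kind in DEFECT_KINDS:
        for j in range(defects_per_kind):
            k = 5 if kind == "STAR_MISMATCHES" else 1
            plan.append((f"{kind.lower()}_{j}", 21, "5p", 4, k, kind))

    # the spacer stream is reproduced from rng_seed inside plant_genome
    # (its prefix), so each precursor can be verified here against its
    # future genomic flanks; unfoldable loci are carved from the stream's
    # tail so their reads stay k-mer-unique against the spacers
    spacer_total = spacer_len * (len(plan) + 1)
    n_flat = sum(1 for entry in plan if entry[5] == "NOT_HAIRPIN")
    stream = to_dna(
        _unique_ac_sequence(
            np.random.default_rng(rng_seed), spacer_total + 46 * n_flat
        )
    )

    precursors: list[PlantedPrecursor] = []
    profiles: dict[str, dict] = {}
    flat_index = 0
    for i, (pid, mlen, arm, loop_len, k, kind) in enumerate(plan):
        left = stream[(i + 1) * spacer_len - 22 : (i + 1) * spacer_len]
        right = stream[(i + 1) * spacer_len : (i + 1) * spacer_len + 22]
        if kind == "NOT_HAIRPIN":
            tail = spacer_total + 46 * flat_index
            p = make_nonhairpin_locus(
                precursor_id=pid, sequence=stream[tail : tail + 46]
            )
            flat_index += 1
            # no 5'-jittered reads: a jittered read would straddle the
            # spacer junction and could multi-map elsewhere
            profiles[pid] = {"sites": [(0, 0.95)], "star": 0.05}
        else:
            p = _verified_precursor(
                rng, mlen, arm, loop_len, k, pid, flanks=(left, right)
            )
            if kind == "AMBIGUOUS_SEQUENCE":
                p = with_ambiguous_loop(p)
            elif kind is not None and kind != "STAR_MISMATCHES":
                p = dataclasses.replace(p, intended_valid=False, defect=kind)
        if kind == "TOO_MANY_5P_SITES":
            profiles[pid] = {
                "sites": [(0, 0.39), (1, 0.295), (2, 0.295)],
                "star": 0.02,
            }
        elif kind == "LOW_PREDOMINANCE":
            profiles[pid] = {
                "sites": [
                    (0, 0.85),
                    (-2, 0.0325),
                    (-1, 0.0325),
                    (1, 0.0325),
                    (2, 0.0325),
                ],
                "star": 0.02,
            }
        precursors.append(p)

    genome, truth = plant_genome(precursors, spacer_len=spacer_len, rng_seed=rng_seed)
    truth.read_profiles = profiles

    valid_ids = [p.id for p in precursors if p.intended_valid]
    defect_ids = [p.id for p in precursors if not p.intended_valid]
    weights: dict[str, dict[str, float]] = {lib: {} for lib in libraries}
    shared = valid_ids[: max(1, int(0.6 * len(valid_ids)))]
    exclusive = valid_ids[len(shared) :]
    for i, pid in enumerate(valid_ids):
        w = float(np.clip(rng.lognormal(mean=0.0, sigma=1.5), 0.05, 12.0))
        if len(libraries) == 1 or pid in shared:
            for lib in libraries:
                weights[lib][pid] = w
        else:
            lib = list(libraries)[exclusive.index(pid) % len(libraries)]
            weights[lib][pid] = w
    for pid in defect_ids:
        for lib in libraries:
            weights[lib][pid] = 2.0
    truth.expression_weights = weights

    if plant_multimapper and valid_ids:
        embed_multimap_copy(genome, truth, valid_ids[0], spacer_index=0)
    return genome, truth
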