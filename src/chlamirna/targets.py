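"""miRNA target site prediction on transcripts.

The complementarity grammar, with miRNA positions numbered 1-based from
the 5' end:

* seed (positions 2-8): perfect Watson-Crick pairing required;
* catalytic center (positions 9-12): all-WC pairing licenses transcript
  cleavage; one to three mismatches/wobbles redirect the site to the
  translational-repression class (the two classes are disjoint);
* remainder (position 1 and 13..end): at most three G:U wobbles AND at
  most three mismatches, with at most a single 1-nt bulge on either
  strand, placed outside the seed and catalytic regions.

Sites are found by sliding windows of length L-1, L and L+1 over each
transcript (L = miRNA length); the scanner prescreens with the seed
7-mer and the brute-force window enumeration is kept as an independent
oracle in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import revcomp_rna, to_rna

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}

#: per-position pairing states
WC, GU, MM, GAP = "WC", "GU", "MM", "GAP"

SEED_POSITIONS = range(2, 9)  # 1-based, inclusive of 2..8
CATALYTIC_POSITIONS = range(9, 13)  # 1-based, 9..12


@dataclass
class DuplexAlignment:
    """Pairing states of a miRNA against one transcript window.

    ``states[k]`` is the state of miRNA position k+1 (1-based numbering
    from the miRNA 5' end); the window is given 5'->3' in transcript
    orientation and read antiparallel against the miRNA.
    """

    mirna_seq: str
    window_seq: str
    states: tuple[str, ...]
    gap_len: int
    gap_pos: int | None  # 1-based miRNA position of/next to the single gap


@dataclass(frozen=True)
class TargetSite:
    transcript_id: str
    start: int  # 0-based half-open window interval on the transcript
    end: int
    mirna_id: str
    site_class: str  # cleavage | translational
    wobbles_remainder: int
    mismatches_remainder: int
    catalytic_imperfections: int
    gap_len: int
    is_self: bool = False


def _state(m: str, t: str) -> str:
    if (m, t) in WC_PAIRS:
        return WC
    if (m, t) in GU_PAIRS:
        return GU
    return MM


def align_duplex(mirna: str, window: str) -> DuplexAlignment:
    """Deterministic antiparallel alignment of a miRNA against a window.

    Equal lengths give the ungapped position-wise states.  A length
    difference of one places the single bulge at the allowed position
    (outside seed and catalytic regions) minimizing first the mismatch
    count and then the position index.
    """
    m = to_rna(mirna)
    w = to_rna(window)
    lm, lw = len(m), len(w)
    if abs(lw - lm) > 1:
        raise ValueError(f"window/miRNA length difference {abs(lw - lm)} > 1")
    rw = w[::-1]  # rw[i] faces miRNA position i+1 in the ungapped case

    if lw == lm:
        states = tuple(_state(m[i], rw[i]) for i in range(lm))
        return DuplexAlignment(m, w, states, gap_len=0, gap_pos=None)

    if lw == lm + 1:
        # one unpaired target base, inserted after `g` paired miRNA
        # positions; choose g by mismatch count via prefix sums
        low = [_state(m[i], rw[i]) for i in range(lm)]  # used below the gap
        high = [_state(m[i], rw[i + 1]) for i in range(lm)]  # above the gap
        mm_low = [0]
        for s in low:
            mm_low.append(mm_low[-1] + (s == MM))
        mm_high = [0]
        for s in reversed(high):
            mm_high.append(mm_high[-1] + (s == MM))
        mm_high.reverse()
        best_g = min([1, *range(12, lm)], key=lambda g: (mm_low[g] + mm_high[g], g))
        states = tuple(low[:best_g] + high[best_g:])
        return DuplexAlignment(m, w, states, gap_len=1, gap_pos=best_g)

    # one unpaired miRNA position p (1-based), shown as a GAP state
    low = [_state(m[i], rw[i]) if i < lw else MM for i in range(lm)]
    high = [_state(m[i], rw[i - 1]) if i >= 1 else MM for i in range(lm)]
    mm_low = [0]
    for s in low:
        mm_low.append(mm_low[-1] + (s == MM))
    mm_high = [0]
    for s in reversed(high):
        mm_high.append(mm_high[-1] + (s == MM))
    mm_high.reverse()
    best_p = min(
        [1, *range(13, lm + 1)],
        key=lambda p: (mm_low[p - 1] + mm_high[p], p),
    )
    states = tuple(
        low[: best_p - 1] + [GAP] + high[best_p:]
    )
    return DuplexAlignment(m, w, states, gap_len=1, gap_pos=best_p)


def duplex_counts(d: DuplexAlignment) -> tuple[int, int, int]:
    """(wobbles_remainder, mismatches_remainder, catalytic_imperfections)."""
    remainder = [0] + list(range(12, len(d.states)))
    wob = sum(d.states[i] == GU for i in remainder)
    mm = sum(d.states[i] == MM for i in remainder)
    cat = sum(d.states[p - 1] in (MM, GU) for p in CATALYTIC_POSITIONS)
    return wob, mm, cat


def classify_duplex(
    d: DuplexAlignment,
    max_wobbles: int = 3,
    max_mismatches: int = 3,
    max_catalytic_imperfections: int = 3,
) -> str | None:
    """Classify a duplex as 'cleavage', 'translational', or None.

    The seed must pair perfectly; the remainder budgets are shared by both
    classes; catalytic perfection vs >=1 imperfection partitions the
    accepted duplexes into the two disjoint classes.
    """
    states = d.states
    if any(states[p - 1] != WC for p in SEED_POSITIONS):
        return None
    if d.gap_len > 1:
        return None
    wob, mm, cat = duplex_counts(d)
    if wob > max_wobbles or mm > max_mismatches:
        return None
    if any(states[p - 1] == GAP for p in CATALYTIC_POSITIONS):
        return None
    if cat == 0:
        return "cleavage"
    if cat <= max_catalytic_imperfections:
        return "translational"
    return None


def _candidate_windows(lm: int, t: int, tr_len: int):
    """Window (start, length) combos whose seed could sit at transcript pos t.

    The seed heptamer occupies window indices [Lw-7-a, Lw-a) where a is its
    offset in the reversed window (0, 1 or 2 depending on gap placement),
    so s = t - Lw + 7 + a.
    """
    for lw in (lm - 1, lm, lm + 1):
        for a in (0, 1, 2):
            s = t - lw + 7 + a
            if 0 <= s and s + lw <= tr_len:
                yield s, lw


def scan_transcriptome(
    mirnas: Iterable[tuple[str, str]],
    transcripts: Iterable[tuple[str, str]],
    precursor_of: Mapping[str, str] | None = None,
) -> list[TargetSite]:
    """Scan every transcript for classified binding sites of every miRNA.

    Duplicate alignments sharing the same (miRNA, transcript, window
    3'-end) are collapsed, keeping the fewest-mismatch alignment.  Sites
    falling on a miRNA's own precursor transcript (``precursor_of``) are
    flagged ``is_self``.
    """
    precursor_of = precursor_of or {}
    best: dict[tuple[str, str, int], tuple[tuple, TargetSite]] = {}
    transcripts = [(tid, to_rna(tseq)) for tid, tseq in transcripts]
    for mirna_id, mirna_seq in mirnas:
        m = to_rna(mirna_seq)
        lm = len(m)
        seed7 = revcomp_rna(m[1:8])
        for tid, tseq in transcripts:
            t = tseq.find(seed7)
            seen: set[tuple[int, int]] = set()
            while t != -1:
                for s, lw in _candidate_windows(lm, t, len(tseq)):
                    if (s, lw) in seen:
                        continue
                    seen.add((s, lw))
                    d = align_duplex(m, tseq[s : s + lw])
                    cls = classify_duplex(d)
                    if cls is None:
                        continue
                    wob, mm, cat = duplex_counts(d)
                    site = TargetSite(
                        transcript_id=tid,
                        start=s,
                        end=s + lw,
                        mirna_id=mirna_id,
                        site_class=cls,
                        wobbles_remainder=wob,
                        mismatches_remainder=mm,
                        catalytic_imperfections=cat,
                        gap_len=d.gap_len,
                        is_self=precursor_of.get(mirna_id) == tid,
                    )
                    # ungapped first: a bulge can masquerade as one fewer
                    # mismatch, but the ungapped window is the site itself
                    rank = (
                        d.gap_len,
                        sum(st == MM for st in d.states),
                        sum(st == GU for st in d.states),
                        s,
                    )
                    key = (mirna_id, tid, s + lw)
                    if key not in best or rank < best[key][0]:
                        best[key] = (rank, site)
                t = tseq.find(seed7, t + 1)
    sites = [site for _rank, site in best.values()]
    sites.sort(key=lambda s: (s.mirna_id, s.transcript_id, s.start, s.end))
    return sites


def sites_table(sites: Sequence[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": s.mirna_id,
                "transcript": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "class": s.site_class,
                "wobbles": s.wobbles_remainder,
                "mismatches": s.mismatches_remainder,
                "catalytic_imperfections": s.catalytic_imperfections,
                "gap_len": s.gap_len,
                "is_self": s.is_self,
            }
            for s in sites
        ],
        columns=[
            "mirna",
            "transcript",
            "start",
            "end",
            "class",
            "wobbles",
            "mismatches",
            "catalytic_imperfections",
            "gap_len",
            "is_self",
        ],
    )


def target_count_table(
    sites: Sequence[TargetSite], exclude_self: bool = True
) -> pd.DataFrame:
    """Distinct target transcripts per miRNA and class.

    With ``exclude_self``, sites on a miRNA's own precursor transcript do
    not count, and a miRNA whose every site was on its precursor ends up
    with zero targets and ``excluded=True`` — the flag also used for
    removing such miRNAs from expression-level comparisons.
    """
    per_mirna: dict[str, dict[str, set[str]]] = {}
    had_any: set[str] = set()
    for site in sites:
        had_any.add(site.mirna_id)
        if exclude_self and site.is_self:
            continue
        slot = per_mirna.setdefault(
            site.mirna_id, {"cleavage": set(), "translational": set()}
        )
        slot[site.site_class].add(site.transcript_id)
    rows = []
    for mirna_id in sorted(had_any):
        slot = per_mirna.get(mirna_id, {"cleavage": set(), "translational": set()})
        n_cleave = len(slot["cleavage"])
        n_trans = len(slot["translational"])
        rows.append(
            {
                "mirna": mirna_id,
                "cleavage": n_cleave,
                "translational": n_trans,
                "excluded": n_cleave + n_trans == 0,
            }
        )
    return pd.DataFrame(rows, columns=["mirna", "cleavage", "translational", "excluded"])
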