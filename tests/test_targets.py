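"""Duplex alignment, the site grammar, and the transcriptome scanner."""

import numpy as np
import pytest

from chlamirna.seqio import revcomp_rna
from chlamirna.targets import (
    GAP,
    GU,
    MM,
    WC,
    align_duplex,
    classify_duplex,
    duplex_counts,
    scan_transcriptome,
    target_count_table,
    TargetSite,
)

MIRNA = "ACGGUUAGCAUCGGAUCAACG"  # 21 nt
PERFECT = revcomp_rna(MIRNA)


def mutate(window, mirna, position, base):
    """Set the target base facing 1-based miRNA ``position``."""
    w = list(window)
    w[len(mirna) - position] = base
    return "".join(w)


def random_rna(rng, n):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=n))


class TestAlignDuplex:
    def test_perfect_complement_all_wc(self):
        d = align_duplex(MIRNA, PERFECT)
        assert set(d.states) == {WC}
        assert d.gap_len == 0

    def test_gu_wobble_state(self):
        # miRNA G at position 4 opposite target U
        assert MIRNA[3] == "G"
        d = align_duplex(MIRNA, mutate(PERFECT, MIRNA, 4, "U"))
        assert d.states[3] == GU

    def test_mismatch_state(self):
        d = align_duplex(MIRNA, mutate(PERFECT, MIRNA, 4, "G"))
        assert d.states[3] == MM

    def test_states_match_naive_recomputation(self, rng):
        # equal-length path against a direct per-position oracle
        for _ in range(200):
            m = random_rna(rng, 21)
            w = random_rna(rng, 21)
            d = align_duplex(m, w)
            rw = w[::-1]
            for i in range(21):
                pair = (m[i], rw[i])
                if pair in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
                    assert d.states[i] == WC
                elif pair in {("G", "U"), ("U", "G")}:
                    assert d.states[i] == GU
                else:
                    assert d.states[i] == MM

    def test_target_bulge_alignment(self):
        # insert a bulged-out target base between miRNA positions 14 and 15
        window = PERFECT[:6] + "A" + PERFECT[6:]
        d = align_duplex(MIRNA, window)
        assert d.gap_len == 1
        assert d.states.count(WC) == 21

    def test_mirna_gap_alignment(self):
        # delete the target base facing miRNA position 15
        window = PERFECT[:6] + PERFECT[7:]
        d = align_duplex(MIRNA, window)
        assert d.gap_len == 1
        assert d.states.count(GAP) == 1
        assert d.states.count(WC) == 20

    def test_length_difference_over_one_rejected(self):
        with pytest.raises(ValueError):
            align_duplex(MIRNA, PERFECT[:-2])


class TestClassifyDuplex:
    def test_perfect_complement_is_cleavage(self):
        assert classify_duplex(align_duplex(MIRNA, PERFECT)) == "cleavage"

    def test_catalytic_wobble_is_translational(self):
        # catalytic position 11 is a U in this miRNA: U:G is a wobble
        assert MIRNA[10] == "U"
        d = align_duplex(MIRNA, mutate(PERFECT, MIRNA, 11, "G"))
        assert d.states[10] == GU
        assert duplex_counts(d)[2] == 1
        assert classify_duplex(d) == "translational"

    def test_seed_mismatch_is_none(self):
        window = mutate(PERFECT, MIRNA, 5, MIRNA[4])  # same base never pairs
        assert classify_duplex(align_duplex(MIRNA, window)) is None

    def test_four_catalytic_imperfections_is_none(self):
        window = PERFECT
        for position in (9, 10, 11, 12):
            window = mutate(window, MIRNA, position, MIRNA[position - 1])
        assert classify_duplex(align_duplex(MIRNA, window)) is None

    def test_remainder_mismatch_budget_boundary(self):
        window = PERFECT
        for position in (14, 16, 18):  # three remainder mismatches: allowed
            window = mutate(window, MIRNA, position, MIRNA[position - 1])
        assert classify_duplex(align_duplex(MIRNA, window)) == "cleavage"
        window = mutate(window, MIRNA, 20, MIRNA[19])  # fourth: over budget
        assert classify_duplex(align_duplex(MIRNA, window)) is None

    def test_remainder_budget_monotonicity(self, rng):
        # relaxing the mismatch budget never removes a classified site
        for _ in range(200):
            d = align_duplex(random_rna(rng, 21), random_rna(rng, 21))
            tight = classify_duplex(d, max_mismatches=2)
            loose = classify_duplex(d, max_mismatches=3)
            if tight is not None:
                assert loose == tight

    def test_position_one_is_budgeted_not_required(self):
        window = mutate(PERFECT, MIRNA, 1, MIRNA[0])
        assert classify_duplex(align_duplex(MIRNA, window)) == "cleavage"


def brute_force_scan(mirnas, transcripts):
    """Independent oracle: enumerate every window x classify, then dedup
    by (miRNA, transcript, window 3'-end) with the scanner's ranking."""
    best = {}
    for mirna_id, m in mirnas:
        lm = len(m)
        for tid, t in transcripts:
            for lw in (lm - 1, lm, lm + 1):
                for s in range(0, len(t) - lw + 1):
                    d = align_duplex(m, t[s : s + lw])
                    cls = classify_duplex(d)
                    if cls is None:
                        continue
                    rank = (
                        d.gap_len,
                        sum(x == MM for x in d.states),
                        sum(x == GU for x in d.states),
                        s,
                    )
                    key = (mirna_id, tid, s + lw)
                    if key not in best or rank < best[key][0]:
                        best[key] = (rank, (s, s + lw, cls))
    return {key + value[1] for key, value in best.items()}


class TestScanTranscriptome:
    def test_reverse_complement_always_yields_cleavage(self, rng):
        for _ in range(10):
            m = random_rna(rng, 21)
            t = random_rna(rng, 80) + revcomp_rna(m) + random_rna(rng, 80)
            sites = scan_transcriptome([("m", m)], [("t", t)])
            assert any(s.site_class == "cleavage" for s in sites)

    def test_matches_brute_force_enumeration(self, rng):
        mirnas = [(f"m{i}", random_rna(rng, int(rng.integers(20, 23)))) for i in range(4)]
        transcripts = []
        for i in range(12):
            t = random_rna(rng, 300)
            if i % 2 == 0:  # ensure some true sites exist
                mid = mirnas[i % 4][1]
                t = t[:100] + revcomp_rna(mid) + t[100 + len(mid) :]
            transcripts.append((f"t{i}", t))
        got = {
            (s.mirna_id, s.transcript_id, s.end, s.start, s.end, s.site_class)
            for s in scan_transcriptome(mirnas, transcripts)
        }
        assert got == brute_force_scan(mirnas, transcripts)

    def test_self_target_flagging(self):
        transcripts = [("precursor_m", "AUC" + PERFECT + "GAU")]
        sites = scan_transcriptome(
            [("m", MIRNA)], transcripts, precursor_of={"m": "precursor_m"}
        )
        assert sites and all(s.is_self for s in sites)


class TestTargetCountTable:
    def _site(self, mirna, transcript, cls="cleavage", is_self=False, start=0):
        return TargetSite(
            transcript_id=transcript,
            start=start,
            end=start + 21,
            mirna_id=mirna,
            site_class=cls,
            wobbles_remainder=0,
            mismatches_remainder=0,
            catalytic_imperfections=0 if cls == "cleavage" else 1,
            gap_len=0,
            is_self=is_self,
        )

    def test_counts_distinct_transcripts(self):
        sites = [
            self._site("m1", "t1"),
            self._site("m1", "t1", start=50),  # second site, same transcript
            self._site("m1", "t2"),
            self._site("m1", "t3", cls="translational"),
        ]
        table = target_count_table(sites).set_index("mirna")
        assert table.loc["m1", "cleavage"] == 2
        assert table.loc["m1", "translational"] == 1
        assert not table.loc["m1", "excluded"]

    def test_self_only_mirna_flagged_excluded(self):
        sites = [self._site("m1", "precursor", is_self=True)]
        table = target_count_table(sites).set_index("mirna")
        assert table.loc["m1", "cleavage"] == 0
        assert bool(table.loc["m1", "excluded"])

    def test_self_counted_when_not_excluding(self):
        sites = [self._site("m1", "precursor", is_self=True)]
        table = target_count_table(sites, exclude_self=False).set_index("mirna")
        assert table.loc["m1", "cleavage"] == 1

    def test_empty_sites_empty_table(self):
        assert target_count_table([]).empty
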