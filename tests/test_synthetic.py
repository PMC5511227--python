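"""The planted-truth generator: precursors, genomes, reads, targets."""

import numpy as np
import pytest

from chlamirna import synthetic
from chlamirna.seqio import revcomp_rna, to_rna
from chlamirna.synthetic import (
    InvalidAlphabetError,
    benchmark_truth,
    make_precursor,
    plant_genome,
    plant_targets,
    simulate_reads,
    simulate_target_counts,
)


def hamming(a, b):
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


MATURE = "ACGGUUAGCAUCGGAUCAACG"


class TestMakePrecursor:
    def test_zero_mismatch_star_is_exact_reverse_complement(self):
        p = make_precursor(MATURE, loop_len=4, star_mismatches=0)
        star = to_rna(p.full_seq)[p.star_offset : p.star_offset + len(MATURE)]
        assert star == revcomp_rna(MATURE)
        assert p.intended_valid

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_star_differs_from_revcomp_at_exactly_k_positions(self, k):
        p = make_precursor(MATURE, star_mismatches=k, rng_seed=7)
        star = to_rna(p.full_seq)[p.star_offset : p.star_offset + len(MATURE)]
        assert hamming(star, revcomp_rna(MATURE)) == k

    def test_five_mismatches_not_intended_valid(self):
        p = make_precursor(MATURE, star_mismatches=5)
        assert not p.intended_valid
        assert p.defect == "STAR_MISMATCHES"

    def test_3p_arm_layout(self):
        p = make_precursor(MATURE, arm="3p", loop_len=5)
        assert p.mature_offset == len(MATURE) + 5
        assert p.star_offset == 0
        assert to_rna(p.full_seq)[p.mature_offset :] == MATURE

    def test_invalid_alphabet(self):
        with pytest.raises(InvalidAlphabetError):
            make_precursor("ACGTXACGTACGTACGTACGT")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mature_seq": "ACGU" * 3},  # too short
            {"mature_seq": MATURE, "loop_len": 2},
            {"mature_seq": MATURE, "star_mismatches": 40},
            {"mature_seq": MATURE, "arm": "mid"},
        ],
    )
    def test_preconditions(self, kwargs):
        with pytest.raises(ValueError):
            make_precursor(**kwargs)


class TestPlantGenome:
    def _precursors(self, n=3):
        rng = np.random.default_rng(1)
        return [
            make_precursor(
                synthetic._random_rna(rng, 21), rng_seed=i, precursor_id=f"p{i}"
            )
            for i in range(n)
        ]

    def test_length_arithmetic(self):
        pre = self._precursors(3)
        genome, truth = plant_genome(pre, spacer_len=500, rng_seed=0)
        expected = sum(p.length for p in pre) + 4 * 500
        assert len(genome["chr1"]) == expected

    def test_placements_match_sequences(self):
        pre = self._precursors(2)
        genome, truth = plant_genome(pre, spacer_len=300, rng_seed=0)
        for p in pre:
            chrom, start, end, strand = truth.placements[p.id]
            assert genome[chrom][start:end] == p.full_seq
            assert strand == "+"

    def test_spacer_precondition(self):
        with pytest.raises(ValueError):
            plant_genome(self._precursors(1), spacer_len=100)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            plant_genome([], spacer_len=500)

    def test_spacers_cannot_self_pair(self):
        genome, truth = plant_genome(self._precursors(1), spacer_len=400, rng_seed=3)
        s, e = truth.spacer_intervals[0]
        assert set(genome["chr1"][s:e]) <= {"A", "C"}


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(5)
    pre = [
        make_precursor(
            synthetic._random_rna(rng, 21),
            star_mismatches=1,
            rng_seed=i,
            precursor_id=f"p{i}",
        )
        for i in range(3)
    ]
    return plant_genome(pre, spacer_len=500, rng_seed=5)


class TestSimulateReads:
    def test_abundance_conservation_is_exact(self, planted):
        genome, truth = planted
        sims = simulate_reads(
            truth, genome, {"L1": 10_000}, background_fraction=0.25, rng_seed=2
        )
        assert sims["L1"].total_reads == 10_000

    def test_degenerate_noise_gives_only_mature_reads(self, planted):
        genome, truth = planted
        sims = simulate_reads(
            truth,
            genome,
            {"L1": 9_000},
            predominance=1.0,
            offset_jitter=0,
            background_fraction=0.0,
            star_fraction=0.0,
            rng_seed=2,
        )
        matures = {synthetic.to_dna(p.mature_seq) for p in truth.precursors}
        assert set(sims["L1"].counts) == matures

    def test_mapped_coordinates_recover_truth_exactly(self, planted):
        genome, truth = planted
        sims = simulate_reads(
            truth,
            genome,
            {"L1": 3_000},
            predominance=1.0,
            offset_jitter=0,
            background_fraction=0.0,
            star_fraction=0.0,
            rng_seed=2,
        )
        for read in sims["L1"].aligned:
            (chrom, start, end, strand) = read.loci[0]
            pid = next(
                pid
                for pid, p in ((p.id, p) for p in truth.precursors)
                if synthetic.to_dna(p.mature_seq) == read.seq
            )
            pchrom, pstart, _pe, _ = truth.placements[pid]
            mstart = pstart + truth.precursor(pid).mature_offset
            assert (chrom, start, end, strand) == (pchrom, mstart, mstart + 21, "+")

    def test_deterministic_outputs(self, planted, tmp_path):
        genome, truth = planted
        out = []
        for run in (1, 2):
            sims = simulate_reads(
                truth, genome, {"L1": 8_000}, background_fraction=0.3, rng_seed=9
            )
            d = tmp_path / f"run{run}"
            synthetic.write_library(sims["L1"], d)
            synthetic.write_truth(truth, d)
            out.append(
                tuple(
                    (f.name, f.read_bytes())
                    for f in sorted(d.iterdir())
                )
            )
        assert out[0] == out[1]

    def test_bad_predominance_rejected(self, planted):
        genome, truth = planted
        with pytest.raises(ValueError):
            simulate_reads(truth, genome, {"L1": 100}, predominance=1.5)


class TestPlantTargets:
    MIRNAS = [("mirA", "ACGGUUAGCAUCGGAUCAACG"), ("mirB", "UUGGCAUGCAAGCUAGGCAAU")]

    def test_cleavage_sites_classify_as_cleavage(self):
        from chlamirna.targets import scan_transcriptome

        transcripts, planted = plant_targets(self.MIRNAS, 2, "cleavage", rng_seed=4)
        sites = scan_transcriptome(self.MIRNAS, transcripts)
        found = {(s.transcript_id, s.start, s.end, s.site_class) for s in sites}
        for tid, (s, e), _mid, cls in planted:
            assert cls == "cleavage"
            assert (tid, s, e, "cleavage") in found

    def test_decoy_transcripts_have_zero_sites(self):
        from chlamirna.targets import scan_transcriptome

        transcripts, planted = plant_targets(self.MIRNAS, 3, "decoy", rng_seed=4)
        assert planted == []
        assert scan_transcriptome(self.MIRNAS, transcripts) == []

    def test_translational_single_wobble_at_position_10(self):
        from chlamirna.targets import align_duplex, classify_duplex

        # engineer the wobble by hand through the helper used by planting
        mirna = "ACGGUUAGCGUCGGAUCAACG"  # position 10 is G -> wobble exists
        window = list(revcomp_rna(mirna))
        synthetic._engineer_position(
            window, mirna, 10, "wobble", np.random.default_rng(0)
        )
        duplex = align_duplex(mirna, "".join(window))
        assert classify_duplex(duplex) == "translational"

    def test_truth_rows_cover_all_planted_windows(self):
        transcripts, planted = plant_targets(self.MIRNAS, 2, "translational", rng_seed=1)
        assert len(planted) == 4
        ids = {tid for tid, *_ in planted}
        assert ids == {tid for tid, _ in transcripts}


class TestTargetCountSimulation:
    def test_shapes_and_floor(self):
        low, high = simulate_target_counts(rng_seed=3)
        assert low.size == 47 and high.size == 18
        assert low.min() >= 1 and high.min() >= 1

    def test_deterministic(self):
        a = simulate_target_counts(rng_seed=3)
        b = simulate_target_counts(rng_seed=3)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()

    def test_group_means_near_configuration(self):
        # average over replicates approaches the configured group means
        lows, highs = [], []
        for seed in range(30):
            low, high = simulate_target_counts(rng_seed=seed)
            lows.append(low.mean())
            highs.append(high.mean())
        assert abs(np.mean(lows) - 5.11) < 0.5
        assert abs(np.mean(highs) - 1.78) < 0.2


class TestBenchmark:
    def test_composition(self, benchmark):
        truth = benchmark["truth"]
        valid = [p for p in truth.precursors if p.intended_valid]
        invalid = [p for p in truth.precursors if not p.intended_valid]
        assert len(valid) == 20 and len(invalid) == 10
        from collections import Counter

        assert Counter(p.defect for p in invalid) == Counter(
            {kind: 2 for kind in synthetic.DEFECT_KINDS}
        )

    def test_one_cluster_per_precursor(self, benchmark, calls_by_precursor):
        assert set(calls_by_precursor) == {
            p.id for p in benchmark["truth"].precursors
        }
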