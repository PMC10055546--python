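import numpy as np
import pandas as pd
import pytest

from remodelseq.intervals import PeakSet
from remodelseq.motifs import MotifPattern, scan_iupac
from remodelseq.signal import count_in_windows
from remodelseq.simulate import (LocusArchetype, default_archetypes,
                                 generate_genome, plant_loci, simulate_atac,
                                 simulate_chip, simulate_expression,
                                 simulate_mnase, simulate_null_counts, TruthTable)


class TestGenerateGenome:
    def test_gc_content_within_3se(self):
        n = 1_000_000
        g = generate_genome(1, n, gc=0.5, seed=3)["chr1"]
        gc = sum(g.count(b) for b in "GC") / n
        se = np.sqrt(0.25 / n)
        assert abs(gc - 0.5) <= 3 * se

    def test_same_seed_identical_sequence(self):
        assert generate_genome(2, 10_000, seed=7) == generate_genome(2, 10_000, seed=7)

    def test_gc_zero_is_all_at(self):
        g = generate_genome(1, 5000, gc=0.0, seed=1)["chr1"]
        assert set(g) <= {"A", "T"}

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(1, 100, gc=1.5)


class TestPlantLoci:
    def test_zero_loci_leaves_genome_unchanged(self):
        g = generate_genome(1, 50_000, seed=5)
        g2, truth = plant_loci(dict(g), 0, seed=5)
        assert g2 == g and len(truth) == 0

    def test_planted_motifs_rescanned_at_recorded_coordinates(self, small_truth):
        genome, truth = small_truth
        for r in truth.df.itertuples(index=False):
            window = genome[r.chrom][r.motif_start:r.motif_end]
            pat = MotifPattern(r.motif_name, r.motif_iupac)
            assert len(scan_iupac(window, pat, both_strands=False)) == 1

    def test_pairwise_separation_respected(self, small_truth):
        _, truth = small_truth
        for chrom, grp in truth.df.groupby("chrom"):
            centers = np.sort(grp["center"].to_numpy())
            assert (np.diff(centers) >= 5000).all()

    def test_insufficient_space_errors(self):
        g = generate_genome(1, 30_000, seed=1)
        with pytest.raises(ValueError):
            plant_loci(g, 500, seed=1)

    def test_truth_round_trips_through_tsv(self, small_truth, tmp_path):
        _, truth = small_truth
        p = tmp_path / "truth.tsv"
        truth.to_tsv(p)
        back = TruthTable.from_tsv(p)
        assert back.chrom_sizes == truth.chrom_sizes
        pd.testing.assert_frame_equal(back.df, truth.df, check_dtype=False)


class TestSimulateAtac:
    def test_poisson_limit_counts_match_programmed_means(self, small_truth):
        _, truth = small_truth
        reps = simulate_atac(truth, "control", "t12", replicates=1,
                             dispersion=0.0, background_density=0.0, seed=21)
        arch = {a.name: a for a in default_archetypes()}
        counts = count_in_windows(reps[0], truth.peaks(), 200, "midpoint")
        for name, grp in truth.df.groupby("archetype"):
            mean = counts[grp.index.to_numpy()].mean()
            expect = arch[name].atac_rate_t12
            se = np.sqrt(expect / len(grp))
            assert abs(mean - expect) <= max(4 * se, 0.02 * expect)

    def test_kd_multiplier_raises_inaccessible_t12_rate(self, small_truth):
        _, truth = small_truth
        inacc = truth.df["archetype"] == "constitutively_inaccessible"
        ctrl = simulate_atac(truth, "control", "t12", replicates=1,
                             dispersion=0.0, background_density=0.0, seed=30)[0]
        kd = simulate_atac(truth, "kd", "t12", replicates=1,
                           dispersion=0.0, background_density=0.0, seed=30)[0]
        peaks = truth.peaks()
        c = count_in_windows(ctrl, peaks, 200)[inacc.to_numpy()].mean()
        k = count_in_windows(kd, peaks, 200)[inacc.to_numpy()].mean()
        mult = default_archetypes()[2].atac_kd_t12_multiplier
        assert k / c == pytest.approx(mult, rel=0.2)

    def test_same_seed_byte_identical(self, small_truth):
        _, truth = small_truth
        a = simulate_atac(truth, "control", "t0", replicates=2, seed=9)
        b = simulate_atac(truth, "control", "t0", replicates=2, seed=9)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.fragments, y.fragments)

    def test_rejects_unknown_condition(self, small_truth):
        _, truth = small_truth
        with pytest.raises(ValueError):
            simulate_atac(truth, "mystery", "t12")


class TestSimulateMnase:
    def test_zero_jitter_no_background_midpoints_exactly_on_dyads(self, small_truth):
        _, truth = small_truth
        frags = simulate_mnase(truth, "control", "t12", jitter_sd_bp=0.0,
                               background_density=0.0, seed=41)
        programmed = set()
        for locus in truth.dyads("control", "t12"):
            programmed.update(p for p, occ in locus)
        assert len(frags) > 0
        assert set(frags.midpoints()) <= programmed

    def test_kd_moves_dyad_mass_off_motif_at_inaccessible_loci(self, small_truth):
        _, truth = small_truth
        inacc = truth.subset("constitutively_inaccessible")
        anchors = PeakSet(inacc.peaks(halfwidth_bp=40).intervals)  # motif-core window
        ctrl = simulate_mnase(truth, "control", "t12", seed=42)
        kd = simulate_mnase(truth, "kd", "t12", seed=43)
        c = count_in_windows(ctrl, anchors, 40, "midpoint").sum()
        k = count_in_windows(kd, anchors, 40, "midpoint").sum()
        assert k < c  # central dyad mass decreases under knockdown


class TestSimulateChip:
    def test_true_peaks_recovered_by_coverage_threshold(self, small_truth):
        _, truth = small_truth
        chip, peaks = simulate_chip(truth, scanning_weight=0.0,
                                    background_density=0.002, seed=51)
        assert len(peaks) > 0
        cov = count_in_windows(chip, peaks, 150)
        bg_per_window = 0.002 * (300 + 200)  # density x (window + frag length)
        assert (cov > 5 * bg_per_window).mean() > 0.95

    def test_zero_scanning_weight_leaves_unbound_loci_at_background(self, small_truth):
        _, truth = small_truth
        chip, peaks = simulate_chip(truth, scanning_weight=0.0,
                                    background_density=0.0, seed=52)
        unbound = truth.peaks(halfwidth_bp=100)
        from remodelseq.intervals import overlap_peaks
        _, unbound_only, _, _ = overlap_peaks(unbound, peaks)
        cov = count_in_windows(chip, unbound_only, 100)
        assert cov.sum() == 0


class TestSimulateExpression:
    def test_zero_noise_reproduces_coupling_exactly(self, small_truth):
        _, truth = small_truth
        expr = simulate_expression(truth, noise_sd=0.0, seed=1)
        expect = truth.df.set_index("gene_id")["gene_log2fc_true"]
        assert np.allclose(expr[expect.index], expect)

    def test_archetype_medians_ordered_by_coupling(self, small_truth):
        _, truth = small_truth
        expr = simulate_expression(truth, noise_sd=0.3, seed=2)
        med = {name: np.median(expr[grp["gene_id"]])
               for name, grp in truth.df.groupby("archetype")}
        assert med["newly_accessible"] > med["constitutively_accessible"]

    def test_permuted_gene_labels_destroy_coupling(self, small_truth, rng):
        _, truth = small_truth
        expr = simulate_expression(truth, noise_sd=0.1, seed=3)
        permuted = pd.Series(rng.permutation(expr.to_numpy()), index=expr.index)

        def spread(series):
            med = [np.median(series[grp["gene_id"]])
                   for _, grp in truth.df.groupby("archetype")]
            return max(med) - min(med)

        assert spread(permuted) < 0.5 * spread(expr)


class TestNullCounts:
    def test_shapes_and_determinism(self):
        a, b, la, lb = simulate_null_counts(100, 3, seed=4)
        a2, b2, *_ = simulate_null_counts(100, 3, seed=4)
        assert a.shape == (100, 3) and b.shape == (100, 3)
        assert np.array_equal(a, a2) and np.array_equal(b, b2)


class TestArchetypeValidation:
    def test_occupancy_bounds_enforced(self):
        with pytest.raises(ValueError):
            LocusArchetype("x", "newly_accessible", array_occupancy_control=1.5)

    def test_spacing_must_exceed_fragment_lengths(self):
        with pytest.raises(ValueError):
            LocusArchetype("x", "newly_accessible", array_spacing_bp=150)
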