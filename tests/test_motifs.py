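import itertools
import math

import numpy as np
import pandas as pd
import pytest

from remodelseq.intervals import GenomicInterval, PeakSet
from remodelseq.motifs import (MotifPattern, build_potential_sites,
                               expected_motif_rate, motif_enrichment,
                               sample_random_regions, scan_iupac,
                               scanning_enrichment, MotifHitSet)
from remodelseq.signal import FragmentSet

WGATAR = MotifPattern("GATA", "WGATAR")
AP1 = MotifPattern("AP1", "TGASTCA")

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s):
    return "".join(COMP[b] for b in reversed(s))


def brute_scan(seq, pattern, both_strands=True):
    """O(n*k) positional check, the independent oracle for scan_iupac."""
    hits = []
    pats = [(pattern, "+")]
    if both_strands:
        pats.append((pattern.reverse_complement(), "-"))
    k = len(pattern)
    for pat, strand in pats:
        for i in range(len(seq) - k + 1):
            window = seq[i:i + k]
            ok = all(
                (b in allowed) or (b == "N" and len(allowed) == 4)
                for b, allowed in zip(window, pat.positions)
            )
            if ok:
                hits.append((i, strand))
    return sorted(hits)


class TestMotifPattern:
    def test_invalid_iupac_letter_rejected(self):
        with pytest.raises(ValueError):
            MotifPattern("bad", "WGXTAR")
        with pytest.raises(ValueError):
            MotifPattern("empty", "")

    def test_reverse_complement_of_wgatar(self):
        assert WGATAR.reverse_complement().iupac == "YTATCW"


class TestScanIupac:
    def test_palindromic_motif_hits_both_strands(self):
        hits = scan_iupac("TGACTCA", AP1, both_strands=True)
        assert len(hits) == 2
        assert {iv.strand for iv in hits.hits} == {"+", "-"}
        assert all((iv.start, iv.end) == (0, 7) for iv in hits.hits)

    def test_forward_only_wgatar(self):
        hits = scan_iupac("AGATAA", WGATAR, both_strands=False)
        assert len(hits) == 1
        assert (hits.hits[0].start, hits.hits[0].end) == (0, 6)

    def test_sequence_n_never_matches_specific_position(self):
        assert len(scan_iupac("AGATNA", WGATAR, both_strands=False)) == 0
        # but N in sequence matches an N pattern position
        patN = MotifPattern("x", "AGNT")
        assert len(scan_iupac("AGNT", patN, both_strands=False)) == 1

    def test_matches_brute_force_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 30_000))
        for pat in (WGATAR, AP1):
            got = sorted((iv.start, iv.strand) for iv in scan_iupac(seq, pat).hits)
            assert got == brute_scan(seq, pat)

    def test_revcomp_sequence_mirrors_hit_coordinates(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 5000))
        fwd = scan_iupac(seq, WGATAR)
        rev = scan_iupac(revcomp(seq), WGATAR)
        n, k = len(seq), len(WGATAR)
        mirrored = sorted((n - iv.end, {"+": "-", "-": "+"}[iv.strand])
                          for iv in rev.hits)
        assert mirrored == sorted((iv.start, iv.strand) for iv in fwd.hits)


class TestExpectedMotifRate:
    def test_wgatar_both_strands_spacing_512(self):
        rate, spacing = expected_motif_rate(WGATAR)
        assert rate == pytest.approx(1 / 512)
        assert spacing == pytest.approx(512.0)

    def test_wgatar_verified_by_hexamer_enumeration(self):
        fwd = sum(WGATAR.matches("".join(k))
                  for k in itertools.product("ACGT", repeat=6))
        rc = WGATAR.reverse_complement()
        rev = sum(rc.matches("".join(k))
                  for k in itertools.product("ACGT", repeat=6))
        assert fwd == 4 and rev == 4
        rate, _ = expected_motif_rate(WGATAR)
        assert rate == pytest.approx((fwd + rev) / 4**6)

    def test_fully_degenerate_and_ap1_rates(self):
        assert expected_motif_rate(MotifPattern("n", "N"), both_strands=False) == (1.0, 1.0)
        rate, spacing = expected_motif_rate(AP1)
        assert spacing == pytest.approx(4096.0)

    def test_zero_probability_base_flags_infinite_spacing(self):
        with pytest.warns(UserWarning):
            rate, spacing = expected_motif_rate(
                MotifPattern("g", "G"), {"A": 0.5, "C": 0.0, "G": 0.0, "T": 0.5},
                both_strands=False)
        assert rate == 0.0 and math.isinf(spacing)

    def test_empirical_rate_matches_analytic_within_3se(self):
        rng = np.random.default_rng(42)
        n = 300_000
        seq = "".join(rng.choice(list("ACGT"), n))
        rate, _ = expected_motif_rate(WGATAR)
        hits = len(scan_iupac(seq, WGATAR))
        expect = rate * (n - len(WGATAR) + 1)
        se = math.sqrt(expect)  # Poisson-scale error for rare hits
        assert abs(hits - expect) <= 3 * se


def hitset(positions, chrom="chr1", pattern=WGATAR):
    k = len(pattern)
    return MotifHitSet(
        PeakSet([GenomicInterval(chrom, p, p + k, strand="+", name=pattern.name)
                 for p in positions]),
        pattern,
    )


class TestBuildPotentialSites:
    def test_mutually_overlapping_pair_both_removed(self):
        sites = build_potential_sites(hitset([1000, 1150]), PeakSet(), 200)
        assert len(sites) == 0

    def test_isolated_hit_retained_at_requested_width(self):
        sites = build_potential_sites(hitset([10_000]), PeakSet(), 200)
        assert len(sites) == 1 and sites[0].length == 200

    def test_hit_overlapping_observed_peak_removed(self):
        peaks = PeakSet([GenomicInterval("chr1", 9950, 10_050)])
        assert len(build_potential_sites(hitset([10_000]), peaks, 200)) == 0

    def test_matches_brute_force_three_rule_filter(self, rng):
        positions = sorted(int(p) for p in rng.integers(500, 100_000, 60))
        peaks = PeakSet([GenomicInterval("chr1", int(s), int(s) + 300)
                         for s in rng.integers(0, 100_000, 15)])
        got = build_potential_sites(hitset(positions), peaks, 200)
        # oracle: apply the three rules literally
        k = len(WGATAR)
        ext = [(p + k // 2 - 100, p + k // 2 + 100) for p in positions]
        ext = sorted(set(ext))
        keep = []
        for i, (s, e) in enumerate(ext):
            clash = any(ss < e and se > s for j, (ss, se) in enumerate(ext) if j != i)
            over_peak = any(iv.start < e and iv.end > s for iv in peaks)
            if not clash and not over_peak:
                keep.append((s, e))
        assert sorted((iv.start, iv.end) for iv in got) == keep

    def test_output_never_overlaps_itself_or_peaks(self, rng):
        positions = sorted(int(p) for p in rng.integers(0, 50_000, 100))
        peaks = PeakSet([GenomicInterval("chr1", int(s), int(s) + 250)
                         for s in rng.integers(0, 50_000, 10)])
        got = build_potential_sites(hitset(positions), peaks, 200)
        ivs = list(got)
        for i, a in enumerate(ivs):
            assert not any(a.overlaps(b) for b in ivs[i + 1:])
            assert not any(a.overlaps(p) for p in peaks)


class TestSampleRandomRegions:
    SIZES = {"chr1": 100_000, "chr2": 50_000}

    def test_zero_regions_empty(self):
        assert len(sample_random_regions(self.SIZES, 0, 200, PeakSet(), 1)) == 0

    def test_whole_genome_excluded_errors(self):
        exclude = PeakSet([GenomicInterval("chr1", 0, 100_000),
                           GenomicInterval("chr2", 0, 50_000)])
        with pytest.raises(ValueError):
            sample_random_regions(self.SIZES, 10, 200, exclude, 1)

    def test_never_intersects_exclusions_and_is_reproducible(self, rng):
        exclude = PeakSet([GenomicInterval("chr1", int(s), int(s) + 1000)
                           for s in rng.integers(0, 99_000, 30)])
        r1 = sample_random_regions(self.SIZES, 50, 200, exclude, seed=9)
        r2 = sample_random_regions(self.SIZES, 50, 200, exclude, seed=9)
        assert [(iv.chrom, iv.start) for iv in r1] == [(iv.chrom, iv.start) for iv in r2]
        for iv in r1:
            assert iv.length == 200
            assert not any(iv.overlaps(e) for e in exclude)


def chip_like(positions, n_per_site, chrom="chr1", lib=int(1e6), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in positions:
        for _ in range(n_per_site):
            mid = p + int(rng.normal(0, 30))
            rows.append((chrom, mid - 100, mid + 100))
    return FragmentSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                       library_size=lib)


class TestScanningEnrichment:
    def test_planted_signal_detected(self, rng):
        cand = PeakSet([GenomicInterval("chr1", int(p) - 100, int(p) + 100)
                        for p in range(5000, 105_000, 2000)])
        ctrl = PeakSet([GenomicInterval("chr1", int(p) - 100, int(p) + 100)
                        for p in range(6000, 106_000, 2000)])
        chip = chip_like([iv.center for iv in cand], 5)
        res = scanning_enrichment(chip, cand, ctrl, 500, 25)
        assert res.pvalue < 0.05
        assert res.candidate_counts.mean() > res.control_counts.mean()

    def test_identical_locus_sets_give_p_one(self):
        cand = PeakSet([GenomicInterval("chr1", p, p + 200)
                        for p in range(1000, 50_000, 3000)])
        chip = chip_like([iv.center for iv in cand], 3)
        res = scanning_enrichment(chip, cand, cand, 500, 25)
        assert res.pvalue == pytest.approx(1.0)

    def test_label_swap_keeps_p_value(self):
        cand = PeakSet([GenomicInterval("chr1", p, p + 200)
                        for p in range(1000, 60_000, 2500)])
        ctrl = PeakSet([GenomicInterval("chr1", p + 700, p + 900)
                        for p in range(1000, 60_000, 2500)])
        chip = chip_like([iv.center for iv in cand], 4)
        r1 = scanning_enrichment(chip, cand, ctrl, 400, 25)
        r2 = scanning_enrichment(chip, ctrl, cand, 400, 25)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_all_zero_counts_warn_p_one(self):
        cand = PeakSet([GenomicInterval("chr1", 1000, 1200)])
        ctrl = PeakSet([GenomicInterval("chr1", 5000, 5200)])
        chip = FragmentSet(pd.DataFrame({"chrom": ["chr2"], "start": [0],
                                         "end": [100]}), library_size=1000)
        with pytest.warns(UserWarning):
            res = scanning_enrichment(chip, cand, ctrl, 200, 25)
        assert res.pvalue == 1.0


class TestMotifEnrichment:
    @staticmethod
    def genome_with_planted(rng, n_regions=60, width=200, frac_with=0.8):
        seq = "".join(rng.choice(list("ACGT"), 200_000))
        seq = seq.replace("GATA", "CCCC")  # suppress background GATA cores
        regions, has = [], []
        arr = list(seq)
        for i in range(n_regions):
            s = 1000 + i * 3000
            if rng.random() < frac_with:
                arr[s + 50:s + 56] = list("AGATAA")
                has.append(True)
            else:
                has.append(False)
            regions.append(GenomicInterval("chr1", s, s + width))
        return {"chr1": "".join(arr)}, PeakSet(regions), has

    def test_planted_pattern_enriched(self, rng):
        genome, peaks, has = self.genome_with_planted(rng)
        background = PeakSet([GenomicInterval("chr1", 1500 + i * 3000, 1700 + i * 3000)
                              for i in range(60)])
        res = motif_enrichment(peaks, [WGATAR], genome, background)
        row = res.iloc[0]
        assert row["odds_ratio"] > 1
        assert row["fdr"] < 0.05

    def test_absent_pattern_reported_na(self):
        genome = {"chr1": "C" * 5000}
        peaks = PeakSet([GenomicInterval("chr1", 0, 200)])
        bg = PeakSet([GenomicInterval("chr1", 1000, 1200)])
        res = motif_enrichment(peaks, [WGATAR], genome, bg)
        assert np.isnan(res.iloc[0]["odds_ratio"])
        assert res.iloc[0]["pvalue"] == 1.0

    def test_peaks_equal_background_odds_near_one(self, rng):
        genome, peaks, _ = self.genome_with_planted(rng, frac_with=0.5)
        res = motif_enrichment(peaks, [WGATAR], genome, peaks)
        assert res.iloc[0]["odds_ratio"] == pytest.approx(1.0)
        assert res.iloc[0]["pvalue"] == pytest.approx(1.0)

    def test_empty_background_errors(self):
        genome = {"chr1": "A" * 1000}
        peaks = PeakSet([GenomicInterval("chr1", 0, 100)])
        with pytest.raises(ValueError):
            motif_enrichment(peaks, [WGATAR], genome, PeakSet())
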