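import numpy as np
import pandas as pd
import pytest

from hzkit.extent import PEMat, PERCENTILE_LEVELS, ExtAucTrack
from hzkit.peaks import (
    GeneticMap,
    Peak,
    cross_population_rank,
    detect_fixed_areas,
    detect_peaks,
    flag_outlier_peaks,
    merge_outlier_regions,
    merge_peaks,
    peak_haplotype_params,
    peak_recombination,
    smooth_track,
)


def mk_peak(height, v_lo, v_hi, lo=0, apex=5, hi=10, pop="A", chrom="1"):
    return Peak(population=pop, chromosome=chrom, apex_idx=apex,
                low_valley_idx=lo, high_valley_idx=hi,
                apex_bp=apex * 1000, low_valley_bp=lo * 1000,
                high_valley_bp=hi * 1000, height=height,
                low_valley_val=v_lo, high_valley_val=v_hi,
                snp_count=hi - lo + 1)


def chain(heights, valleys):
    """Adjacent peaks sharing valleys: len(valleys) = len(heights) - 1."""
    out = []
    lo_val = 0.0
    pos = 0
    for i, h in enumerate(heights):
        v_hi = valleys[i] if i < len(valleys) else 0.0
        out.append(mk_peak(h, lo_val, v_hi, lo=pos, apex=pos + 5, hi=pos + 10))
        lo_val = v_hi
        pos += 10
    return out


class TestSmoothing:
    def test_constant_track(self):
        x = np.arange(100) * 1000.0
        sm, dv = smooth_track(np.full(100, 3.5), x)
        np.testing.assert_allclose(sm, 3.5, rtol=1e-9)
        assert np.max(np.abs(dv)) < 1e-9

    def test_gaussian_bump_single_sign_change(self):
        # bump width comfortably above the knot spacing (3% of loci)
        x = np.linspace(0, 1, 400)
        y = np.exp(-((x - 0.5) ** 2) / 0.05)
        sm, dv = smooth_track(y, x)
        sgn = np.sign(dv)
        changes = np.sum(np.abs(np.diff(sgn)) > 1)
        assert changes == 1  # one + -> - crossing

    def test_sine_extrema_within_one_locus(self):
        x = np.linspace(0, 4 * np.pi, 600)
        y = np.sin(x)
        sm, dv = smooth_track(y, x)
        pk = detect_peaks(sm, dv, x)
        analytic = [np.pi / 2, 2.5 * np.pi]
        dx = x[1] - x[0]
        assert len(pk) == 2
        for p, a in zip(pk, analytic):
            assert abs(x[p.apex_idx] - a) <= 1.5 * dx

    def test_too_few_loci(self):
        with pytest.raises(ValueError, match="merge"):
            smooth_track(np.zeros(20), np.arange(20.0))


class TestDetectPeaks:
    def test_monotone_no_peaks(self):
        x = np.arange(50.0)
        assert detect_peaks(x, np.ones(50), x) == []

    def test_two_bumps_shared_valley(self):
        x = np.linspace(0, 1, 400)
        y = np.exp(-((x - 0.3) ** 2) / 0.01) + 0.8 * np.exp(-((x - 0.7) ** 2) / 0.01)
        sm, dv = smooth_track(y, x)
        pk = detect_peaks(sm, dv, x)
        assert len(pk) == 2
        assert pk[0].high_valley_idx == pk[1].low_valley_idx

    def test_apexes_match_bruteforce_local_maxima(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 1, 400)
        y = np.zeros(400)
        for c in rng.uniform(0.1, 0.9, 5):
            y += rng.uniform(0.5, 1.5) * np.exp(-((x - c) ** 2) / 0.002)
        sm, dv = smooth_track(y, x)
        pk = detect_peaks(sm, dv, x)
        brute = [i for i in range(1, 399)
                 if sm[i] > sm[i - 1] and sm[i] >= sm[i + 1]]
        assert sorted(p.apex_idx for p in pk) == brute


class TestMergePeaks:
    def test_similar_peaks_shallow_valley_merge(self):
        peaks = chain([1.00, 0.95], [0.93])
        merged = merge_peaks(peaks)
        assert len(merged) == 1
        assert merged[0].height == 1.00
        assert merged[0].low_valley_idx == 0
        assert merged[0].high_valley_idx == 20

    def test_deep_valley_blocks_merge(self):
        assert len(merge_peaks(chain([1.00, 0.95], [0.80]))) == 2

    def test_dissimilar_heights_block_merge(self):
        assert len(merge_peaks(chain([1.00, 0.80], [0.99]))) == 2

    def test_single_peak_identity(self):
        peaks = chain([1.0], [])
        assert merge_peaks(peaks) == peaks

    def test_fixpoint_reached_chain(self):
        # chain of near-equal peaks collapses fully in bounded iterations
        merged = merge_peaks(chain([1.0, 0.99, 0.98, 0.97],
                                   [0.99, 0.98, 0.97]))
        assert len(merged) == 1


class TestOutliers:
    def test_boxplot_outlier_flagged(self):
        peaks = chain([1, 1, 1, 1, 10], [0] * 4)
        flag_outlier_peaks(peaks)
        assert [p.outlier for p in peaks] == [False] * 4 + [True]

    def test_all_equal_none_flagged(self):
        peaks = chain([2.0] * 5, [0] * 4)
        flag_outlier_peaks(peaks)
        assert not any(p.outlier for p in peaks)

    def test_fewer_than_four_peaks_no_outliers(self):
        peaks = chain([1.0, 100.0], [0.0])
        flag_outlier_peaks(peaks)
        assert not any(p.outlier for p in peaks)

    def test_matches_independent_quartile_oracle(self):
        from oracles import quantile_type7

        rng = np.random.default_rng(44)
        heights = rng.uniform(0, 5, 30)
        peaks = chain(list(heights), [0.0] * 29)
        flag_outlier_peaks(peaks)
        q1 = quantile_type7(heights, 0.25)
        q3 = quantile_type7(heights, 0.75)
        thr = q3 + 1.5 * (q3 - q1)
        assert [p.outlier for p in peaks] == [h > thr for h in heights]


class TestOutlierRegions:
    def test_shallow_separation_merges(self):
        a, b = chain([1.0, 0.9], [0.6])
        regions = merge_outlier_regions([a, b])
        assert len(regions) == 1 and len(regions[0].members) == 2

    def test_clear_separation_keeps_apart(self):
        a, b = chain([1.0, 0.9], [0.3])
        regions = merge_outlier_regions([a, b])
        assert len(regions) == 2

    def test_isolated_outlier_singleton_region(self):
        (a,) = chain([1.0], [])
        regions = merge_outlier_regions([a])
        assert len(regions) == 1 and regions[0].members == [a]


def mk_pemat(values):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return PEMat(values, "A", "cM", np.array(["1"] * n),
                 np.arange(1, n + 1) * 1000)


class TestHaplotypeParams:
    def test_grid_example(self):
        # one locus offering (0.1, 0.9), (0.5, 0.5), (1.0, 0.2):
        # products 0.09 / 0.25 / 0.20 -> Extent_min 0.5, p_max 0.5
        row = np.zeros(101)
        row[10] = 0.1   # Pr = 0.90
        row[50] = 0.5   # Pr = 0.50
        row[80] = 1.0   # Pr = 0.20
        pm = mk_pemat(np.tile(row, (3, 1)))
        p = mk_peak(1.0, 0, 0, lo=0, apex=1, hi=2)
        peak_haplotype_params(p, pm)
        assert p.extent_min == pytest.approx(0.5)
        assert p.p_max == pytest.approx(0.5)
        assert p.freq_hap_exp == pytest.approx(np.sqrt(0.5))

    def test_fixed_region_pmax_one(self):
        values = np.tile(np.full(101, 2.0), (3, 1))  # extent 2 at all levels
        pm = mk_pemat(values)
        p = mk_peak(1.0, 0, 0, lo=0, apex=1, hi=2)
        peak_haplotype_params(p, pm)
        assert p.p_max == pytest.approx(1.0)
        assert p.freq_hap_exp == pytest.approx(1.0)

    def test_maximality_over_grid(self):
        rng = np.random.default_rng(50)
        values = np.sort(rng.uniform(0, 3, size=(5, 101)), axis=1)
        pm = mk_pemat(values)
        p = mk_peak(1.0, 0, 0, lo=0, apex=2, hi=4)
        peak_haplotype_params(p, pm)
        best = p.extent_min * p.p_max
        pr = 1 - PERCENTILE_LEVELS
        assert best >= np.max(values * pr[None, :]) - 1e-12

    def test_no_qualifying_segment_freq_zero(self):
        pm = mk_pemat(np.tile(np.linspace(0, 1, 101), (3, 1)))
        p = mk_peak(1.0, 0, 0, lo=0, apex=1, hi=2)
        peak_haplotype_params(p, pm, segments=[])
        assert p.freq_hap_max == 0.0


class TestCrossPopulationRank:
    def _track(self, rank):
        n = len(rank)
        t = ExtAucTrack("X", np.zeros(n), np.array(["1"] * n),
                        np.arange(1, n + 1) * 1000)
        t.rank = np.asarray(rank, dtype=float)
        return t

    def test_global_maximum_inside_peak(self):
        tracks = {"A": self._track([0.1, 0.5, 1.0, 0.3, 0.2])}
        p = mk_peak(1.0, 0, 0, lo=1, apex=2, hi=3, pop="A")
        cross_population_rank(p, tracks)
        assert p.rank_self == 1.0

    def test_identical_tracks_identical_ranks(self):
        r = [0.2, 0.8, 0.4]
        tracks = {"A": self._track(r), "B": self._track(r)}
        p = mk_peak(1.0, 0, 0, lo=0, apex=1, hi=2, pop="A")
        cross_population_rank(p, tracks)
        assert p.rank_self == p.rank_other["B"] == 0.8

    def test_windowed_max_oracle(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(0, 1, 40)
        tracks = {"A": self._track(r)}
        p = mk_peak(1.0, 0, 0, lo=7, apex=15, hi=23, pop="A")
        cross_population_rank(p, tracks)
        assert p.rank_self == pytest.approx(r[7:24].max())


class TestFixedAreas:
    def test_runs_of_nonzero_zeroth_percentile(self):
        values = np.zeros((5, 101))
        values[1, 0] = 5.0
        values[2, 0] = 5.0
        values[4, 0] = 7.0
        runs, _ = detect_fixed_areas(mk_pemat(values))
        assert [(r.start_idx, r.end_idx) for r in runs] == [(1, 2), (4, 4)]
        assert runs[0].snp_count == 2 and runs[1].extent == 7.0

    def test_all_zero_none(self):
        runs, cand = detect_fixed_areas(mk_pemat(np.zeros((4, 101))))
        assert runs == [] and cand == []

    def test_candidates_exceed_first_quartiles(self):
        values = np.zeros((30, 101))
        values[0:2, 0] = 1.0          # short, small extent
        values[5:7, 0] = 1.0
        values[10:12, 0] = 1.0
        values[20:28, 0] = 9.0        # long, large extent
        runs, cand = detect_fixed_areas(mk_pemat(values))
        assert len(runs) == 4
        assert [(r.start_idx, r.end_idx) for r in cand] == [(20, 27)]


class TestRecombination:
    def _uniform_map(self, rate=1.0, end=10_000_000):
        pos = np.array([1.0, end])
        return GeneticMap(pos, np.array([0.0, rate * (end - 1) / 1e6]))

    def _track(self, n=100):
        v = np.zeros(n)
        v[40:60] = np.linspace(0, 1, 20)
        v[60:80] = np.linspace(1, 0, 20)
        return ExtAucTrack("A", v, np.array(["1"] * n),
                           np.arange(1, n + 1) * 1000)

    def test_uniform_map_rate_one(self):
        p = mk_peak(1.0, 0, 0, lo=30, apex=55, hi=85)
        p.low_valley_bp, p.high_valley_bp = 30_000, 85_000
        peak_recombination(p, self._track(), self._uniform_map())
        assert p.recomb_rate == pytest.approx(1.0, rel=1e-9)

    def test_hotspot_rate_hand_computed(self):
        # map: 1 cM/Mb up to 50 kb, 10 cM/Mb beyond
        pos = np.array([1.0, 50_000.0, 10_000_000.0])
        cm = np.array([0.0, 0.049999, 0.049999 + 10 * (10_000_000 - 50_000) / 1e6])
        gmap = GeneticMap(pos, cm)
        rate = gmap.rate(40_000, 60_000)
        dcm = (np.interp(60_000, pos, cm) - np.interp(40_000, pos, cm))
        assert rate == pytest.approx(dcm / 0.02, rel=1e-9)

    def test_rate_at_reference_median_percentile(self):
        p = mk_peak(1.0, 0, 0, lo=30, apex=55, hi=85)
        p.low_valley_bp, p.high_valley_bp = 30_000, 85_000
        track = self._track()
        ref = {np.round((85_000 - 30_000 + 1) * 0.5): None}
        # reference bin populated symmetrically around the observed rate
        gmap = self._uniform_map()
        peak_recombination(p, track, gmap,
                           bin_reference={30_000: np.array([0.5, 1.0, 2.0])})
        assert p.recomb_rate_percentile == pytest.approx(2 / 3)

    def test_window_outside_map_errors(self):
        p = mk_peak(1.0, 0, 0, lo=30, apex=55, hi=85)
        p.low_valley_bp, p.high_valley_bp = 30_000, 85_000
        short_map = GeneticMap(np.array([1.0, 40_000.0]), np.array([0.0, 0.04]))
        with pytest.raises(ValueError):
            peak_recombination(p, self._track(), short_map)
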