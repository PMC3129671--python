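import numpy as np
import pytest

from hzkit.annotate import (
    PhasedHaplotypePanel,
    annotate_hps,
    compute_misl,
    coverage_curves,
    founder_hap_freq,
    hps,
    intersect_segments,
    mad_score,
    mappable_length,
)
from hzkit.detect import HomozygousSegment, SegmentSet, detect_segments

from conftest import make_gm


def seg(start_idx, end_idx, sample="S0", chrom="1", positions=None, **kw):
    if positions is None:
        positions = np.arange(1, end_idx + 2) * 1000
    return HomozygousSegment(
        sample_id=sample, chromosome=chrom,
        start_bp=int(positions[start_idx]), end_bp=int(positions[end_idx]),
        start_idx=start_idx, end_idx=end_idx,
        snp_count=end_idx - start_idx + 1, het_count=0, nocall_count=0, **kw)


class TestHps:
    def test_direct_product(self):
        s = seg(0, 1)
        assert hps(s, np.array([0.5, 0.5])) == pytest.approx(0.25)

    def test_fixed_locus_contributes_factor_one(self):
        s = seg(0, 2)
        assert hps(s, np.array([0.5, 1.0, 0.5])) == pytest.approx(0.25)

    def test_filter_boundary_at_hps_cutoff(self):
        # 0.8^20 = 0.0115 fails the <=0.01 filter; 0.8^21 = 0.0092 passes
        s20 = seg(0, 19)
        s21 = seg(0, 20)
        assert hps(s20, np.full(20, 0.8)) > 0.01
        assert hps(s21, np.full(21, 0.8)) <= 0.01

    def test_log_space_matches_direct_product(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = rng.integers(2, 60)
            f = rng.uniform(0.05, 1.0, n)
            s = seg(0, n - 1)
            direct = float(np.prod(f))
            assert hps(s, f) == pytest.approx(direct, rel=1e-12)

    def test_missing_freq_hom_raises(self):
        s = seg(0, 1)
        with pytest.raises(ValueError, match="locus"):
            hps(s, np.array([0.5, np.nan]))


class TestMisl:
    def test_min_of_maxes(self):
        segs = [seg(0, 299, "S0"), seg(0, 99, "S0"),
                seg(0, 199, "S1")]
        t = compute_misl(SegmentSet(segs, None))
        assert t.misl_chr["1"] == 199_001  # S1's best
        assert t.misl_gw == t.misl_chr["1"]

    def test_gw_is_min_over_chromosomes_and_subsets(self):
        segs = [seg(0, 299, "S0", "1"), seg(0, 99, "S0", "2")]
        t = compute_misl(SegmentSet(segs, None), subsets={"1+2": ["1", "2"]})
        assert t.misl_gw == min(t.misl_chr.values())
        assert t.misl_subset["1+2"] == t.misl_gw

    def test_matches_two_level_minmax_oracle(self):
        rng = np.random.default_rng(9)
        segs = []
        table = {}
        for sid in ("S0", "S1", "S2"):
            for chrom in ("1", "2"):
                for _ in range(rng.integers(1, 5)):
                    a = int(rng.integers(0, 50))
                    b = a + int(rng.integers(1, 200))
                    pos = np.arange(1, b + 2) * 1000
                    s = seg(a, b, sid, chrom, positions=pos)
                    segs.append(s)
                    key = (chrom, sid)
                    table[key] = max(table.get(key, 0), s.length_bp)
        t = compute_misl(SegmentSet(segs, None))
        for chrom in ("1", "2"):
            want = min(v for (c, _), v in table.items() if c == chrom)
            assert t.misl_chr[chrom] == want


class TestMadScore:
    def test_length_at_median_scores_zero(self):
        islm = np.array([[100.0], [200.0], [300.0]])
        s = seg(0, 0)
        s.start_bp, s.end_bp = 1, 200  # length 200 = median
        assert mad_score(s, islm) == pytest.approx(0.0)

    def test_hand_computed_robust_zscore(self):
        # ISLV_nz = {100, 100, 110, 120} kb: median 105 kb, raw MAD 5 kb
        islm = np.array([[100_000.0], [100_000.0], [110_000.0], [120_000.0]])
        s = seg(0, 0)
        s.start_bp, s.end_bp = 1, 400_000  # 400 kb segment
        want = (400_000 - 105_000) / (1.4826 * 5_000)
        assert mad_score(s, islm) == pytest.approx(want)
        assert mad_score(s, islm) > 10

    def test_uniform_population_scores_zero(self):
        islm = np.full((10, 5), 50_000.0)
        s = seg(0, 4)
        s.start_bp, s.end_bp = 1, 50_000
        assert mad_score(s, islm) == pytest.approx(0.0)

    def test_zero_mad_path(self):
        islm = np.array([[100.0], [100.0], [100.0]])
        longer = seg(0, 0)
        longer.start_bp, longer.end_bp = 1, 500
        assert mad_score(longer, islm) == np.inf
        at_median = seg(0, 0)
        at_median.start_bp, at_median.end_bp = 1, 100
        assert mad_score(at_median, islm) == 0.0

    def test_invariant_to_duplicated_columns(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(1e4, 1e5, size=(8, 3))
        dup = base[:, [0, 0, 1, 1, 1, 2]]  # adjacent duplicates collapse
        s1 = seg(0, 2)
        s1.start_bp, s1.end_bp = 1, 300_000
        s2 = seg(0, 5)
        s2.start_bp, s2.end_bp = 1, 300_000
        assert mad_score(s1, base) == pytest.approx(mad_score(s2, dup))


class TestFounderHapFreq:
    def _panel(self, haps, pops=None):
        n = len(haps) // 2
        return PhasedHaplotypePanel(np.array(haps, dtype=np.int8),
                                    [f"S{i}" for i in range(n)], pops)

    def test_exact_match_proportion(self):
        # founder 0101 present in 2 of 8 panel haplotypes; segment calls
        # homozygous alt at loci 1,3 -> founder (0,1,0,1)
        target = [0, 1, 0, 1]
        other = [1, 1, 1, 1]
        panel = self._panel([target, other] * 4)
        calls = np.array([0, 2, 0, 2])
        s = seg(0, 3)
        f = founder_hap_freq(s, panel, calls=calls)
        assert f == pytest.approx(4 / 8)  # 4 rows equal target

    def test_tolerance_is_max_of_percent_and_one(self):
        rng = np.random.default_rng(1)
        L = 300
        founder = rng.integers(0, 2, L)
        calls = np.where(founder == 1, 2, 0)
        rows = []
        for k in (0, 1, 2, 3, 4):  # rows at increasing mismatch counts
            h = founder.copy()
            h[:k] = 1 - h[:k]
            rows.append(h)
        rows.append(1 - founder)
        panel = self._panel(rows)
        s = seg(0, L - 1)
        # tolerance = max(0.01*300, 1) = 3 mismatches -> rows 0..3 match
        assert founder_hap_freq(s, panel, calls=calls) == pytest.approx(4 / 6)

    def test_small_segment_tolerance_floor_one(self):
        L = 50
        founder = np.zeros(L, dtype=np.int8)
        one_off = founder.copy()
        one_off[0] = 1
        two_off = founder.copy()
        two_off[:2] = 1
        panel = self._panel([founder, one_off, two_off, 1 - founder])
        s = seg(0, L - 1)
        calls = np.zeros(L, dtype=np.uint8)
        # tolerance = max(0.5, 1) = 1 mismatch
        assert founder_hap_freq(s, panel, calls=calls) == pytest.approx(2 / 4)

    def test_monomorphic_matching_panel_gives_one(self):
        L = 20
        panel = self._panel([np.zeros(L, dtype=np.int8)] * 6)
        s = seg(0, L - 1)
        assert founder_hap_freq(s, panel,
                                calls=np.zeros(L, dtype=np.uint8)) == 1.0

    def test_het_loci_excluded_from_comparison(self):
        L = 10
        founder = np.zeros(L, dtype=np.int8)
        panel = self._panel([founder] * 4)
        calls = np.zeros(L, dtype=np.uint8)
        calls[3] = 1  # absorbed het: dropped from the distance computation
        s = seg(0, L - 1)
        assert founder_hap_freq(s, panel, calls=calls) == 1.0


class TestMappableLength:
    def test_single_large_gap_removes_everything(self):
        assert mappable_length([1, 1_000_001]) == 0

    def test_uniform_spacing_no_subtraction(self):
        pos = np.arange(1000) * 1000 + 1
        assert mappable_length(pos) == 999_000

    def test_mixed_fixture_matches_direct_sum(self):
        rng = np.random.default_rng(2)
        gaps = rng.choice([1000, 5000, 600_000, 2_000_000], size=200,
                          p=[0.8, 0.15, 0.04, 0.01])
        pos = np.concatenate([[1], 1 + np.cumsum(gaps)])
        want = int(pos[-1] - pos[0] - gaps[gaps > 500_000].sum())
        assert mappable_length(pos) == want

    def test_too_few_loci(self):
        with pytest.raises(ValueError):
            mappable_length([5])


class TestCoverageCurves:
    def _fixture(self, lengths_by_sample, n_loci=1000):
        calls = np.full((len(lengths_by_sample), n_loci), 1, dtype=np.uint8)
        gm = make_gm(calls)
        segs = []
        for i, lengths in enumerate(lengths_by_sample):
            at = 0
            for L in lengths:
                n = L // 1000
                s = seg(at, at + n - 1, f"S{i}", positions=gm.positions)
                s.hps_ex = 1e-6
                segs.append(s)
                at += n + 2
        return gm, SegmentSet(segs, None)

    def test_single_segment_step(self):
        gm, ss = self._fixture([[200_000]])
        df = coverage_curves(ss, gm, cutoffs=[100_000, 200_000, 500_000])
        mappable = mappable_length(gm.positions)
        got = df.set_index("cutoff_bp")["median_proportion"]
        assert got[100_000] == 0.0
        expected = ss.segments[0].length_bp / mappable
        assert got[200_000] == pytest.approx(expected, rel=1e-3)
        assert got[500_000] == pytest.approx(expected, rel=1e-3)

    def test_median_of_two_individuals(self):
        gm, ss = self._fixture([[100_000], [300_000]])
        df = coverage_curves(ss, gm, cutoffs=[400_000])
        mappable = mappable_length(gm.positions)
        lens = sorted(s.length_bp for s in ss.segments)
        want = np.median([lens[0] / mappable, lens[1] / mappable])
        assert df.median_proportion.iloc[0] == pytest.approx(want, rel=1e-6)

    def test_matches_bruteforce_cumsum_oracle(self):
        rng = np.random.default_rng(8)
        lengths = [sorted(rng.integers(10, 200, size=5) * 1000)
                   for _ in range(4)]
        gm, ss = self._fixture(lengths, n_loci=5000)
        cutoffs = np.arange(0, 1_000_001, 50_000)
        df = coverage_curves(ss, gm, cutoffs=cutoffs)
        mappable = mappable_length(gm.positions)
        by_sample = {}
        for s in ss.segments:
            by_sample.setdefault(s.sample_id, []).append(s.length_bp)
        for c in cutoffs:
            want = np.median([
                sum(L for L in v if L <= c) / mappable
                for v in by_sample.values()])
            got = df[df.cutoff_bp == c].median_proportion.iloc[0]
            assert got == pytest.approx(want, rel=1e-9), c


class TestIntersectSegments:
    def test_basic_overlap_both_directions(self):
        a = [("1", 100, 200)]
        b = [("1", 150, 300)]
        assert intersect_segments(a, b) == [(1, [0])]
        assert intersect_segments(b, a) == [(1, [0])]

    def test_disjoint_sets(self):
        a = [("1", 100, 200), ("2", 100, 200)]
        b = [("1", 300, 400)]
        assert [c for c, _ in intersect_segments(a, b)] == [0, 0]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(6)
        def rand_ivs(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 10_000))
                out.append((str(rng.integers(1, 4)), s, s + int(rng.integers(1, 500))))
            return out
        a, b = rand_ivs(300), rand_ivs(300)
        got = intersect_segments(a, b)
        for (ca, sa, ea), (cnt, hits) in zip(a, got):
            want = [j for j, (cb, sb, eb) in enumerate(b)
                    if cb == ca and sb <= ea and eb >= sa]
            assert sorted(hits) == want and cnt == len(want)


class TestAnnotateHps:
    def test_external_and_internal_scopes_differ(self, sim_bundle):
        _, gm, _, _, _ = sim_bundle
        ss = detect_segments(gm)
        annotate_hps(ss, gm)
        hx = np.array([s.hps_ex for s in ss.segments])
        hi = np.array([s.hps_in for s in ss.segments])
        assert np.all((hx > 0) & (hx <= 1)) and np.all((hi > 0) & (hi <= 1))
        assert not np.allclose(hx, hi)
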