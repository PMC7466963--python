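"""Box smoothing, permutation envelopes, region calling and region tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divscape import (ChromMap, RegionCall, ScanConfig, call_regions,
                      compare_region_sizes, kernel_smooth,
                      permutation_envelope, region_dxy_contrast,
                      scan_comparison, shared_regions, site_components,
                      windowed_stats)


def _wt(fst, dxy=None, chrom="chr1", window_bp=50_000):
    n = len(fst)
    return pd.DataFrame({
        "chrom": [chrom] * n, "start": np.arange(n) * window_bp,
        "end": (np.arange(n) + 1) * window_bp, "n_sites": 10,
        "fst": fst, "dxy": dxy if dxy is not None else [0.01] * n})


class TestKernelSmooth:
    def test_constant_preserved(self):
        out = kernel_smooth(np.full(50, 3.7), bandwidth=20)
        np.testing.assert_allclose(out, 3.7)

    def test_single_spike_truncated_moving_average(self):
        v = np.zeros(30)
        v[10] = 1.0
        out = kernel_smooth(v, bandwidth=8)  # half-width 4 → support 9
        # hand-computed: window i averages v[i-4 : i+5] clipped to bounds
        expected = []
        for i in range(30):
            lo, hi = max(i - 4, 0), min(i + 5, 30)
            expected.append(v[lo:hi].mean())
        np.testing.assert_allclose(out, expected)

    def test_linear_ramp_unchanged_in_interior(self):
        v = np.arange(40, dtype=float)
        out = kernel_smooth(v, bandwidth=10)
        np.testing.assert_allclose(out[5:35], v[5:35])

    def test_empty_input(self):
        assert kernel_smooth(np.array([]), 20).size == 0


class TestPermutationEnvelope:
    def test_constant_input_thresholds_equal_constant(self):
        cfg = ScanConfig(bandwidth=4, n_perm=50, seed=0)
        up, lo = permutation_envelope(np.full(30, 0.2), cfg)
        assert up == pytest.approx(0.2) and lo == pytest.approx(0.2)

    def test_matches_naive_full_materialization(self):
        v = np.random.default_rng(3).normal(size=25)
        cfg = ScanConfig(bandwidth=6, n_perm=40, seed=42)
        up, lo = permutation_envelope(v, cfg)
        # naive oracle: same rng stream, all smoothed lines materialized
        rng = np.random.default_rng(42)
        lines = []
        for _ in range(40):
            order = np.argsort(rng.random((1, v.size)), axis=1)[0]
            lines.append(kernel_smooth(v[order], 6))
        lines = np.vstack(lines)
        assert up == pytest.approx(lines.max())
        assert lo == pytest.approx(lines.min())

    def test_thresholds_bracket_mean(self):
        v = np.random.default_rng(4).normal(size=60)
        cfg = ScanConfig(bandwidth=10, n_perm=200, seed=1)
        up, lo = permutation_envelope(v, cfg)
        assert lo <= v.mean() <= up

    def test_too_short_chromosome_errors(self):
        with pytest.raises(ValueError):
            permutation_envelope(np.ones(5), ScanConfig(bandwidth=20))


class TestCallRegions:
    cfg = ScanConfig(bandwidth=4, n_perm=10, merge_gap=10, seed=0)

    def _call(self, smoothed, thresholds, n=None):
        n = n if n is not None else len(smoothed)
        return call_regions(_wt([0.1] * n), np.asarray(smoothed, float),
                            thresholds, self.cfg)

    def test_flat_landscape_no_calls(self):
        assert self._call([0.1] * 40, (0.2, 0.0)) == []

    def test_merge_gap_ten_vs_eleven(self):
        n = 40
        sm = np.zeros(n)
        sm[[5, 16]] = 1.0            # gap of 10 windows between runs
        regions = self._call(sm, (0.5, -1.0))
        assert len(regions) == 1
        assert regions[0].n_windows == 12
        sm2 = np.zeros(n)
        sm2[[5, 17]] = 1.0           # gap of 11 → two regions
        assert len(self._call(sm2, (0.5, -1.0))) == 2

    def test_islands_and_valleys_not_merged_together(self):
        sm = np.zeros(30)
        sm[5] = 1.0
        sm[8] = -1.0
        regions = self._call(sm, (0.5, -0.5))
        kinds = sorted(r.kind for r in regions)
        assert kinds == ["island", "valley"]

    def test_region_span_uses_window_bounds(self):
        sm = np.zeros(20)
        sm[3:6] = 1.0
        (r,) = self._call(sm, (0.5, -1.0))
        assert (r.start, r.end) == (3 * 50_000, 6 * 50_000)


class TestRegionDxyContrast:
    def test_identical_to_background_median_p_one(self):
        wt = _wt([0.1] * 30, dxy=[0.02] * 30)
        region = RegionCall("island", "chr1", 0, 150_000, 3, 0.1, 0.02)
        p, d = region_dxy_contrast(region, wt)
        assert p == 1.0 and d == 0

    def test_shifted_region_detected_with_direction(self):
        dxy = [0.02] * 30
        for i in range(8):
            dxy[i] = 0.03
        wt = _wt([0.1] * 30, dxy=dxy)
        region = RegionCall("island", "chr1", 0, 8 * 50_000, 8, 0.1, 0.03)
        p, d = region_dxy_contrast(region, wt)
        assert p < 0.05 and d == 1

    def test_small_region_matches_exact_signed_rank(self):
        rng = np.random.default_rng(5)
        dxy = list(rng.uniform(0.01, 0.03, 30))
        wt = _wt([0.1] * 30, dxy=dxy)
        region = RegionCall("valley", "chr1", 0, 6 * 50_000, 6, 0.1, 0.0)
        p, _ = region_dxy_contrast(region, wt)
        med = np.median(dxy[6:])
        expected = stats.wilcoxon(np.asarray(dxy[:6]) - med,
                                  zero_method="wilcox").pvalue
        assert p == pytest.approx(expected)


class TestCompareRegionSizes:
    def _regions(self, sizes):
        return [RegionCall("island", "chr1", 0, s, 1, 0.1, 0.01)
                for s in sizes]

    def test_identical_groups_p_near_one(self):
        groups = {c: self._regions([100, 200, 300]) for c in "abc"}
        _, p = compare_region_sizes(groups)
        assert p > 0.9

    def test_shifted_group_small_p(self):
        groups = {"a": self._regions([100, 110, 120, 130, 125]),
                  "b": self._regions([1000, 1100, 1200, 1300, 1250])}
        _, p = compare_region_sizes(groups)
        assert p < 0.05

    def test_matches_rank_formula(self):
        groups = {"a": self._regions([10, 40]),
                  "b": self._regions([20, 50]),
                  "c": self._regions([30, 60])}
        stat, _ = compare_region_sizes(groups)
        sizes = np.array([10, 40, 20, 50, 30, 60], float)
        ranks = stats.rankdata(sizes)
        rsums = [ranks[:2].sum(), ranks[2:4].sum(), ranks[4:].sum()]
        n = 6
        h = 12 / (n * (n + 1)) * sum(r * r / 2 for r in rsums) - 3 * (n + 1)
        assert stat == pytest.approx(h)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            compare_region_sizes({"a": self._regions([10])})


class TestSharedRegions:
    def _r(self, kind, start, end, chrom="chr1"):
        return RegionCall(kind, chrom, start, end, 1, 0.1, 0.01)

    def test_disjoint_regions_empty(self):
        out = shared_regions({"a": [self._r("island", 0, 100)],
                              "b": [self._r("island", 200, 300)]})
        assert out.empty

    def test_overlapping_pair_grouped_with_sizes(self):
        out = shared_regions({
            "a": [self._r("island", 0, 100_000)],
            "b": [self._r("island", 50_000, 200_000)]})
        assert len(out) == 2
        assert set(out["size_bp"]) == {100_000, 150_000}
        assert out["group"].nunique() == 1

    def test_same_comparison_only_not_reported(self):
        out = shared_regions({"a": [self._r("island", 0, 100),
                                    self._r("island", 50, 200)]})
        assert out.empty

    def test_matches_bruteforce_pairwise_overlap(self):
        rng = np.random.default_rng(6)
        groups = {}
        for label in "abc":
            regs = []
            for _ in range(8):
                s = int(rng.integers(0, 900)) * 1000
                regs.append(self._r("island", s, s + int(rng.integers(1, 80)) * 1000))
            groups[label] = regs
        out = shared_regions(groups)
        # brute force: a region is in some shared group iff a same-kind
        # region of another comparison overlaps it (transitively; direct
        # overlap is sufficient evidence of membership)
        direct = set()
        items = [(l, r) for l, regs in groups.items() for r in regs]
        for i, (la, ra) in enumerate(items):
            for lb, rb in items[i + 1:]:
                if la != lb and ra.start < rb.end and rb.start < ra.end:
                    direct.add((la, ra.start, ra.end))
                    direct.add((lb, rb.start, rb.end))
        reported = set(zip(out["comparison"], out["start"], out["end"]))
        assert direct <= reported


class TestEndToEndScan:
    def test_spike_recovered_and_boundaries_close(self, spiked,
                                                  chrom_map_single):
        spec, gm, truth = spiked
        sc = site_components(gm, "popA", "popB")
        wt = windowed_stats(sc, chrom_map_single, spec.window_bp, min_sites=10)
        cfg = ScanConfig(bandwidth=20, n_perm=500, merge_gap=10, seed=2)
        regions = scan_comparison(wt, cfg, comparison="AB")
        islands = [r for r in regions if r.kind == "island"]
        (truth_island,) = [t for t in truth if t[0] == "island"]
        hits = [r for r in islands
                if r.start < truth_island[3] and r.end > truth_island[2]]
        assert len(hits) >= 1
        # called boundaries within bandwidth windows of the truth interval
        tol = cfg.bandwidth * spec.window_bp
        assert abs(hits[0].start - truth_island[2]) <= tol
        assert abs(hits[0].end - truth_island[3]) <= tol

    def test_valley_recovered_with_low_dxy(self, spiked, chrom_map_single):
        spec, gm, truth = spiked
        sc = site_components(gm, "popA", "popB")
        wt = windowed_stats(sc, chrom_map_single, spec.window_bp, min_sites=10)
        cfg = ScanConfig(bandwidth=20, n_perm=500, merge_gap=10, seed=3)
        regions = scan_comparison(wt, cfg)
        (tv,) = [t for t in truth if t[0] == "valley"]
        valleys = [r for r in regions if r.kind == "valley"
                   and r.start < tv[3] and r.end > tv[2]]
        assert len(valleys) >= 1
        background = wt.loc[~((wt["start"] >= tv[2]) & (wt["end"] <= tv[3])),
                            "dxy"].mean()
        assert valleys[0].mean_dxy < background

    def test_scan_shift_invariance(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0.1, 0.02, 120)
        cfg = ScanConfig(bandwidth=10, n_perm=300, seed=9)
        r1 = scan_comparison(_wt(list(vals)), cfg)
        r2 = scan_comparison(_wt(list(vals + 5.0)), cfg)
        assert [(r.kind, r.start, r.end) for r in r1] == \
               [(r.kind, r.start, r.end) for r in r2]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        vals = list(rng.normal(0.1, 0.02, 80))
        cfg = ScanConfig(bandwidth=10, n_perm=200, seed=11)
        r1 = scan_comparison(_wt(vals), cfg)
        r2 = scan_comparison(_wt(vals), cfg)
        assert [(r.kind, r.start, r.end) for r in r1] == \
               [(r.kind, r.start, r.end) for r in r2]
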