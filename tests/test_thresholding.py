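import numpy as np
import pytest

from conftest import make_dom, make_hist, random_filtered_hist
from hueseg.config import Config
from hueseg.histogram import GaussianFitResult, evaluate_fit
from hueseg.thresholding import (
    CaseType,
    Direction,
    ThresholdDetectionError,
    classify_case,
    classify_dominant,
    combine,
    detect_th1,
    detect_th2,
    detect_th3,
    detect_th4,
    detect_th5,
    enumerate_valleys_peaks,
)

SQRT2 = np.sqrt(2.0)


def fit1(b1, sigma, a1=1000.0):
    """Single-component fit with the given true standard deviation."""
    return GaussianFitResult(a1=a1, b1=float(b1), c1=sigma * SQRT2,
                             a2=np.nan, b2=np.nan, c2=np.nan, n_peaks=1,
                             converged=True, residual_norm=0.0)


def fit2(b1, c1, b2, c2, a1=1000.0, a2=500.0):
    return GaussianFitResult(a1=a1, b1=float(b1), c1=float(c1), a2=a2,
                             b2=float(b2), c2=float(c2), n_peaks=2,
                             converged=True, residual_norm=0.0)


# ---------------------------------------------------------------- oracles

def oracle_walk(hist, dom):
    pairs = sorted(zip(hist.bin_centers.tolist(), hist.counts.tolist()))
    if dom.direction is Direction.INCREASING:
        return [(h, c) for h, c in pairs if h >= dom.main_hue]
    return [(h, c) for h, c in reversed(pairs) if h <= dom.main_hue]


def oracle_extrema(hist, dom):
    """Naive run-compressed valley/peak enumeration along the walk."""
    seq = oracle_walk(hist, dom)
    runs = []
    for i, (h, c) in enumerate(seq):
        if runs and runs[-1][2] == c:
            continue
        runs.append((i, h, c))
    valleys, peaks = [], []
    for j in range(1, len(runs) - 1):
        _, _, prev_c = runs[j - 1]
        idx, hue, c = runs[j]
        _, _, next_c = runs[j + 1]
        if c < prev_c and c < next_c:
            valleys.append((idx, hue, c))
        elif c > prev_c and c > next_c:
            peaks.append((idx, hue, c))
    return seq, valleys, peaks


def oracle_th3_stops(hist, dom):
    _, valleys, _ = oracle_extrema(hist, dom)
    return [float(valleys[i][1]) for i in range(len(valleys) - 1)
            if valleys[i][2] < valleys[i + 1][2]]


def oracle_th4_stops(hist, dom):
    seq, valleys, _ = oracle_extrema(hist, dom)
    counts = [c for _, c in seq]
    stops = []
    for idx, hue, c in valleys:
        end = idx
        while end + 1 < len(counts) and counts[end + 1] == c:
            end += 1
        if end + 2 < len(counts) and counts[end] < counts[end + 1] < counts[end + 2]:
            stops.append(float(hue))
    return stops


def oracle_th5_stops(hist, dom):
    _, valleys, peaks = oracle_extrema(hist, dom)
    stops = []
    for i in range(len(peaks) - 1):
        if not peaks[i][2] < peaks[i + 1][2]:
            continue
        before = [v for v in valleys if v[0] < peaks[i][0]]
        after = [v for v in valleys if v[0] > peaks[i][0]]
        if before and after:
            vb, va = before[-1], after[0]
            stops.append(float(vb[1]) if vb[2] <= va[2] else float(va[1]))
    return stops


# ------------------------------------------------------- classification

class TestClassification:
    @pytest.mark.parametrize(
        "mean, expected_class, expected_dir",
        [
            (45.0, "non_vegetation", Direction.INCREASING),
            (110.0, "vegetation", Direction.DECREASING),
            (60.0, "vegetation", Direction.DECREASING),  # boundary -> green
        ],
    )
    def test_dominant_rule(self, mean, expected_class, expected_dir):
        h = make_hist([int(mean) - 1, int(mean), int(mean) + 1], [5, 50, 5])
        dom = classify_dominant(fit1(mean, 8.0), h)
        assert dom.dominant_class == expected_class
        assert dom.direction == expected_dir
        assert dom.mean_dominant == mean

    @pytest.mark.parametrize(
        "n_peaks, veg, expected",
        [
            (1, False, CaseType.CASE1),
            (1, True, CaseType.CASE2),
            (2, False, CaseType.CASE3),
            (2, True, CaseType.CASE4),
        ],
    )
    def test_case_mapping(self, n_peaks, veg, expected):
        fit = fit2(40, 10, 120, 15) if n_peaks == 2 else fit1(40, 8)
        dom = make_dom(40, Direction.DECREASING if veg else Direction.INCREASING)
        assert classify_case(fit, dom) == expected

    def test_fallback_uses_main_hue(self):
        bad = GaussianFitResult(a1=9.0, b1=200.0, c1=np.nan, a2=np.nan,
                                b2=np.nan, c2=np.nan, n_peaks=1,
                                converged=False, residual_norm=np.inf)
        h = make_hist([38, 40, 42], [5, 50, 5])
        dom = classify_dominant(bad, h)
        assert dom.mean_dominant == 40.0
        assert dom.dominant_class == "non_vegetation"


# ---------------------------------------------------------------- th1

class TestTh1:
    def _hist_low_end(self, lo):
        return make_hist([lo, 40, 60], [3, 50, 3])

    def test_highest_multiple_accepted(self):
        # sigma = 8, S2 = 40 - 10 = 30: 3 sigma = 24 < 30 -> k = 3, th1 = 64
        h = self._hist_low_end(10)
        dom = make_dom(40, Direction.INCREASING)
        th1, k, s2 = detect_th1(fit1(40, 8.0), h, dom)
        assert s2 == 30
        assert k == 3
        assert th1 == pytest.approx(64.0)

    def test_falls_back_to_lower_multiple(self):
        # sigma = 12: 36 >= 30 rejected, 24 < 30 -> k = 2, th1 = 64
        h = self._hist_low_end(10)
        th1, k, _ = detect_th1(fit1(40, 12.0), h, make_dom(40, Direction.INCREASING))
        assert k == 2
        assert th1 == pytest.approx(64.0)

    def test_all_multiples_rejected(self):
        th1, k, _ = detect_th1(fit1(40, 40.0), self._hist_low_end(10),
                               make_dom(40, Direction.INCREASING))
        assert th1 is None and k is None

    def test_equal_is_rejected(self):
        # 3 sigma = 30 == S2 -> not strictly smaller -> k = 2
        _, k, _ = detect_th1(fit1(40, 10.0), self._hist_low_end(10),
                             make_dom(40, Direction.INCREASING))
        assert k == 2

    def test_subtracts_when_vegetation_dominant(self):
        h = make_hist([60, 110, 150], [3, 50, 3])
        dom = make_dom(110, Direction.DECREASING)
        th1, k, s2 = detect_th1(fit1(110, 12.0), h, dom)
        assert s2 == 40  # 150 - 110, far end opposite the downward search
        assert k == 3
        assert th1 == pytest.approx(110 - 36)


# ---------------------------------------------------------------- th2

class TestTh2:
    def test_absent_for_single_peak(self):
        assert detect_th2(fit1(40, 8), make_dom(40, Direction.INCREASING)) is None

    def test_symmetric_components_meet_in_middle(self):
        fit = fit2(40, 10, 120, 10, a1=1000, a2=1000)
        th2 = detect_th2(fit, make_dom(40, Direction.INCREASING))
        assert th2 == pytest.approx(80.0, abs=1e-3)

    def test_matches_exhaustive_scan(self):
        fit = fit2(40, 10, 120, 20, a1=5000, a2=1000)
        th2 = detect_th2(fit, make_dom(40, Direction.INCREASING))
        grid = np.arange(40, 120.0001, 0.01)
        brute = grid[int(np.argmin(evaluate_fit(fit, grid)))]
        assert th2 == pytest.approx(brute, abs=0.1)

    def test_relabeling_invariance(self):
        a = fit2(40, 10, 120, 15, a1=800, a2=800)
        b = fit2(120, 15, 40, 10, a1=800, a2=800)
        dom = make_dom(40, Direction.INCREASING)
        assert detect_th2(a, dom) == pytest.approx(detect_th2(b, dom), abs=1e-6)

    def test_absent_when_secondary_behind_search(self):
        # secondary at lower hue while searching upward
        fit = fit2(110, 12, 40, 8)
        assert detect_th2(fit, make_dom(110, Direction.INCREASING)) is None


# ------------------------------------------------- valleys, peaks, walks

class TestExtrema:
    def test_textbook_sequence(self):
        # counts along walk [9,4,7,2,8]: valleys at 4 and 2, peak at 7
        h = make_hist([40, 41, 42, 43, 44], [9, 4, 7, 2, 8])
        valleys, peaks = enumerate_valleys_peaks(h, make_dom(40))
        assert [(hue, c) for _, hue, c in valleys] == [(41, 4), (43, 2)]
        assert [(hue, c) for _, hue, c in peaks] == [(42, 7)]

    def test_monotone_walk_has_no_extrema(self):
        h = make_hist([40, 41, 42, 43], [9, 7, 5, 3])
        assert enumerate_valleys_peaks(h, make_dom(40)) == ([], [])

    def test_plateau_contributes_first_bin(self):
        h = make_hist([40, 41, 42, 43, 44], [9, 4, 4, 4, 8])
        valleys, _ = enumerate_valleys_peaks(h, make_dom(40))
        assert [(hue, c) for _, hue, c in valleys] == [(41, 4)]

    def test_alternation_property(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            hist, dom = random_filtered_hist(rng)
            valleys, peaks = enumerate_valleys_peaks(hist, dom)
            merged = sorted(
                [(v[0], "v") for v in valleys] + [(p[0], "p") for p in peaks]
            )
            kinds = [k for _, k in merged]
            assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_matches_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            hist, dom = random_filtered_hist(rng)
            valleys, peaks = enumerate_valleys_peaks(hist, dom)
            _, ov, op = oracle_extrema(hist, dom)
            assert [(h, c) for _, h, c in valleys] == [(h, c) for _, h, c in ov]
            assert [(h, c) for _, h, c in peaks] == [(h, c) for _, h, c in op]


class TestTh3:
    def test_spec_example(self):
        # valleys 100@45, 300@55, 50@65, 400@75 -> stops 45, 65 -> mean 55
        bins = [40, 45, 50, 55, 60, 65, 70, 75, 80]
        counts = [1000, 100, 600, 300, 700, 50, 800, 400, 900]
        th3, stops = detect_th3(make_hist(bins, counts), make_dom(40))
        assert stops == [45.0, 65.0]
        assert th3 == pytest.approx(55.0)

    def test_absent_outside_window(self):
        bins = [70, 75, 80, 85, 90, 95, 100, 105, 110]
        counts = [1000, 100, 600, 300, 700, 50, 800, 400, 900]
        th3, stops = detect_th3(make_hist(bins, counts), make_dom(70))
        assert stops == [75.0, 95.0]
        assert th3 is None

    def test_matches_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            hist, dom = random_filtered_hist(rng)
            _, stops = detect_th3(hist, dom)
            assert stops == oracle_th3_stops(hist, dom)


class TestTh4:
    def test_two_rises_make_a_stop(self):
        h = make_hist([40, 41, 42, 43, 44], [10, 3, 5, 9, 4])
        th4, stops = detect_th4(h, make_dom(40))
        assert stops == [41.0]
        assert th4 == pytest.approx(41.0)

    def test_single_rise_is_not_a_stop(self):
        h = make_hist([40, 41, 42, 43, 44], [10, 3, 5, 2, 6])
        _, stops = detect_th4(h, make_dom(40))
        assert 41.0 not in stops

    def test_matches_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(100):
            hist, dom = random_filtered_hist(rng)
            _, stops = detect_th4(hist, dom)
            assert stops == oracle_th4_stops(hist, dom)


class TestTh5:
    def test_smaller_flanking_valley_wins(self):
        # peaks 200@42 then 500@44; flanking valleys 80@41 and 120@43
        h = make_hist([40, 41, 42, 43, 44, 45], [1000, 80, 200, 120, 500, 100])
        th5, stops = detect_th5(h, make_dom(40))
        assert stops == [41.0]
        assert th5 == pytest.approx(41.0)

    def test_single_peak_no_stop(self):
        h = make_hist([40, 41, 42, 43], [1000, 80, 200, 100])
        th5, stops = detect_th5(h, make_dom(40))
        assert stops == [] and th5 is None

    def test_matches_oracle(self):
        rng = np.random.default_rng(16)
        for _ in range(100):
            hist, dom = random_filtered_hist(rng)
            _, stops = detect_th5(hist, dom)
            assert stops == oracle_th5_stops(hist, dom)


# ---------------------------------------------------------------- combine

class TestCombine:
    def _kwargs(self, **over):
        base = dict(
            th1=None, th2=None, th3=None, th4=None, th5=None,
            th3_stops=[], th4_stops=[], th5_stops=[],
            chosen_sigma_multiple=None, s2=30.0, case=CaseType.CASE1,
            dominant=make_dom(40),
        )
        base.update(over)
        return base

    def test_mean_of_present(self):
        rep = combine(**self._kwargs(th1=64.0, th3=55.0, th4=58.0,
                                     chosen_sigma_multiple=3))
        assert rep.final_threshold == pytest.approx((64 + 55 + 58) / 3)

    def test_singleton(self):
        rep = combine(**self._kwargs(th3=50.0))
        assert rep.final_threshold == 50.0

    def test_none_present_raises(self):
        with pytest.raises(ThresholdDetectionError):
            combine(**self._kwargs())

    def test_window_extension_to_all_candidates(self):
        cfg = Config(bounds_on_all_candidates=True)
        rep = combine(**self._kwargs(th1=90.0, th3=50.0), config=cfg)
        assert rep.th1 is None
        assert rep.final_threshold == 50.0

    def test_report_serializable(self):
        import json

        rep = combine(**self._kwargs(th1=64.0, th3=55.0, th3_stops=[45.0, 65.0]))
        d = json.loads(json.dumps(rep.to_dict()))
        assert d["final_threshold"] == rep.final_threshold
        assert d["dominant"]["direction"] == "increasing_hue"
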