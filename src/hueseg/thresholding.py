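"""Detection of the five candidate hue thresholds and their combination.

The method assumes a crop-field image contains two hue populations — soil
(roughly 20-60 degrees) and vegetation (60-180 degrees) — of which at
least the dominant one is approximately Gaussian. The threshold that
separates them is sought just past the border of the dominant
population's hue distribution:

* ``th1`` — the dominant centroid plus (or minus, when searching toward
  lower hue) the largest admissible confidence interval among sigma,
  2*sigma, 3*sigma. A multiple is admissible only when it is strictly
  smaller than S2, the distance from the centroid to the far end of the
  histogram support on the side *opposite* the search; a wider interval
  than that signals a bad fit and the candidate is dropped.
* ``th2`` — the valley of the fitted two-term curve between the two
  centroids (only when a second component exists in the search
  direction).
* ``th3``/``th4``/``th5`` — local-minimum rules on the filtered
  histogram itself, walked from the main hue bin in the search
  direction. Each rule yields a list of candidate *stops*; stops outside
  the 30-70 degree admissibility window are dropped and the survivors
  averaged.

The final threshold is the unweighted mean of whichever candidates were
detected.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import minimize_scalar

from .config import DEFAULT_CONFIG, Config
from .histogram import GaussianFitResult, HueHistogram, evaluate_fit

__all__ = [
    "Direction",
    "CaseType",
    "DominantClassInfo",
    "ThresholdReport",
    "ThresholdDetectionError",
    "classify_dominant",
    "classify_case",
    "detect_th1",
    "detect_th2",
    "enumerate_valleys_peaks",
    "detect_th3",
    "detect_th4",
    "detect_th5",
    "combine",
    "detect_threshold",
]


class ThresholdDetectionError(RuntimeError):
    """No candidate threshold could be detected for this image."""


class Direction(str, Enum):
    INCREASING = "increasing_hue"
    DECREASING = "decreasing_hue"


class CaseType(str, Enum):
    """One/two peaks x non-vegetation/vegetation dominant."""

    CASE1 = "case1"  # one peak, dominant non-vegetation
    CASE2 = "case2"  # one peak, dominant vegetation
    CASE3 = "case3"  # two peaks, dominant non-vegetation
    CASE4 = "case4"  # two peaks, dominant vegetation


@dataclass(frozen=True)
class DominantClassInfo:
    mean_dominant: float  # centroid of the dominant Gaussian, degrees
    main_hue: int  # highest-count surviving histogram bin, degrees
    dominant_class: str  # "vegetation" | "non_vegetation"
    direction: Direction


@dataclass(frozen=True)
class ThresholdReport:
    """Full provenance of one threshold-detection run."""

    th1: float | None
    th2: float | None
    th3: float | None
    th4: float | None
    th5: float | None
    th3_stops: tuple[float, ...]
    th4_stops: tuple[float, ...]
    th5_stops: tuple[float, ...]
    chosen_sigma_multiple: int | None
    s2: float
    case: CaseType
    dominant: DominantClassInfo
    final_threshold: float
    used_fallback: bool = False

    @property
    def candidates(self) -> dict[str, float | None]:
        return {
            "th1": self.th1, "th2": self.th2, "th3": self.th3,
            "th4": self.th4, "th5": self.th5,
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["case"] = self.case.value
        d["dominant"] = {
            "mean_dominant": self.dominant.mean_dominant,
            "main_hue": self.dominant.main_hue,
            "dominant_class": self.dominant.dominant_class,
            "direction": self.dominant.direction.value,
        }
        d["th3_stops"] = list(self.th3_stops)
        d["th4_stops"] = list(self.th4_stops)
        d["th5_stops"] = list(self.th5_stops)
        return d


def classify_dominant(
    fit: GaussianFitResult, h: HueHistogram, config: Config = DEFAULT_CONFIG
) -> DominantClassInfo:
    """Classify the dominant class and fix the threshold-search direction.

    The dominant centroid (or, for a non-converged fit, the main hue bin)
    is compared against the 60-degree yellow/green boundary: at or above
    it the dominant class is vegetation. The search then walks *toward*
    the other class: up the hue axis when soil dominates, down when
    vegetation dominates.
    """
    main_hue = h.main_hue
    mean_dominant = fit.b1 if fit.converged else float(main_hue)
    veg = mean_dominant >= config.veg_boundary
    return DominantClassInfo(
        mean_dominant=float(mean_dominant),
        main_hue=main_hue,
        dominant_class="vegetation" if veg else "non_vegetation",
        direction=Direction.DECREASING if veg else Direction.INCREASING,
    )


def classify_case(fit: GaussianFitResult, dom: DominantClassInfo) -> CaseType:
    if fit.n_peaks == 1:
        return CaseType.CASE1 if dom.dominant_class == "non_vegetation" else CaseType.CASE2
    return CaseType.CASE3 if dom.dominant_class == "non_vegetation" else CaseType.CASE4


def compute_s2(
    fit: GaussianFitResult,
    h: HueHistogram,
    dom: DominantClassInfo,
    config: Config = DEFAULT_CONFIG,
) -> float:
    """Distance from the dominant centroid to the far histogram end
    opposite the search direction (or to centroid -/+ 3c of the fit when
    ``s2_from_fit`` is set)."""
    if config.s2_from_fit and fit.converged and np.isfinite(fit.c1):
        return 3.0 * fit.c1
    if dom.direction is Direction.INCREASING:
        return float(dom.mean_dominant - h.bin_centers.min())
    return float(h.bin_centers.max() - dom.mean_dominant)


def detect_th1(
    fit: GaussianFitResult,
    h: HueHistogram,
    dom: DominantClassInfo,
    config: Config = DEFAULT_CONFIG,
) -> tuple[float | None, int | None, float]:
    """Confidence-interval threshold off the dominant centroid.

    Returns (th1 or None, chosen sigma multiple or None, S2). The
    largest k in {3, 2, 1} with k*sigma strictly below S2 wins; when even
    sigma is too wide the candidate is absent (the fit did not describe
    the histogram well enough to trust its spread).
    """
    s2 = compute_s2(fit, h, dom, config)
    if not fit.converged or not np.isfinite(fit.c1):
        return None, None, s2
    sigma = fit.sigma1
    for k in (3, 2, 1):
        if k * sigma < s2:
            sign = 1.0 if dom.direction is Direction.INCREASING else -1.0
            return float(dom.mean_dominant + sign * k * sigma), k, s2
    return None, None, s2


def detect_th2(
    fit: GaussianFitResult, dom: DominantClassInfo, config: Config = DEFAULT_CONFIG
) -> float | None:
    """Valley of the fitted curve between the two component centroids.

    Absent for single-peak fits and when the secondary centroid does not
    lie in the search direction. The minimum is located by a 0.1-degree
    grid scan over the closed inter-centroid interval, refined locally.
    """
    if fit.n_peaks != 2 or not fit.converged:
        return None
    # gate on the non-dominant centroid, label-free: relabeling the two
    # components must not change the outcome
    d1 = abs(fit.b1 - dom.mean_dominant)
    d2 = abs(fit.b2 - dom.mean_dominant)
    other = fit.b2 if d1 <= d2 else fit.b1
    if dom.direction is Direction.INCREASING and other <= dom.mean_dominant:
        return None
    if dom.direction is Direction.DECREASING and other >= dom.mean_dominant:
        return None
    lo, hi = sorted((fit.b1, fit.b2))
    if hi - lo < 1e-9:
        return None
    grid = np.arange(lo, hi + 0.05, 0.1)
    grid = np.clip(grid, lo, hi)
    vals = evaluate_fit(fit, grid)
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    if b - a > 1e-9:
        res = minimize_scalar(
            lambda x: evaluate_fit(fit, float(x)), bounds=(a, b), method="bounded",
            options={"xatol": 1e-6},
        )
        if res.fun <= vals[i]:
            return float(res.x)
    return float(grid[i])


def _walk(h: HueHistogram, dom: DominantClassInfo, config: Config):
    """Surviving (hue, count) pairs from the anchor bin outward in the
    search direction; index 0 is the anchor itself."""
    anchor = (
        dom.main_hue
        if config.walk_anchor == "main_hue"
        else int(round(dom.mean_dominant))
    )
    bins = h.bin_centers
    counts = h.counts
    if dom.direction is Direction.INCREASING:
        sel = bins >= anchor
        order = np.argsort(bins[sel])
    else:
        sel = bins <= anchor
        order = np.argsort(-bins[sel])
    return bins[sel][order], counts[sel][order]


def enumerate_valleys_peaks(
    h: HueHistogram, dom: DominantClassInfo, config: Config = DEFAULT_CONFIG
) -> tuple[list[tuple[int, int, int]], list[tuple[int, int, int]]]:
    """Valleys and peaks along the walk, as (walk position, hue, count).

    A valley (peak) is a surviving bin whose count is strictly below
    (above) both neighbours *in the surviving sequence*; runs of equal
    counts are compared as a unit and contribute their first bin in walk
    order. Valleys and peaks strictly alternate. With fewer than three
    bins on the walk both sequences are empty.
    """
    hues, counts = _walk(h, dom, config)
    n = len(counts)
    if n < 3:
        return [], []
    # compress equal-count runs
    runs = []  # (start_idx, end_idx, count)
    s = 0
    for i in range(1, n + 1):
        if i == n or counts[i] != counts[s]:
            runs.append((s, i - 1, int(counts[s])))
            s = i
    valleys, peaks = [], []
    for j in range(1, len(runs) - 1):
        prev_c, cur, next_c = runs[j - 1][2], runs[j], runs[j + 1][2]
        start, _end, c = cur
        if c < prev_c and c < next_c:
            valleys.append((start, int(hues[start]), c))
        elif c > prev_c and c > next_c:
            peaks.append((start, int(hues[start]), c))
    return valleys, peaks


def _admissible_mean(stops: list[float], config: Config) -> float | None:
    ok = [s for s in stops if config.stop_lo <= s <= config.stop_hi]
    return float(np.mean(ok)) if ok else None


def detect_th3(
    h: HueHistogram, dom: DominantClassInfo, config: Config = DEFAULT_CONFIG
) -> tuple[float | None, list[float]]:
    """Valleys lower than the valley that follows them.

    Every valley whose count is strictly below the next valley's count is
    a stop; stops are filtered to the 30-70 degree window and averaged.
    """
    valleys, _ = enumerate_valleys_peaks(h, dom, config)
    stops = [
        float(valleys[i][1])
        for i in range(len(valleys) - 1)
        if valleys[i][2] < valleys[i + 1][2]
    ]
    return _admissible_mean(stops, config), stops


def detect_th4(
    h: HueHistogram, dom: DominantClassInfo, config: Config = DEFAULT_CONFIG
) -> tuple[float | None, list[float]]:
    """Valleys followed by two successive rises.

    A valley is a stop when the next two surviving bins along the walk
    have strictly increasing counts; survivors of the 30-70 degree window
    are averaged.
    """
    hues, counts = _walk(h, dom, config)
    valleys, _ = enumerate_valleys_peaks(h, dom, config)
    n = len(counts)
    stops = []
    for pos, hue, _c in valleys:
        # rises are counted from the end of the valley's equal-count run
        end = pos
        while end + 1 < n and counts[end + 1] == counts[pos]:
            end += 1
        if end + 2 < n and counts[end] < counts[end + 1] < counts[end + 2]:
            stops.append(float(hue))
    return _admissible_mean(stops, config), stops


def detect_th5(
    h: HueHistogram, dom: DominantClassInfo, config: Config = DEFAULT_CONFIG
) -> tuple[float | None, list[float]]:
    """Lower of the valleys flanking a peak that is lower than the next peak.

    For each peak whose count is strictly below the following peak's, the
    valley immediately before and the one immediately after it (in walk
    order) are compared; the lower-count valley is a stop (the earlier
    one in walk order on a tie). Peaks lacking either flanking valley are
    skipped. Stops are windowed to 30-70 degrees and averaged.
    """
    valleys, peaks = enumerate_valleys_peaks(h, dom, config)
    stops = []
    for i in range(len(peaks) - 1):
        if peaks[i][2] >= peaks[i + 1][2]:
            continue
        pos = peaks[i][0]
        before = [v for v in valleys if v[0] < pos]
        after = [v for v in valleys if v[0] > pos]
        if not before or not after:
            continue
        vb, va = before[-1], after[0]
        stop = vb if vb[2] <= va[2] else va
        stops.append(float(stop[1]))
    return _admissible_mean(stops, config), stops


def combine(
    *,
    th1: float | None,
    th2: float | None,
    th3: float | None,
    th4: float | None,
    th5: float | None,
    th3_stops: list[float],
    th4_stops: list[float],
    th5_stops: list[float],
    chosen_sigma_multiple: int | None,
    s2: float,
    case: CaseType,
    dominant: DominantClassInfo,
    config: Config = DEFAULT_CONFIG,
) -> ThresholdReport:
    """Average the detected candidates into the final threshold."""
    cands = {"th1": th1, "th2": th2, "th3": th3, "th4": th4, "th5": th5}
    if config.bounds_on_all_candidates:
        for k in ("th1", "th2"):
            v = cands[k]
            if v is not None and not (config.stop_lo <= v <= config.stop_hi):
                cands[k] = None
    present = [v for v in cands.values() if v is not None]
    if not present:
        raise ThresholdDetectionError(
            "no candidate threshold detected (all of th1-th5 absent)"
        )
    return ThresholdReport(
        th1=cands["th1"], th2=cands["th2"], th3=cands["th3"],
        th4=cands["th4"], th5=cands["th5"],
        th3_stops=tuple(th3_stops), th4_stops=tuple(th4_stops),
        th5_stops=tuple(th5_stops),
        chosen_sigma_multiple=chosen_sigma_multiple, s2=s2,
        case=case, dominant=dominant,
        final_threshold=float(np.mean(present)),
    )


def detect_threshold(
    fit: GaussianFitResult, h: HueHistogram, config: Config = DEFAULT_CONFIG
) -> ThresholdReport:
    """Run the full candidate detection and combination for one image."""
    dom = classify_dominant(fit, h, config)
    case = classify_case(fit, dom)
    th1, k, s2 = detect_th1(fit, h, dom, config)
    th2 = detect_th2(fit, dom, config)
    th3, stops3 = detect_th3(h, dom, config)
    th4, stops4 = detect_th4(h, dom, config)
    th5, stops5 = detect_th5(h, dom, config)
    return combine(
        th1=th1, th2=th2, th3=th3, th4=th4, th5=th5,
        th3_stops=stops3, th4_stops=stops4, th5_stops=stops5,
        chosen_sigma_multiple=k, s2=s2, case=case, dominant=dom,
        config=config,
    )
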