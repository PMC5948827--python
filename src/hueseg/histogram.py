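"""Hue histogram construction, small-presence filtering and Gaussian fitting.

The hue histogram pairs each integer hue degree with its pixel count.
Filtering removes low-presence bins *from the sequence* (they are not
zeroed), so later valley/peak logic walks consecutive surviving bins.
The filtered histogram is then fitted with a sum of (up to) two Gaussian
terms

    y(x) = sum_i  a_i * exp(-((x - b_i) / c_i)^2)

where ``a`` is the amplitude (pixels), ``b`` the centroid (degrees) and
``c`` the width parameter. Note the exponent carries no factor 1/2: the
model's ``c`` equals sqrt(2) times the standard deviation of an ordinary
normal, so confidence intervals use sigma = c / sqrt(2).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .colorspace import HsvImage
from .config import DEFAULT_CONFIG, Config

__all__ = [
    "HueHistogram",
    "GaussianFitResult",
    "DegenerateHistogramError",
    "build_histogram",
    "filter_histogram",
    "fit_gaussians",
    "evaluate_fit",
    "histogram_to_csv",
    "histogram_from_csv",
]


class DegenerateHistogramError(ValueError):
    """Raised when filtering removes every bin or too few bins survive."""


@dataclass(frozen=True)
class HueHistogram:
    """Ordered (hue bin, pixel count) pairs over integer degrees.

    ``bin_centers[k]`` is the integer degree d of a bin covering
    [d, d+1); ``counts[k]`` is its pixel count. Before filtering the
    counts sum to ``total_pixels``; after filtering some bins are gone
    and the sum may be smaller.
    """

    bin_centers: np.ndarray  # int, strictly increasing
    counts: np.ndarray  # int, >= 0
    total_pixels: int
    filtered: bool = False

    def __post_init__(self):
        if len(self.bin_centers) != len(self.counts):
            raise ValueError("bin_centers and counts length mismatch")
        if len(self.bin_centers) > 1 and not np.all(np.diff(self.bin_centers) > 0):
            raise ValueError("bin_centers must be strictly increasing")
        if int(self.counts.sum()) > self.total_pixels:
            raise ValueError("counts exceed total pixel count")

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    @property
    def main_hue(self) -> int:
        """Hue of the highest-count bin (first one on ties)."""
        return int(self.bin_centers[int(np.argmax(self.counts))])


@dataclass(frozen=True)
class GaussianFitResult:
    """Fitted parameters of the (up to) two-term Gaussian model.

    Components are sorted by amplitude, descending; with ``n_peaks == 1``
    the second triple is NaN. ``converged`` is False when the optimiser
    failed even after restarts, in which case the centroid fields hold a
    raw-histogram peak estimate.
    """

    a1: float
    b1: float
    c1: float
    a2: float
    b2: float
    c2: float
    n_peaks: int
    converged: bool
    residual_norm: float
    halved_exponent: bool = False

    @property
    def sigma1(self) -> float:
        """Standard deviation of the dominant component."""
        return self.c1 if self.halved_exponent else self.c1 / np.sqrt(2.0)


def build_histogram(hsv: HsvImage) -> HueHistogram:
    """Bin the hue plane into 360 one-degree bins ([k, k+1) each)."""
    hue = np.asarray(hsv.hue, dtype=np.float64).ravel()
    idx = np.floor(hue).astype(np.intp)
    idx = np.clip(idx, 0, 359)  # hue == 360.0 cannot occur; guard rounding
    counts = np.bincount(idx, minlength=360)
    return HueHistogram(
        bin_centers=np.arange(360, dtype=np.intp),
        counts=counts.astype(np.int64),
        total_pixels=int(hue.size),
        filtered=False,
    )


def filter_histogram(h: HueHistogram, config: Config = DEFAULT_CONFIG) -> HueHistogram:
    """Drop small-presence bins (count < filter_fraction * total pixels).

    The comparison is strict, so a bin sitting exactly on the cutoff
    survives. Surviving bins keep their original counts; dropped bins are
    removed from the sequence entirely. Idempotent.
    """
    cutoff = config.filter_fraction * h.total_pixels
    # integer counts vs a float cutoff: guard the boundary against
    # representation error in filter_fraction * total (strictly-below rule)
    keep = h.counts >= cutoff - 1e-9 * max(1.0, cutoff)
    # zero-count bins never represent a hue actually present
    keep &= h.counts > 0
    if not np.any(keep):
        raise DegenerateHistogramError(
            "small-presence filter removed every histogram bin"
        )
    return HueHistogram(
        bin_centers=h.bin_centers[keep],
        counts=h.counts[keep],
        total_pixels=h.total_pixels,
        filtered=True,
    )


def _model(x: np.ndarray, params: np.ndarray, halved: bool) -> np.ndarray:
    y = np.zeros_like(x, dtype=np.float64)
    for a, b, c in params.reshape(-1, 3):
        z = (x - b) / c
        y += a * np.exp(-0.5 * z * z if halved else -z * z)
    return y


def _fit_once(x, y, p0, halved):
    def resid(p):
        return _model(x, p, halved) - y

    try:
        sol = least_squares(resid, p0, method="lm", max_nfev=20000)
    except Exception:
        return None
    if not np.all(np.isfinite(sol.x)):
        return None
    p = sol.x.copy()
    p = p.reshape(-1, 3)
    p[:, 2] = np.abs(p[:, 2])  # width sign is a gauge freedom
    return p.ravel(), float(np.linalg.norm(resid(sol.x)))


def _initial_guesses(h: HueHistogram, rng: np.random.Generator, n_restarts: int):
    """Seeded initial parameter vectors: data-driven first, then jittered."""
    x = h.bin_centers.astype(np.float64)
    y = h.counts.astype(np.float64)
    i1 = int(np.argmax(y))
    b1, a1 = x[i1], y[i1]
    far = np.abs(x - b1) >= 30.0
    if np.any(far):
        i2 = int(np.argmax(np.where(far, y, -np.inf)))
        b2, a2 = x[i2], y[i2]
    else:
        b2, a2 = None, None

    base2 = None if b2 is None else np.array([a1, b1, 10.0, a2, b2, 10.0])
    base1 = np.array([a1, b1, 10.0])
    guesses2, guesses1 = [], []
    if base2 is not None:
        guesses2.append(base2)
    guesses1.append(base1)
    for _ in range(n_restarts):
        jit = rng.normal(0.0, 1.0, size=6)
        if base2 is not None:
            g = base2.copy()
            g[[1, 4]] += 5.0 * jit[:2]
            g[[2, 5]] = np.abs(g[[2, 5]] + 4.0 * jit[2:4])
            g[[0, 3]] = np.abs(g[[0, 3]] * (1 + 0.2 * jit[4:6]))
            guesses2.append(g)
        g = base1.copy()
        g[1] += 5.0 * jit[0]
        g[2] = abs(g[2] + 4.0 * jit[1])
        guesses1.append(g)
    return guesses1, guesses2


def fit_gaussians(
    h: HueHistogram, config: Config = DEFAULT_CONFIG
) -> GaussianFitResult:
    """Least-squares fit of the two-term Gaussian model to a filtered histogram.

    Levenberg-Marquardt from a data-driven start (up to ``n_restarts``
    seeded jittered restarts). The two-term solution is kept only when it
    is both substantially better than the one-term fit (SSE ratio below
    ``two_term_sse_ratio``) and plausible: the secondary amplitude is at
    least ``min_secondary_amplitude_frac`` of the dominant one, its
    centroid lies in [0, 360) and its width is below
    ``max_secondary_width``. Otherwise the image is single-peaked.
    """
    if not h.filtered:
        raise ValueError("fit requires a filtered histogram")
    if h.n_bins < 4:
        raise DegenerateHistogramError(
            f"need >= 4 surviving bins to fit, have {h.n_bins}"
        )
    x = h.bin_centers.astype(np.float64)
    y = h.counts.astype(np.float64)
    halved = config.halved_exponent
    rng = np.random.default_rng(config.seed)
    guesses1, guesses2 = _initial_guesses(h, rng, config.n_restarts)

    best1 = best2 = None
    for g in guesses1:
        r = _fit_once(x, y, g, halved)
        if r is not None and (best1 is None or r[1] < best1[1]):
            best1 = r
    for g in guesses2:
        r = _fit_once(x, y, g, halved)
        if r is not None and (best2 is None or r[1] < best2[1]):
            best2 = r

    if best1 is None and best2 is None:
        # optimiser never converged: fall back to raw-histogram peaks
        n_peaks = _raw_peak_count(h)
        i1 = int(np.argmax(y))
        return GaussianFitResult(
            a1=float(y[i1]), b1=float(x[i1]), c1=np.nan,
            a2=np.nan, b2=np.nan, c2=np.nan,
            n_peaks=n_peaks, converged=False,
            residual_norm=np.inf, halved_exponent=halved,
        )

    use_two = False
    if best2 is not None:
        p2 = np.asarray(best2[0]).reshape(2, 3)
        order = np.argsort(-p2[:, 0])
        p2 = p2[order]
        (a1, b1, c1), (a2, b2, c2) = p2
        plausible = (
            a2 >= config.min_secondary_amplitude_frac * a1
            and 0.0 <= b2 < 360.0
            and 0.0 < c2 <= config.max_secondary_width
            and a1 > 0
        )
        if plausible:
            if best1 is None:
                use_two = True
            else:
                sse1, sse2 = best1[1] ** 2, best2[1] ** 2
                use_two = sse2 <= config.two_term_sse_ratio * sse1
    if use_two:
        return GaussianFitResult(
            a1=float(a1), b1=float(b1), c1=float(c1),
            a2=float(a2), b2=float(b2), c2=float(c2),
            n_peaks=2, converged=True,
            residual_norm=float(best2[1]), halved_exponent=halved,
        )
    if best1 is None:
        # two-term converged but implausible and no one-term solution
        p2 = np.asarray(best2[0]).reshape(2, 3)
        a1, b1, c1 = p2[int(np.argmax(p2[:, 0]))]
        return GaussianFitResult(
            a1=float(a1), b1=float(b1), c1=float(c1),
            a2=np.nan, b2=np.nan, c2=np.nan,
            n_peaks=1, converged=True,
            residual_norm=float(best2[1]), halved_exponent=halved,
        )
    a1, b1, c1 = best1[0]
    return GaussianFitResult(
        a1=float(a1), b1=float(b1), c1=float(c1),
        a2=np.nan, b2=np.nan, c2=np.nan,
        n_peaks=1, converged=True,
        residual_norm=float(best1[1]), halved_exponent=halved,
    )


def _raw_peak_count(h: HueHistogram) -> int:
    """Count well-separated local maxima in the surviving bins (1 or 2)."""
    y = h.counts.astype(np.float64)
    if len(y) < 3:
        return 1
    peaks = [
        i for i in range(1, len(y) - 1) if y[i] > y[i - 1] and y[i] > y[i + 1]
    ]
    # consider only peaks at least 5% of the global max and >= 30 deg apart
    peaks = [i for i in peaks if y[i] >= 0.05 * y.max()]
    if len(peaks) < 2:
        return 1
    xs = h.bin_centers[peaks]
    return 2 if (xs.max() - xs.min()) >= 30 else 1


def evaluate_fit(fit: GaussianFitResult, hue) -> np.ndarray | float:
    """Evaluate the fitted model sum_i a_i exp(-((x-b_i)/c_i)^2) at ``hue``."""
    if not fit.converged:
        raise ValueError("cannot evaluate a non-converged fit")
    x = np.asarray(hue, dtype=np.float64)
    params = [fit.a1, fit.b1, fit.c1]
    if fit.n_peaks == 2:
        params += [fit.a2, fit.b2, fit.c2]
    y = _model(x, np.asarray(params), fit.halved_exponent)
    return float(y) if np.isscalar(hue) or x.ndim == 0 else y


def histogram_to_csv(h: HueHistogram, path: str | Path) -> None:
    """Write (bin, count) rows; total pixels recorded in a header comment."""
    with open(path, "w", newline="") as f:
        f.write(f"# total_pixels={h.total_pixels} filtered={int(h.filtered)}\n")
        w = csv.writer(f)
        w.writerow(["bin", "count"])
        for b, c in zip(h.bin_centers, h.counts):
            w.writerow([int(b), int(c)])


def histogram_from_csv(path: str | Path) -> HueHistogram:
    with open(path) as f:
        header = f.readline().strip().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        rows = list(csv.reader(f))[1:]
    bins = np.array([int(r[0]) for r in rows], dtype=np.intp)
    counts = np.array([int(r[1]) for r in rows], dtype=np.int64)
    return HueHistogram(
        bin_centers=bins,
        counts=counts,
        total_pixels=int(meta["total_pixels"]),
        filtered=bool(int(meta["filtered"])),
    )
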