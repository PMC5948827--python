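"""Color-index transforms and Otsu thresholding — the comparison baselines.

The classical route to vegetation segmentation from RGB alone is a scalar
color index per pixel followed by automatic thresholding:

    NDI   = 128 * ((G - R) / (G + R) + 1)
    ExG   = 2g - r - b
    ExR   = 1.3 r - g
    ExGR  = ExG - ExR
    CIVE  = 0.441 R - 0.811 G + 0.385 B + 18.78745
    COM1  = ExG + CIVE + ExGR + VEG
    COM2  = 0.36 ExG + 0.47 CIVE + 0.17 VEG
    NGRDI = (G - R) / (G + R)
    VEG   = g / (r^0.667 * b^0.333)

Lower-case r, g, b are chromatic coordinates (each channel over the
channel sum), the dominant convention for the ExG family; CIVE always
uses raw 8-bit channels since its additive constant presumes that scale.
"""

from __future__ import annotations

import numpy as np

from .colorspace import rgb_to_hsv, validate_rgb
from .config import DEFAULT_CONFIG, Config

__all__ = [
    "INDEX_NAMES",
    "INDEX_POLARITY",
    "compute_index",
    "otsu_threshold",
    "baseline_segment",
]

INDEX_NAMES = (
    "NDI", "ExG", "ExR", "ExGR", "CIVE", "COM1", "COM2", "NGRDI", "VEG",
)

# vegetation side of the threshold: +1 high-index side, -1 low-index side
INDEX_POLARITY = {
    "NDI": 1, "ExG": 1, "ExR": -1, "ExGR": 1, "CIVE": -1,
    "COM1": 1, "COM2": -1, "NGRDI": 1, "VEG": 1, "hue": 1,
}

_EPS = 1e-9


def _channels(img: np.ndarray, chromatic: bool):
    rgb = validate_rgb(img).astype(np.float64)
    R, G, B = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    if not chromatic:
        return R, G, B
    s = R + G + B
    s = np.where(s > 0, s, 1.0)
    return R / s, G / s, B / s


def compute_index(
    img: np.ndarray, name: str, config: Config = DEFAULT_CONFIG
) -> np.ndarray:
    """Evaluate the named color index per pixel (finite everywhere)."""
    if name not in INDEX_NAMES:
        raise ValueError(f"unknown index {name!r}; choose from {INDEX_NAMES}")
    chromatic = config.chromatic_coords
    r, g, b = _channels(img, chromatic)

    if name == "NDI":
        denom = g + r
        ratio = np.where(denom > 0, (g - r) / np.where(denom > 0, denom, 1.0), 0.0)
        return 128.0 * (ratio + 1.0)
    if name == "ExG":
        return 2.0 * g - r - b
    if name == "ExR":
        return config.exr_coefficient * r - g
    if name == "ExGR":
        return compute_index(img, "ExG", config) - compute_index(img, "ExR", config)
    if name == "CIVE":
        R, G, B = _channels(img, chromatic=False)
        return 0.441 * R - 0.811 * G + 0.385 * B + 18.78745
    if name == "VEG":
        rr, gg, bb = _channels(img, chromatic=True)
        return gg / (np.power(rr + _EPS, 0.667) * np.power(bb + _EPS, 0.333))
    if name == "COM1":
        return (
            compute_index(img, "ExG", config)
            + compute_index(img, "CIVE", config)
            + compute_index(img, "ExGR", config)
            + compute_index(img, "VEG", config)
        )
    if name == "COM2":
        return (
            0.36 * compute_index(img, "ExG", config)
            + 0.47 * compute_index(img, "CIVE", config)
            + 0.17 * compute_index(img, "VEG", config)
        )
    # NGRDI
    denom = g + r
    return np.where(denom > 0, (g - r) / np.where(denom > 0, denom, 1.0), 0.0)


def otsu_threshold(gray: np.ndarray, n_levels: int = 256) -> float:
    """Otsu's automatic threshold on a real-valued image.

    The image is quantized to ``n_levels`` over its finite range, and the
    level cut maximizing between-class variance of the two resulting
    pixel groups is returned, mapped back to image units (the upper edge
    of the low class). Ties go to the lowest level.
    """
    x = np.asarray(gray, dtype=np.float64).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("image contains non-finite values")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("constant image: Otsu threshold undefined")
    counts, edges = np.histogram(x, bins=n_levels, range=(lo, hi))
    p = counts.astype(np.float64) / x.size
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = np.where(
            valid, (mu_t * w0 - mu) ** 2 / (w0 * w1), -np.inf
        )
    k = int(np.argmax(var_between))  # argmax takes the lowest level on ties
    if not np.isfinite(var_between[k]):
        raise ValueError("degenerate image: no valid Otsu split")
    return float(edges[k + 1])


def baseline_segment(
    img: np.ndarray, name: str, config: Config = DEFAULT_CONFIG
) -> tuple[np.ndarray, float]:
    """Color-index (or hue) + Otsu segmentation.

    Returns (mask, threshold). ``name`` is a color index or ``"hue"``;
    vegetation lies on the high side of the cut except for CIVE and ExR,
    whose polarity is inverted.
    """
    if name == "hue":
        gray = rgb_to_hsv(img).hue
        t = otsu_threshold(gray, n_levels=360)
    else:
        gray = compute_index(img, name, config)
        t = otsu_threshold(gray, n_levels=256)
    if INDEX_POLARITY[name] > 0:
        mask = np.where(gray > t, 255, 0).astype(np.uint8)
    else:
        mask = np.where(gray <= t, 255, 0).astype(np.uint8)
    return mask, t
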