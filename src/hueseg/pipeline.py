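"""End-to-end segmentation: RGB image in, vegetation mask + report out."""

from __future__ import annotations

import numpy as np

from .baselines import otsu_threshold
from .binarization import binarize
from .colorspace import rgb_to_hsv
from .config import DEFAULT_CONFIG, Config
from .histogram import build_histogram, filter_histogram, fit_gaussians
from .thresholding import (
    ThresholdDetectionError,
    ThresholdReport,
    classify_case,
    classify_dominant,
    combine,
    detect_th1,
    detect_th2,
    detect_th3,
    detect_th4,
    detect_th5,
)

__all__ = ["segment_image", "detect_report"]


def detect_report(img: np.ndarray, config: Config = DEFAULT_CONFIG) -> ThresholdReport:
    """Hue-histogram threshold detection for one RGB image.

    Runs the full chain — HSV conversion, histogram build + filter,
    Gaussian fit, candidate detection, combination — and returns the
    provenance report. Raises ThresholdDetectionError when no candidate
    is found and the Otsu fallback is disabled.
    """
    return _detect_from_hsv(rgb_to_hsv(img), config)


def _detect_from_hsv(hsv, config: Config) -> ThresholdReport:
    hist = filter_histogram(build_histogram(hsv), config)
    fit = fit_gaussians(hist, config)
    dom = classify_dominant(fit, hist, config)
    case = classify_case(fit, dom)
    th1, k, s2 = detect_th1(fit, hist, dom, config)
    th2 = detect_th2(fit, dom, config)
    th3, stops3 = detect_th3(hist, dom, config)
    th4, stops4 = detect_th4(hist, dom, config)
    th5, stops5 = detect_th5(hist, dom, config)
    try:
        return combine(
            th1=th1, th2=th2, th3=th3, th4=th4, th5=th5,
            th3_stops=stops3, th4_stops=stops4, th5_stops=stops5,
            chosen_sigma_multiple=k, s2=s2, case=case, dominant=dom,
            config=config,
        )
    except ThresholdDetectionError:
        if not config.fallback_otsu:
            raise
        t = otsu_threshold(hsv.hue, n_levels=360)
        return ThresholdReport(
            th1=None, th2=None, th3=None, th4=None, th5=None,
            th3_stops=(), th4_stops=(), th5_stops=(),
            chosen_sigma_multiple=None, s2=s2, case=case, dominant=dom,
            final_threshold=float(t), used_fallback=True,
        )


def segment_image(
    img: np.ndarray, config: Config = DEFAULT_CONFIG
) -> tuple[np.ndarray, ThresholdReport]:
    """Segment vegetation in an RGB image; returns (mask, report)."""
    hsv = rgb_to_hsv(img)
    report = _detect_from_hsv(hsv, config)
    mask = binarize(hsv.hue, report, config)
    return mask, report
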