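"""Apply a detected threshold to the hue plane to get the vegetation mask."""

from __future__ import annotations

import numpy as np

from .config import DEFAULT_CONFIG, Config
from .thresholding import Direction, ThresholdReport

__all__ = ["binarize", "binarize_value"]


def binarize_value(
    hue: np.ndarray,
    threshold: float,
    direction: Direction,
    config: Config = DEFAULT_CONFIG,
) -> np.ndarray:
    """Threshold a hue plane into a {0, 255} vegetation mask.

    Walking up the hue axis (soil dominant) vegetation is
    ``threshold < hue <= veg_hue_max``; walking down (vegetation
    dominant) it is ``threshold <= hue <= veg_hue_max``. Either way a
    pixel sitting exactly on the threshold stays with the dominant
    class's side, and hues above ``veg_hue_max`` (magenta/red) are never
    vegetation.
    """
    hue = np.asarray(hue, dtype=np.float64)
    if direction is Direction.INCREASING:
        veg = (hue > threshold) & (hue <= config.veg_hue_max)
    else:
        veg = (hue >= threshold) & (hue <= config.veg_hue_max)
    return np.where(veg, 255, 0).astype(np.uint8)


def binarize(
    hue: np.ndarray, report: ThresholdReport, config: Config = DEFAULT_CONFIG
) -> np.ndarray:
    """Binarize using the final threshold and direction of a report."""
    if report.final_threshold is None:
        raise ValueError("report carries no final threshold")
    return binarize_value(
        hue, report.final_threshold, report.dominant.direction, config
    )
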