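"""Tunable parameters for the segmentation pipeline.

Every knob that the hue-threshold method or a baseline depends on lives in
one frozen dataclass, so a run is fully described by (image, Config, seed)
and two runs with identical settings are bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class Config:
    """Pipeline configuration with field-standard defaults.

    Parameters
    ----------
    filter_fraction : float
        A hue bin whose pixel count is strictly below
        ``filter_fraction * total_pixels`` is removed from the histogram
        (small-presence outlier filter). Default 1e-5, i.e. 0.001 %.
    halved_exponent : bool
        If True the Gaussian model uses exp(-((x-b)/c)^2 / 2) instead of
        the literal exp(-((x-b)/c)^2). Default False: the literal form,
        under which c = sqrt(2)*sigma of a standard normal.
    n_restarts : int
        Jittered re-initialisations of the curve fit before giving up.
    min_secondary_amplitude_frac : float
        The fitted second component is discarded when its amplitude is
        below this fraction of the dominant amplitude.
    max_secondary_width : float
        The second component is discarded when its width parameter c
        exceeds this many degrees (implausibly broad).
    two_term_sse_ratio : float
        The two-term fit is kept only when its residual sum of squares is
        at most this fraction of the one-term fit's; otherwise the image
        is treated as single-peaked.
    veg_boundary : float
        Hue (degrees) splitting non-vegetation from vegetation when
        classifying the dominant class; the boundary itself counts as
        vegetation (green starts at yellow, 60 deg).
    stop_lo, stop_hi : float
        Admissibility window (degrees) for local-minimum stop candidates:
        stops outside [stop_lo, stop_hi] are dropped before averaging.
    bounds_on_all_candidates : bool
        Extend the admissibility window to th1/th2 as well (off by
        default: it applies to the local-minima detectors only).
    s2_from_fit : bool
        Measure the S2 rejection distance to mean +/- 3c of the fitted
        curve instead of to the end of the surviving histogram support.
    walk_anchor : str
        "main_hue" (highest-count surviving bin, default) or
        "mean_dominant": where the valley/peak walk starts.
    veg_hue_max : float
        Upper hue cap (degrees) of the vegetation class; pixels beyond it
        (magenta/red side) are never vegetation.
    fallback_otsu : bool
        When no candidate threshold is detected, fall back to Otsu on the
        hue image instead of raising a detection failure.
    chromatic_coords : bool
        Evaluate ExG-family indices on chromatic coordinates
        r = R/(R+G+B) etc.; raw 8-bit channels when False. CIVE always
        uses raw channels (its additive constant presumes raw scale).
    exr_coefficient : float
        Red weight in ExR = coeff*R - G (1.3 as adopted here; some
        literature uses 1.4).
    seed : int
        Seed for the fit-restart jitter; part of the run identity.
    """

    filter_fraction: float = 1e-5
    halved_exponent: bool = False
    n_restarts: int = 5
    min_secondary_amplitude_frac: float = 0.05
    max_secondary_width: float = 120.0
    two_term_sse_ratio: float = 0.5
    veg_boundary: float = 60.0
    stop_lo: float = 30.0
    stop_hi: float = 70.0
    bounds_on_all_candidates: bool = False
    s2_from_fit: bool = False
    walk_anchor: str = "main_hue"
    veg_hue_max: float = 180.0
    fallback_otsu: bool = False
    chromatic_coords: bool = True
    exr_coefficient: float = 1.3
    seed: int = 0

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_CONFIG = Config()
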