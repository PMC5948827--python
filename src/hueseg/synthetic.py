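"""Seeded synthetic crop-field scenes with exact ground-truth masks.

Real UAV frames of row crops show two hue populations — soil around
20-60 degrees and green canopy around 60-180 — whose relative weight
shifts with growth stage, under saturation/brightness variation that
leaves hue (nearly) untouched. The generator reproduces exactly that
structure: a vegetation support drawn as rows, patches or scattered
plants; per-pixel hue sampled from the class's normal distribution; S
and V drawn uniformly and optionally dimmed by a horizontal illumination
gradient; then HSV rendered to 8-bit RGB. The truth mask is the support
itself, so ground truth is exact by construction.

It does not attempt photorealism: no plant geometry, shadows, or camera
noise beyond 8-bit quantization.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy.ndimage import gaussian_filter

from .colorspace import save_mask

__all__ = [
    "FieldSpec",
    "SyntheticScene",
    "GenerationError",
    "generate",
    "growth_series",
    "irrigated_preset",
    "write_scene",
]

LAYOUTS = ("rows", "patches", "scattered")


class GenerationError(ValueError):
    """Raised for infeasible field specifications."""


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic field scene.

    Defaults put soil at N(40, 8) degrees and vegetation at N(110, 12)
    degrees — a soil peak left of the 60-degree yellow/green boundary
    and canopy mass inside the 60-180 green band — with S in [0.3, 0.9]
    and V in [0.3, 0.95]. ``illumination_gradient`` in [0, 1] dims V
    linearly across the image width (amplitude 1 halves V at the right
    edge) without touching hue.
    """

    height: int = 256
    width: int = 256
    veg_fraction: float = 0.3
    soil_hue_mean: float = 40.0
    soil_hue_sd: float = 8.0
    veg_hue_mean: float = 110.0
    veg_hue_sd: float = 12.0
    sat_range: tuple[float, float] = (0.3, 0.9)
    val_range: tuple[float, float] = (0.3, 0.95)
    layout: str = "rows"
    row_spacing_px: int = 32
    illumination_gradient: float = 0.0
    seed: int = 0
    allow_class_swap: bool = False  # permit hue means violating the 60-deg split

    def __post_init__(self):
        if not 0.0 <= self.veg_fraction <= 1.0:
            raise GenerationError("veg_fraction must lie in [0, 1]")
        if self.layout not in LAYOUTS:
            raise GenerationError(f"layout must be one of {LAYOUTS}")
        if self.height < 1 or self.width < 1:
            raise GenerationError("image must have positive dimensions")
        if self.layout == "rows" and self.veg_fraction > 0 and (
            self.row_spacing_px < 2 or self.row_spacing_px > self.width
        ):
            raise GenerationError(
                "row spacing must be in [2, width] for a rows layout"
            )
        if not self.allow_class_swap:
            if self.veg_hue_mean < 60.0 or self.soil_hue_mean >= 60.0:
                raise GenerationError(
                    "class-consistent spec needs veg hue >= 60 > soil hue "
                    "(set allow_class_swap to override)"
                )

    def replace(self, **kwargs) -> "FieldSpec":
        return dataclasses.replace(self, **kwargs)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FieldSpec":
        d = json.loads(text)
        for k in ("sat_range", "val_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) uint8
    truth: np.ndarray  # (H, W) uint8, {0, 255}
    spec: FieldSpec

    @property
    def truth_fraction(self) -> float:
        return float(np.mean(self.truth == 255))


def _support(spec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Boolean vegetation support with exactly round(f * N) pixels.

    A layout-specific scalar field is ranked and the lowest-valued
    pixels become vegetation, so the target fraction is met exactly up
    to integer rounding regardless of layout.
    """
    H, W = spec.height, spec.width
    n_veg = int(round(spec.veg_fraction * H * W))
    if n_veg == 0:
        return np.zeros((H, W), dtype=bool)
    if n_veg == H * W:
        return np.ones((H, W), dtype=bool)
    x = np.arange(W)[None, :].repeat(H, axis=0).astype(np.float64)
    if spec.layout == "rows":
        field = np.mod(x, spec.row_spacing_px)
    elif spec.layout == "patches":
        field = -gaussian_filter(rng.standard_normal((H, W)), sigma=12.0)
    else:  # scattered
        field = -gaussian_filter(rng.standard_normal((H, W)), sigma=2.5)
    # deterministic sub-pixel tie-break
    field = field + np.linspace(0.0, 1e-6, H * W).reshape(H, W)
    thresh = np.partition(field.ravel(), n_veg - 1)[n_veg - 1]
    support = field <= thresh
    # trim possible over-count from residual ties
    if support.sum() > n_veg:
        extra = np.flatnonzero(support.ravel() & (field.ravel() == thresh))
        drop = extra[n_veg - support.sum():]
        flat = support.ravel()
        flat[drop] = False
        support = flat.reshape(H, W)
    return support


def generate(spec: FieldSpec) -> SyntheticScene:
    """Render one scene; identical specs give bit-identical scenes."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    support = _support(spec, rng)

    hue = np.where(
        support,
        rng.normal(spec.veg_hue_mean, spec.veg_hue_sd, size=(H, W)),
        rng.normal(spec.soil_hue_mean, spec.soil_hue_sd, size=(H, W)),
    )
    hue = np.clip(hue, 0.0, 359.999)
    sat = rng.uniform(*spec.sat_range, size=(H, W))
    val = rng.uniform(*spec.val_range, size=(H, W))
    if spec.illumination_gradient > 0:
        ramp = np.linspace(0.0, 1.0, W)[None, :]
        val = val * (1.0 - 0.5 * spec.illumination_gradient * ramp)
    val = np.clip(val, 0.05, 1.0)

    hsv = np.stack([hue / 360.0, sat, val], axis=-1)
    img = np.round(hsv_to_rgb(hsv) * 255.0).astype(np.uint8)
    truth = np.where(support, 255, 0).astype(np.uint8)
    return SyntheticScene(image=img, truth=truth, spec=spec)


def growth_series(base: FieldSpec, fractions) -> list[SyntheticScene]:
    """One scene per vegetation fraction, seeds derived from the base seed."""
    scenes = []
    for i, f in enumerate(fractions):
        child_seed = (base.seed * 1000003 + 7919 * i) % (2**31)
        scenes.append(generate(base.replace(veg_fraction=float(f), seed=child_seed)))
    return scenes


def irrigated_preset(**overrides) -> FieldSpec:
    """Wet-soil stress preset: soil hue pushed toward the green boundary.

    Irrigated dark soil shifts the soil hue population up toward 60-80
    degrees, eroding the separation the method relies on — the regime
    where hue thresholding degrades on real fields.
    """
    kwargs = dict(
        soil_hue_mean=70.0, soil_hue_sd=10.0, allow_class_swap=True
    )
    kwargs.update(overrides)
    return FieldSpec(**kwargs)


def write_scene(scene: SyntheticScene, directory: str | Path, stem: str) -> None:
    """Write image PNG + mask PNG + spec JSON as <stem>.png/_mask.png/.json."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / f"{stem}.png", scene.image)
    save_mask(scene.truth, directory / f"{stem}_mask.png")
    (directory / f"{stem}.json").write_text(scene.spec.to_json())
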