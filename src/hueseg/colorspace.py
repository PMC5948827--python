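"""Raster I/O and the RGB -> HSV transform.

Images are plain numpy arrays: an RGB image is an (H, W, 3) uint8 array, a
binary mask an (H, W) uint8 array with values {0, 255} (255 = vegetation).
The HSV representation keeps hue in *degrees* [0, 360) because every
threshold in this method is an integer degree value; saturation and value
are floats in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "HsvImage",
    "load_rgb",
    "save_mask",
    "load_mask",
    "rgb_to_hsv",
    "validate_rgb",
    "validate_mask",
]


@dataclass(frozen=True)
class HsvImage:
    """Per-channel HSV planes of an RGB image.

    hue: degrees in [0, 360); saturation, value: fractions in [0, 1].
    All three share the spatial shape of the source image.
    """

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        if not (self.hue.shape == self.saturation.shape == self.value.shape):
            raise ValueError("HSV planes must share one spatial shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hue.shape


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check an array is a valid H x W x 3 8-bit RGB raster."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise ValueError("RGB image must be 8-bit (values in [0, 255])")
    return img


def validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected (H, W) mask, got shape {mask.shape}")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 255))):
        raise ValueError("mask values must be 0 or 255")
    return mask.astype(np.uint8)


def load_rgb(path: str | Path, *, strip_alpha: bool = True) -> np.ndarray:
    """Load a PNG/JPEG/TIFF raster as an (H, W, 3) uint8 RGB array.

    16-bit inputs are rescaled to 8-bit (divide by 257, round). RGBA
    inputs are alpha-stripped when ``strip_alpha`` is set, rejected
    otherwise; single-channel inputs are always rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = iio.imread(path)
    if img.dtype == np.uint16:
        img = np.round(img / 257.0).astype(np.uint8)
    if img.ndim == 2:
        raise ValueError(f"{path}: single-channel image is not an RGB input")
    if img.ndim == 3 and img.shape[2] == 4:
        if not strip_alpha:
            raise ValueError(f"{path}: RGBA input and alpha stripping disabled")
        img = img[:, :, :3]
    return validate_rgb(img)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0, 255} vegetation mask as a single-channel 8-bit PNG."""
    mask = validate_mask(mask)
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    iio.imwrite(path, mask)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a single-channel {0, 255} mask PNG."""
    img = iio.imread(Path(path))
    if img.ndim == 3:
        img = img[:, :, 0]
    return validate_mask(img)


def rgb_to_hsv(img: np.ndarray) -> HsvImage:
    """Convert an 8-bit RGB image to hue/saturation/value planes.

    Channels are first normalised to [0, 1]; with M = max(R', G', B'),
    m = min(R', G', B') and chroma C = M - m:

        H = 0 when C = 0, else 60 deg * (((G'-B')/C) mod 6)  when M = R'
                           60 deg * ((B'-R')/C + 2)          when M = G'
                           60 deg * ((R'-G')/C + 4)          when M = B'
        S = 0 when M = 0, else C / M
        V = M

    Achromatic pixels (C = 0) therefore land at H = 0 and fall in the
    non-vegetation hue region by construction.
    """
    img = validate_rgb(img)
    rgb = img.astype(np.float64) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]

    M = np.max(rgb, axis=-1)
    m = np.min(rgb, axis=-1)
    C = M - m

    safe_c = np.where(C > 0, C, 1.0)
    h = np.zeros_like(M)
    # branch order matters only for ties; numpy where-chains resolve ties
    # toward the first matching branch (R', then G', then B'), and tied
    # maxima give identical hue under all matching branches anyway.
    is_r = (M == r) & (C > 0)
    is_g = (M == g) & (C > 0) & ~is_r
    is_b = (C > 0) & ~is_r & ~is_g
    h = np.where(is_r, np.mod((g - b) / safe_c, 6.0), h)
    h = np.where(is_g, (b - r) / safe_c + 2.0, h)
    h = np.where(is_b, (r - g) / safe_c + 4.0, h)
    h = 60.0 * h

    s = np.where(M > 0, C / np.where(M > 0, M, 1.0), 0.0)
    return HsvImage(hue=h, saturation=s, value=M)
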