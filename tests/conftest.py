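import numpy as np
import pytest

from hueseg.histogram import HueHistogram
from hueseg.thresholding import Direction, DominantClassInfo


def make_hist(bins, counts, total=None, filtered=True) -> HueHistogram:
    """Hand-built histogram for thresholding tests."""
    bins = np.asarray(bins, dtype=np.intp)
    counts = np.asarray(counts, dtype=np.int64)
    if total is None:
        total = int(counts.sum())
    return HueHistogram(bins, counts, total, filtered=filtered)


def make_dom(main_hue, direction=Direction.INCREASING, mean=None) -> DominantClassInfo:
    veg = direction is Direction.DECREASING
    return DominantClassInfo(
        mean_dominant=float(main_hue if mean is None else mean),
        main_hue=int(main_hue),
        dominant_class="vegetation" if veg else "non_vegetation",
        direction=direction,
    )


def random_filtered_hist(rng, hue_span=(0, 180)):
    """Random surviving-bin histogram plus a consistent dominant-class info."""
    n = int(rng.integers(8, 50))
    bins = np.sort(rng.choice(np.arange(*hue_span), size=n, replace=False))
    counts = rng.integers(1, 40, size=n).astype(np.int64)
    hist = make_hist(bins, counts)
    direction = Direction.INCREASING if rng.random() < 0.5 else Direction.DECREASING
    return hist, make_dom(hist.main_hue, direction)


@pytest.fixture(scope="session")
def default_scene():
    from hueseg.synthetic import FieldSpec, generate

    return generate(FieldSpec(height=192, width=192, veg_fraction=0.4, seed=11))
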