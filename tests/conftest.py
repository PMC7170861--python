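import numpy as np
import pytest

from chemoquant import GradientAxis, Track


@pytest.fixture
def x_axis() -> GradientAxis:
    return GradientAxis(np.array([1.0, 0.0]))


def make_track(xy, dt=1.0, id="t0", group="g", volume=None) -> Track:
    """Build a Track from a list of (x, y) points at uniform time spacing."""
    xy = np.asarray(xy, dtype=float)
    t = np.arange(len(xy)) * dt
    return Track(id=id, group=group, points=np.column_stack([t, xy]), volume=volume)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_blob_mask(rng, size=96, sigma=6.0, min_pixels=200) -> np.ndarray:
    """Random single-component blob mask via thresholded smoothed noise."""
    from scipy import ndimage

    while True:
        noise = rng.normal(size=(size, size))
        smooth = ndimage.gaussian_filter(noise, sigma)
        mask = smooth > np.quantile(smooth, 0.85)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        if n == 0:
            continue
        sizes = ndimage.sum(mask, labels, range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
        mask = ndimage.binary_fill_holes(mask)
        # keep away from the border so erosion-based perimeters are clean
        mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        if n != 1:
            continue
        if mask.sum() >= min_pixels:
            return mask
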