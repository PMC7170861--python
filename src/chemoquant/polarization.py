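"""Front-rear polarization quantification from segmented single-cell images.

Coordinate convention: pixel centers sit at integer coordinates, origin at
the top-left pixel, x increasing rightward (columns), y increasing downward
(rows). Centroids are reported as (x, y).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import ComputationError, InputError, ParameterError

__all__ = [
    "CellImage",
    "PolarizationResult",
    "AspectRatioRecord",
    "object_centroid",
    "signal_centroid",
    "polarization_index",
    "centroid_displacement_um",
    "analyze_polarization",
    "aspect_ratio",
    "classify_polarization",
    "percent_polarized",
]

_FULL = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass
class CellImage:
    """A segmented cell: binary mask, aligned intensity channels, pixel size.

    ``source_direction`` is the in-plane unit vector pointing toward the
    chemoattractant source, in (dx, dy) image coordinates (y downward); any
    non-zero vector is normalized on construction.
    """

    mask: np.ndarray
    channels: Mapping[str, np.ndarray]
    pixel_size: float
    source_direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask).astype(bool)
        if m.ndim != 2 or not m.any():
            raise InputError("mask must be a non-empty 2-D binary grid")
        n_comp = ndimage.label(m, structure=_FULL)[1]
        if n_comp != 1:
            raise InputError(f"mask must be one 8-connected object, found {n_comp}")
        self.mask = m
        chans = {}
        for name, arr in dict(self.channels).items():
            a = np.asarray(arr, dtype=float)
            if a.shape != m.shape:
                raise InputError(
                    f"channel {name!r} shape {a.shape} != mask shape {m.shape}"
                )
            chans[name] = a
        self.channels = chans
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if self.source_direction is not None:
            d = np.asarray(self.source_direction, dtype=float)
            if d.shape != (2,) or not np.all(np.isfinite(d)):
                raise ParameterError("source_direction must be a finite 2-vector")
            n = float(np.linalg.norm(d))
            if n < 1e-12:
                raise ParameterError("source_direction must be non-zero")
            self.source_direction = d / n


@dataclass(frozen=True)
class PolarizationResult:
    """Centroid-displacement polarization readout for one cell.

    ``index`` is the verbatim coordinate-ratio formula
    1 - |(X_signal/X_object) * (Y_signal/Y_object)| and is therefore
    origin-dependent and unclamped (it can be negative).
    ``displacement_um`` is the translation-invariant companion metric
    ||signal_centroid - object_centroid|| * pixel_size — NOT the same
    quantity, provided for sanity checks.
    """

    object_centroid: tuple[float, float]
    signal_centroid: tuple[float, float]
    index: float
    displacement_um: float


@dataclass(frozen=True)
class AspectRatioRecord:
    ar: float
    classification: str
    in_focus: bool = True


def object_centroid(image: CellImage) -> tuple[float, float]:
    """Unweighted mean (x, y) of the mask pixel coordinates."""
    rows, cols = np.nonzero(image.mask)
    return float(cols.mean()), float(rows.mean())


def signal_centroid(image: CellImage, channel: str) -> tuple[float, float]:
    """Intensity-weighted centroid (x, y) of a channel over the mask."""
    if channel not in image.channels:
        raise InputError(f"channel {channel!r} not present")
    rows, cols = np.nonzero(image.mask)
    w = image.channels[channel][rows, cols]
    total = float(w.sum())
    if total <= 0:
        raise ComputationError("total masked intensity is zero")
    return float((cols * w).sum() / total), float((rows * w).sum() / total)


def polarization_index(
    object_c: Sequence[float], signal_c: Sequence[float]
) -> float:
    """Coordinate-ratio polarization index, computed verbatim.

    index = 1 - |(X_signal / X_object) * (Y_signal / Y_object)|.

    The formula divides by the object-centroid coordinates, so it depends on
    the image origin and can be negative; both properties are preserved
    deliberately. Zero object coordinates raise, since the ratio is then
    undefined.
    """
    xo, yo = float(object_c[0]), float(object_c[1])
    xs, ys = float(signal_c[0]), float(signal_c[1])
    if xo == 0 or yo == 0:
        raise ComputationError(
            "object centroid has a zero coordinate; the coordinate-ratio index "
            "is origin-dependent and undefined there"
        )
    return 1.0 - abs((xs / xo) * (ys / yo))


def centroid_displacement_um(
    image: CellImage, object_c: Sequence[float], signal_c: Sequence[float]
) -> float:
    """Translation-invariant centroid offset in um (companion metric)."""
    dx = float(signal_c[0]) - float(object_c[0])
    dy = float(signal_c[1]) - float(object_c[1])
    return float(np.hypot(dx, dy)) * image.pixel_size


def analyze_polarization(image: CellImage, channel: str) -> PolarizationResult:
    """Object + signal centroids, ratio index, and displacement for one cell."""
    oc = object_centroid(image)
    sc = signal_centroid(image, channel)
    return PolarizationResult(
        object_centroid=oc,
        signal_centroid=sc,
        index=polarization_index(oc, sc),
        displacement_um=centroid_displacement_um(image, oc, sc),
    )


def aspect_ratio(image: CellImage) -> float:
    """Minor/major axis ratio of the mask's moment-equivalent ellipse, in (0, 1].

    Higher values mean rounder cells, matching the imaging-flow-cytometry
    score orientation; invert for the opposite convention.
    """
    if int(image.mask.sum()) < 5:
        raise InputError("mask needs >= 5 pixels for a stable moment ellipse")
    props = measure.regionprops(image.mask.astype(np.uint8))[0]
    major = props.axis_major_length
    minor = props.axis_minor_length
    if major <= 0 or minor <= 0:
        raise ComputationError("degenerate (collinear) mask: zero minor axis")
    return float(min(minor / major, 1.0))


def classify_polarization(ar: float, low: float = 0.5, high: float = 0.8) -> str:
    """Gate an aspect-ratio score: < low -> polarized, > high -> unpolarized."""
    if not (0 < ar <= 1):
        raise InputError(f"aspect ratio must be in (0, 1], got {ar}")
    if not (low < high):
        raise ParameterError("low threshold must be < high threshold")
    if ar < low:
        return "polarized"
    if ar > high:
        return "unpolarized"
    return "intermediate"


def percent_polarized(records: Iterable[AspectRatioRecord]) -> dict[str, float]:
    """Class percentages over in-focus records; the three classes sum to 100."""
    counts = {"polarized": 0, "unpolarized": 0, "intermediate": 0}
    total = 0
    for rec in records:
        if not rec.in_focus:
            continue
        if rec.classification not in counts:
            raise InputError(f"unknown classification {rec.classification!r}")
        counts[rec.classification] += 1
        total += 1
    if total == 0:
        raise InputError("no in-focus records")
    return {k: 100.0 * v / total for k, v in counts.items()}
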