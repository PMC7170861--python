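"""Live-cell membrane-biosensor quantification.

Per frame, the readout is the mean intensity over the source-facing half of
the cell perimeter divided by the mean intensity over the source-facing half
of the cell area; per cell, the time series of that ratio is reported
relative to the frame at stimulation onset (t = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ComputationError, InputError, ParameterError
from .polarization import CellImage, object_centroid
from .tracks import GroupSummary, summarize_group

__all__ = [
    "BiosensorFrame",
    "BiosensorSeries",
    "front_partition",
    "pip3_ratio",
    "relative_series",
    "group_mean_series",
]

_FULL = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BiosensorFrame:
    """One time point: a segmented cell image plus seconds since stimulation."""

    image: CellImage
    t: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise InputError("frame time must be >= 0 seconds")
        if self.image.source_direction is None:
            raise InputError("biosensor frames require image.source_direction")


@dataclass(frozen=True)
class BiosensorSeries:
    """Time-ordered frames with per-frame ratios and baseline-relative values."""

    frames: tuple[BiosensorFrame, ...] = ()
    ratios: tuple[float, ...] = ()
    relative: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.frames:
            times = [f.t for f in self.frames]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise InputError("frame times must be strictly increasing")
        if self.relative is not None and self.relative:
            if not math.isclose(self.relative[0], 1.0, rel_tol=1e-12):
                raise InputError("relative series must start at 1")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([f.t for f in self.frames], dtype=float)


def _perimeter_band(mask: np.ndarray, band: int) -> np.ndarray:
    """Boundary band: mask pixels within ``band`` erosions of the background.

    A pixel is in the 1-pixel band iff any of its 8 neighbours (or the image
    border) is background.
    """
    eroded = ndimage.binary_erosion(mask, structure=_FULL, iterations=band,
                                    border_value=0)
    return mask & ~eroded


def front_partition(
    image: CellImage, band: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Split the cell into its source-facing halves.

    Every mask pixel gets the projection score (p - object_centroid) .
    source_direction; the front area is the top ceil(area/2) mask pixels by
    score and the front perimeter the top ceil(perimeter/2) boundary-band
    pixels, with score ties broken by ascending row-major pixel index.

    Returns
    -------
    front_area, front_perimeter : (n, 2) int arrays of (row, col) coordinates.
    """
    if image.source_direction is None:
        raise InputError("front_partition requires image.source_direction")
    if band < 1:
        raise ParameterError("perimeter band width must be >= 1")
    cx, cy = object_centroid(image)
    dx, dy = image.source_direction

    def top_half(sel: np.ndarray) -> np.ndarray:
        rows, cols = np.nonzero(sel)
        score = (cols - cx) * dx + (rows - cy) * dy
        flat = rows * sel.shape[1] + cols
        order = np.lexsort((flat, -score))
        k = math.ceil(len(rows) / 2)
        keep = order[:k]
        return np.column_stack([rows[keep], cols[keep]])

    perim = _perimeter_band(image.mask, band)
    return top_half(image.mask), top_half(perim)


def pip3_ratio(
    frame: BiosensorFrame, channel: str, mode: str = "mean", band: int = 1
) -> float:
    """Front perimeter intensity over front area intensity for one frame.

    ``mode="mean"`` (default) uses mean pixel intensities, making the ratio
    dimensionless and cell-size independent; ``mode="sum"`` uses integrated
    intensities.
    """
    if mode not in ("mean", "sum"):
        raise ParameterError(f"unknown intensity mode {mode!r}")
    img = frame.image
    if channel not in img.channels:
        raise InputError(f"channel {channel!r} not present")
    area_px, perim_px = front_partition(img, band=band)
    chan = img.channels[channel]
    area_i = chan[area_px[:, 0], area_px[:, 1]]
    perim_i = chan[perim_px[:, 0], perim_px[:, 1]]
    num = perim_i.sum() if mode == "sum" else perim_i.mean()
    den = area_i.sum() if mode == "sum" else area_i.mean()
    if den <= 0:
        raise ComputationError("front-area intensity is zero; ratio undefined")
    return float(num / den)


def relative_series(
    series: BiosensorSeries | Sequence[BiosensorFrame],
    channel: str,
    mode: str = "mean",
    band: int = 1,
) -> BiosensorSeries:
    """Compute per-frame ratios and express them relative to the t=0 baseline.

    Accepts either a frame sequence or a series whose ratios are already
    filled (frames may then be empty); relative[k] = ratio[k] / ratio[0].
    """
    if isinstance(series, BiosensorSeries):
        frames = series.frames
        ratios = list(series.ratios)
    else:
        frames = tuple(series)
        ratios = []
    if not ratios:
        ratios = [pip3_ratio(f, channel, mode=mode, band=band) for f in frames]
    if not ratios:
        raise InputError("empty series")
    baseline = ratios[0]
    if baseline <= 0:
        raise ComputationError("baseline (t=0) ratio is zero; relative series undefined")
    rel = tuple(r / baseline for r in ratios)
    return BiosensorSeries(frames=frames, ratios=tuple(ratios), relative=rel)


def group_mean_series(series_set: Sequence[BiosensorSeries]) -> pd.DataFrame:
    """Per-timepoint mean +/- s.e.m. across cells, using the relative values.

    All series must share one time grid (or, when frames are absent, one
    length). Returns a DataFrame with columns t, n, mean, sem.
    """
    if not series_set:
        raise InputError("no series given")
    values = []
    for s in series_set:
        v = s.relative if s.relative is not None else s.ratios
        values.append(np.asarray(v, dtype=float))
    lengths = {len(v) for v in values}
    if len(lengths) != 1:
        raise InputError("series lengths differ; shared time grid required")
    if series_set[0].frames:
        grid = series_set[0].times
        for s in series_set[1:]:
            if len(s.frames) != len(grid) or not np.allclose(s.times, grid):
                raise InputError("series time grids differ")
        times = grid
    else:
        times = np.arange(lengths.pop(), dtype=float)
    mat = np.vstack(values)
    rows = []
    for j, t in enumerate(times):
        summ: GroupSummary = summarize_group(mat[:, j], group=f"t={t:g}")
        rows.append({"t": float(t), "n": summ.n, "mean": summ.mean, "sem": summ.sem})
    return pd.DataFrame(rows)
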