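"""File readers/writers for the pipeline's plain-text and TIFF dialects.

Track CSV header: ``track_id,frame,t_min,x_um,y_um,volume_um3,group``
(volume_um3 may be empty). Isotherm CSV: ``conc_uM,response_RU``. Kinase
CSV: ``conc_uM,activity``. Cell images: multi-page TIFF (page 1 = 0/1 mask,
pages 2+ = intensity channels) with a JSON sidecar carrying pixel size,
channel names, source direction and frame time.

All writes are atomic: data goes to a temp file in the target directory and
is renamed into place, so interrupted runs never leave truncated tables.
Numeric CSV output is repr-faithful (full precision).
"""

from __future__ import annotations

import csv
import json
import logging
import math
import os
import tempfile
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile

from .binding import Isotherm
from .errors import FormatError, ValidationError
from .polarization import CellImage
from .tracks import Track

logger = logging.getLogger(__name__)

__all__ = [
    "atomic_write",
    "write_tracks",
    "read_tracks",
    "write_cell_image",
    "read_cell_image",
    "write_isotherm",
    "read_isotherm",
    "read_kinase_table",
    "write_json",
]

TRACK_COLUMNS = ["track_id", "frame", "t_min", "x_um", "y_um", "volume_um3", "group"]


class atomic_write:
    """Context manager yielding a temp path that is renamed onto ``path`` on success."""

    def __init__(self, path: str | os.PathLike, mode: str = "w"):
        self.path = Path(path)
        self.mode = mode
        self._tmp: Path | None = None

    def __enter__(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        fd, tmp = tempfile.mkstemp(dir=self.path.parent, prefix=f".{self.path.name}.")
        os.close(fd)
        self._tmp = Path(tmp)
        return self._tmp

    def __exit__(self, exc_type, exc, tb):
        assert self._tmp is not None
        if exc_type is None:
            os.replace(self._tmp, self.path)
        else:
            self._tmp.unlink(missing_ok=True)
        return False


def _fmt(x: float) -> str:
    return repr(float(x))


def write_tracks(tracks: Sequence[Track], path: str | os.PathLike) -> None:
    with atomic_write(path) as tmp:
        with open(tmp, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(TRACK_COLUMNS)
            for tr in tracks:
                vol = _fmt(tr.volume) if tr.volume is not None else ""
                for frame, (t, x, y) in enumerate(tr.points):
                    w.writerow([tr.id, frame, _fmt(t), _fmt(x), _fmt(y), vol, tr.group])


def read_tracks(path: str | os.PathLike) -> list[Track]:
    """Read a track CSV; one Track per distinct track_id, points ordered by time.

    Malformed rows are reported with their 1-based line numbers; a
    non-increasing timestamp within a track raises naming the track.
    """
    path = Path(path)
    try:
        header = pd.read_csv(path, nrows=0).columns.tolist()
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file without header") from None
    missing = [c for c in TRACK_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = pd.read_csv(path, dtype={"track_id": str, "group": str})
    if df.empty:
        logger.warning("%s: no track rows", path)
        return []
    bad_lines = []
    for col in ("t_min", "x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | ~np.isfinite(vals)]
        bad_lines.extend(int(i) + 2 for i in bad)  # +2: header + 1-based
        df[col] = vals
    if bad_lines:
        raise ValidationError(
            f"{path}: malformed numeric values at line(s) {sorted(set(bad_lines))}"
        )
    tracks = []
    for tid, sub in df.groupby("track_id", sort=False):
        sub = sub.sort_values("t_min", kind="stable")
        t = sub["t_min"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"{path}: track {tid!r} has duplicated or non-increasing timestamps"
            )
        vol_raw = sub["volume_um3"].iloc[0]
        vol = None if pd.isna(vol_raw) else float(vol_raw)
        tracks.append(
            Track(
                id=str(tid),
                group=str(sub["group"].iloc[0]),
                points=np.column_stack([t, sub["x_um"].to_numpy(),
                                        sub["y_um"].to_numpy()]),
                volume=vol,
            )
        )
    return tracks


def write_cell_image(
    image: CellImage, path: str | os.PathLike, t: float | None = None
) -> None:
    """Multi-page TIFF (mask, then channels) + ``<path>.json`` sidecar."""
    path = Path(path)
    names = list(image.channels)
    pages = [image.mask.astype(np.uint8)] + [
        image.channels[n].astype(np.float32) for n in names
    ]
    with atomic_write(path) as tmp:
        tifffile.imwrite(tmp, pages)
    meta = {
        "pixel_size_um": image.pixel_size,
        "channels": names,
        "source_direction": (
            None
            if image.source_direction is None
            else [float(v) for v in image.source_direction]
        ),
        "t_s": t,
    }
    write_json(meta, path.with_suffix(path.suffix + ".json"))


def read_cell_image(path: str | os.PathLike) -> tuple[CellImage, float | None]:
    """Read a TIFF + sidecar pair; returns (image, frame time or None)."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    pages = np.asarray(pages)
    if pages.ndim == 2:
        raise FormatError(f"{path}: expected multi-page TIFF (mask + channels)")
    names = meta["channels"]
    if pages.shape[0] != len(names) + 1:
        raise FormatError(
            f"{path}: {pages.shape[0]} pages but sidecar lists {len(names)} channels"
        )
    src = meta.get("source_direction")
    image = CellImage(
        mask=pages[0] > 0,
        channels={n: pages[i + 1].astype(float) for i, n in enumerate(names)},
        pixel_size=float(meta["pixel_size_um"]),
        source_direction=None if src is None else np.asarray(src, dtype=float),
    )
    return image, meta.get("t_s")


def write_isotherm(iso: Isotherm, path: str | os.PathLike) -> None:
    with atomic_write(path) as tmp:
        with open(tmp, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["conc_uM", "response_RU"])
            for c, r in zip(iso.concentrations, iso.responses):
                w.writerow([_fmt(c), _fmt(r)])


def read_isotherm(path: str | os.PathLike, label: str = "") -> Isotherm:
    df = pd.read_csv(path)
    for col in ("conc_uM", "response_RU"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return Isotherm(
        concentrations=df["conc_uM"].to_numpy(float),
        responses=df["response_RU"].to_numpy(float),
        label=label or Path(path).stem,
    )


def read_kinase_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("conc_uM", "activity"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df


def write_json(obj, path: str | os.PathLike) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with atomic_write(path) as tmp:
        tmp.write_text(json.dumps(obj, indent=2, default=default) + "\n")
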