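"""Migration-track quantification.

Implements the chamber-slide migration readouts: per-track path length,
velocity (total path / duration, in um/min), directionality (cosine of the
angle between the net start-to-end displacement and the gradient axis,
a.k.a. meandering index, in [-1, 1]), exclusion filters (small objects,
static cells, short tracks), analysis-window selection, group summaries
(mean +/- s.e.m.) and two-group comparisons (rank-sum / t-test), plus the
transwell induced-migration subtraction and reference-group normalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, InputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "Track",
    "GradientAxis",
    "TrackMetrics",
    "FilterCriteria",
    "GroupSummary",
    "path_length",
    "net_displacement",
    "velocity",
    "directionality",
    "track_metrics",
    "filter_tracks",
    "select_analysis_window",
    "summarize_group",
    "compare_groups",
    "induced_transmigration",
    "normalize_to_reference",
]


@dataclass(frozen=True)
class Track:
    """A tracked cell centroid trajectory.

    Parameters
    ----------
    id : str
        Track identifier, unique within a recording.
    group : str
        Experimental group label (e.g. genotype).
    points : (n, 3) ndarray
        Columns are time (minutes), x (um), y (um); time strictly
        increasing, n >= 2.
    volume : float, optional
        Mean segmented object volume in um^3, when the upstream tracker
        provides one. ``None`` disables the volume filter for this track.
    """

    id: str
    group: str
    points: np.ndarray
    volume: float | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InputError(f"track {self.id}: points must be (n, 3), got {pts.shape}")
        if pts.shape[0] < 2:
            raise InputError(f"track {self.id}: needs >= 2 points, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise InputError(f"track {self.id}: non-finite coordinates")
        if not np.all(np.diff(pts[:, 0]) > 0):
            raise InputError(f"track {self.id}: time must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def t(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, 1:3]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class GradientAxis:
    """Unit vector pointing from the cell region toward the attractant source.

    Any non-zero vector is accepted and normalized on construction.
    """

    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (2,) or not np.all(np.isfinite(d)):
            raise InputError("gradient axis must be a finite 2-vector")
        n = float(np.linalg.norm(d))
        if n < 1e-12:
            raise InputError("gradient axis must be non-zero")
        object.__setattr__(self, "direction", d / n)


@dataclass(frozen=True)
class TrackMetrics:
    """Per-track scalar metrics. ``dmi`` is NaN when net displacement is 0."""

    track_id: str
    group: str
    path_length: float
    duration: float
    velocity: float
    net_displacement: float
    dmi: float


@dataclass(frozen=True)
class FilterCriteria:
    """Track exclusion thresholds.

    ``min_path_length`` applies to total path length (the tracker's notion of
    track length); set ``min_path_length`` on net displacement instead by
    pre-computing it if the displacement interpretation is wanted.
    """

    min_volume: float = 16.0
    min_path_length: float = 50.0
    static_displacement_threshold: float = 2.0
    target_duration: float = 60.0
    duration_tolerance: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "min_volume",
            "min_path_length",
            "static_displacement_threshold",
            "target_duration",
            "duration_tolerance",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float


# ---------------------------------------------------------------------------
# per-track metrics


def path_length(track: Track) -> float:
    """Total path length: sum of Euclidean distances between consecutive points."""
    steps = np.diff(track.xy, axis=0)
    return float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))


def net_displacement(track: Track) -> float:
    """Straight-line distance between the first and last point."""
    d = track.xy[-1] - track.xy[0]
    return float(np.hypot(d[0], d[1]))


def velocity(track: Track) -> float:
    """Mean speed along the total path, um/min."""
    dur = track.duration
    if dur <= 0:
        raise InputError(f"track {track.id}: zero duration")
    return path_length(track) / dur


def directionality(track: Track, axis: GradientAxis, method: str = "cosine") -> float:
    """Directionality index of a track relative to the gradient axis.

    ``method="cosine"`` (default) is the cosine of the angle between the net
    start-to-end displacement and the axis: 1 = straight toward the source,
    -1 = straight away. ``method="sine_bearing"`` is the sine of the bearing
    angle, with the bearing measured from the axis normal toward the axis —
    under that convention sin(bearing) == cos(migration angle), so the two
    readouts coincide; the option exists to make the convention explicit.

    Returns NaN when the net displacement is zero (undefined direction).
    """
    if method not in ("cosine", "sine_bearing"):
        raise ParameterError(f"unknown directionality method {method!r}")
    disp = track.xy[-1] - track.xy[0]
    norm = float(np.hypot(disp[0], disp[1]))
    if norm < 1e-300:
        return float("nan")
    return float(np.dot(disp, axis.direction) / norm)


def track_metrics(track: Track, axis: GradientAxis) -> TrackMetrics:
    """Bundle all per-track metrics into one record."""
    pl = path_length(track)
    dur = track.duration
    return TrackMetrics(
        track_id=track.id,
        group=track.group,
        path_length=pl,
        duration=dur,
        velocity=pl / dur,
        net_displacement=net_displacement(track),
        dmi=directionality(track, axis),
    )


# ---------------------------------------------------------------------------
# filtering / selection

_DEFAULT_ORDER = ("volume", "static", "short")


def filter_tracks(
    tracks: Sequence[Track],
    criteria: FilterCriteria = FilterCriteria(),
    order: Sequence[str] = _DEFAULT_ORDER,
) -> tuple[list[Track], pd.DataFrame]:
    """Partition tracks into retained and rejected.

    A track is rejected with the first applicable reason in ``order``:
    ``volume`` (object volume < min_volume; skipped with a warning when the
    track carries no volume), ``static`` (net displacement below the static
    threshold), ``short`` (path length < min_path_length). Idempotent on the
    retained set.

    Returns
    -------
    retained : list of Track
    rejections : DataFrame with columns ``id``, ``reason``
    """
    unknown = set(order) - set(_DEFAULT_ORDER)
    if unknown:
        raise ParameterError(f"unknown filter rule(s): {sorted(unknown)}")
    retained: list[Track] = []
    rej_ids: list[str] = []
    rej_reasons: list[str] = []
    warned_volume = False
    for tr in tracks:
        reason = None
        for rule in order:
            if rule == "volume":
                if tr.volume is None:
                    if not warned_volume:
                        logger.warning(
                            "track %s has no volume; volume filter skipped", tr.id
                        )
                        warned_volume = True
                elif tr.volume < criteria.min_volume:
                    reason = "volume"
            elif rule == "static":
                if net_displacement(tr) < criteria.static_displacement_threshold:
                    reason = "static"
            elif rule == "short":
                if path_length(tr) < criteria.min_path_length:
                    reason = "short"
            if reason is not None:
                break
        if reason is None:
            retained.append(tr)
        else:
            rej_ids.append(tr.id)
            rej_reasons.append(reason)
    rejections = pd.DataFrame({"id": rej_ids, "reason": rej_reasons})
    return retained, rejections


def select_analysis_window(
    tracks: Sequence[Track],
    criteria: FilterCriteria,
    recording_span: tuple[float, float],
) -> list[Track]:
    """Select tracks of roughly the target duration from the middle of a recording.

    Retains tracks whose duration lies within target_duration * (1 +/-
    duration_tolerance) and whose temporal midpoint falls in the central half
    of ``recording_span``; the result is sorted by descending path length.
    """
    t0, t1 = recording_span
    if t1 <= t0:
        raise InputError("recording span must have t1 > t0")
    lo = criteria.target_duration * (1 - criteria.duration_tolerance)
    hi = criteria.target_duration * (1 + criteria.duration_tolerance)
    span = t1 - t0
    mid_lo, mid_hi = t0 + span / 4.0, t1 - span / 4.0
    kept = []
    for tr in tracks:
        mid = 0.5 * (tr.t[0] + tr.t[-1])
        if lo <= tr.duration <= hi and mid_lo <= mid <= mid_hi:
            kept.append(tr)
    kept.sort(key=path_length, reverse=True)
    return kept


# ---------------------------------------------------------------------------
# statistics


def summarize_group(values: Iterable[float], group: str = "") -> GroupSummary:
    """Mean and standard error (sample sd / sqrt(n)); sem is 0 for n == 1."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise InputError("cannot summarize an empty group")
    sem = float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
    return GroupSummary(group=group, n=int(v.size), mean=float(np.mean(v)), sem=sem)


_EXACT_MAX_COMBINATIONS = 200_000


def _rank_sum_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating group assignments.

    Handles ties (ranks are mid-ranks of the pooled sample). Two-sided p is
    the probability of a U statistic at least as far from its mean n1*n2/2
    as the observed one, which is 1 for identical groups.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2.0
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    dev = abs(u_obs - mu)
    total = math.comb(n1 + n2, n1)
    count = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev - 1e-12:
            count += 1
    return u_obs, count / total


def _rank_sum_asymptotic(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Tie-corrected normal approximation for the rank-sum test."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(a), len(b)
    n = n1 + n2
    u = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return u, 1.0
    z = (u - mu) / math.sqrt(var)
    return u, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def compare_groups(
    a: Sequence[float], b: Sequence[float], method: str = "rank_sum"
) -> tuple[float, float]:
    """Two-sided two-group comparison.

    ``rank_sum`` reports the Mann-Whitney U of the first group; the p-value
    comes from exact enumeration when each group has <= 20 observations and
    the assignment count is enumerable (<= 200k), otherwise from the
    tie-corrected normal approximation. ``t_test`` is the two-sided
    equal-variance Student's t-test.
    """
    av = np.asarray(list(a), dtype=float)
    bv = np.asarray(list(b), dtype=float)
    if av.size < 2 or bv.size < 2:
        raise InputError("each group needs n >= 2")
    if method == "t_test":
        res = stats.ttest_ind(av, bv)
        return float(res.statistic), float(res.pvalue)
    if method != "rank_sum":
        raise ParameterError(f"unknown method {method!r}")
    small = av.size <= 20 and bv.size <= 20
    if small and math.comb(av.size + bv.size, av.size) <= _EXACT_MAX_COMBINATIONS:
        return _rank_sum_exact(av, bv)
    return _rank_sum_asymptotic(av, bv)


# ---------------------------------------------------------------------------
# transwell / normalization


def induced_transmigration(total_with_chemokine: float, random_without: float) -> float:
    """Chemokine-induced migration: total minus random; may be negative."""
    if total_with_chemokine < 0 or random_without < 0:
        raise InputError("cell counts must be non-negative")
    return total_with_chemokine - random_without


def normalize_to_reference(
    values: pd.DataFrame, reference_group: str, value_col: str = "value",
    group_col: str = "group",
) -> pd.DataFrame:
    """Divide every value by the reference group's mean.

    The reference group's normalized mean is 1 by construction. Returns a
    copy with an added ``normalized`` column.
    """
    ref = values.loc[values[group_col] == reference_group, value_col]
    if ref.empty:
        raise InputError(f"reference group {reference_group!r} is empty")
    ref_mean = float(ref.mean())
    if ref_mean == 0:
        raise ComputationError("reference group mean is zero")
    out = values.copy()
    out["normalized"] = out[value_col] / ref_mean
    return out
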