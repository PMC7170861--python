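"""End-to-end track pipeline: simulate/read -> filter -> metrics -> summarize -> compare.

The configuration is a plain mapping (typically loaded from YAML). Unknown
keys are rejected so typos cannot silently disable a stage, and every
stochastic stage requires an explicit seed — there is no implicit clock
seeding. The returned report carries per-stage record counts that must be
conserved (read = retained + rejected), the group summaries, any requested
comparison, the tool version and an echo of the configuration.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParameterError, ValidationError
from .io import read_tracks, write_json, write_tracks
from .synthetic import TrackSimParams, simulate_tracks
from .tracks import (
    FilterCriteria,
    GradientAxis,
    Track,
    compare_groups,
    filter_tracks,
    select_analysis_window,
    summarize_group,
    track_metrics,
)

__all__ = ["RunReport", "run_pipeline"]

_TOP_KEYS = {"out_dir", "axis", "simulate", "tracks_csv", "filter", "window", "compare"}
_SIM_KEYS = {"groups", "defaults"}
_FILTER_KEYS = {
    "min_volume",
    "min_path_length",
    "static_displacement_threshold",
    "target_duration",
    "duration_tolerance",
    "order",
}
_WINDOW_KEYS = {"recording_span"}
_COMPARE_KEYS = {"metric", "method", "groups"}


@dataclass
class RunReport:
    version: str
    config: dict
    seeds: dict[str, int]
    counts: dict[str, int]
    rejections: dict[str, int]
    summaries: list[dict]
    comparison: dict | None

    def check_conservation(self) -> None:
        c = self.counts
        if c["read"] != c["retained"] + c["rejected"]:
            raise ValidationError(
                f"record conservation violated: read={c['read']} != "
                f"retained={c['retained']} + rejected={c['rejected']}"
            )


def _check_keys(block: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ParameterError(f"unknown key(s) in {where}: {sorted(unknown)}")


def run_pipeline(config: Mapping[str, Any], out_dir: str | None = None) -> RunReport:
    """Run the configured stages and write all artifacts under ``out_dir``.

    Identical config and seeds produce byte-identical numeric outputs.
    """
    _check_keys(config, _TOP_KEYS, "config")
    out = Path(out_dir or config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)

    axis = GradientAxis(np.asarray(config.get("axis", (1.0, 0.0)), dtype=float))

    # --- acquire tracks ---------------------------------------------------
    seeds: dict[str, int] = {}
    tracks: list[Track] = []
    if "simulate" in config:
        sim = config["simulate"]
        _check_keys(sim, _SIM_KEYS, "simulate")
        defaults = dict(sim.get("defaults", {}))
        for group, block in sim["groups"].items():
            kwargs = {**defaults, **dict(block)}
            if "seed" not in kwargs:
                raise ParameterError(f"simulate.groups.{group}: explicit seed required")
            params = TrackSimParams(group=group, **kwargs)
            seeds[group] = params.seed
            tracks.extend(simulate_tracks(params))
        write_tracks(tracks, out / "tracks.csv")
    elif "tracks_csv" in config:
        tracks = read_tracks(config["tracks_csv"])
    else:
        raise ParameterError("config needs either 'simulate' or 'tracks_csv'")
    n_read = len(tracks)

    # --- filter -----------------------------------------------------------
    fconf = dict(config.get("filter", {}))
    _check_keys(fconf, _FILTER_KEYS, "filter")
    order = fconf.pop("order", ("volume", "static", "short"))
    criteria = FilterCriteria(**fconf)
    retained, rejections = filter_tracks(tracks, criteria, order=order)
    rejections.to_csv(out / "rejections.csv", index=False)

    if "window" in config and config["window"] is not None:
        wconf = dict(config["window"])
        _check_keys(wconf, _WINDOW_KEYS, "window")
        span = tuple(wconf.get("recording_span")
                     or (min(t.t[0] for t in tracks), max(t.t[-1] for t in tracks)))
        windowed = select_analysis_window(retained, criteria, span)
        window_dropped = len(retained) - len(windowed)
        retained = windowed
    else:
        window_dropped = 0

    # --- metrics ----------------------------------------------------------
    metrics = pd.DataFrame([dataclasses.asdict(track_metrics(t, axis))
                            for t in retained])
    metrics.to_csv(out / "metrics.csv", index=False, float_format="%.17g")

    # --- summaries --------------------------------------------------------
    summaries = []
    if not metrics.empty:
        for group, sub in metrics.groupby("group", sort=True):
            for metric in ("velocity", "dmi", "path_length", "net_displacement"):
                vals = sub[metric].dropna()
                if vals.empty:
                    continue
                s = summarize_group(vals, group=group)
                summaries.append(
                    {"group": group, "metric": metric, "n": s.n,
                     "mean": s.mean, "sem": s.sem}
                )

    # --- comparison -------------------------------------------------------
    comparison = None
    if "compare" in config and config["compare"] is not None:
        cconf = dict(config["compare"])
        _check_keys(cconf, _COMPARE_KEYS, "compare")
        metric = cconf.get("metric", "dmi")
        method = cconf.get("method", "rank_sum")
        ga, gb = cconf["groups"]
        a = metrics.loc[metrics["group"] == ga, metric].dropna()
        b = metrics.loc[metrics["group"] == gb, metric].dropna()
        stat, p = compare_groups(a, b, method=method)
        comparison = {"metric": metric, "method": method, "groups": [ga, gb],
                      "statistic": stat, "p_value": p}

    report = RunReport(
        version=__version__,
        config={k: v for k, v in config.items()},
        seeds=seeds,
        counts={
            "read": n_read,
            "retained": len(retained),
            "rejected": len(rejections) + window_dropped,
        },
        rejections=dict(rejections["reason"].value_counts())
        | ({"window": window_dropped} if window_dropped else {}),
        summaries=summaries,
        comparison=comparison,
    )
    report.check_conservation()
    write_json(dataclasses.asdict(report), out / "report.json")
    return report
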