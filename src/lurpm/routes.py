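"""Idealized-route construction and interpolation of per-round local PM.

The rounds of one measurement area never follow exactly the same GPS trace.
An *idealized route* is built by resampling every round to a common
arc-length parameterization, averaging positions pointwise, and resampling
the mean path to uniform spacing (default 25 m, so adjacent buffer disks
abut).  Preprocessed samples from all rounds are then pooled per route
point: every sample within an inclusive 25 m radius contributes, and the
point records the maximum, minimum, mean and (population) standard deviation
of local PM2.5 plus the contributor count.  The per-point *maximum* is the
modelling target exported downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .preprocess import SensorTrack
from .synthetic import polyline_length, resample_polyline

__all__ = ["RoutePointSet", "build_ideal_route", "aggregate_to_route"]


@dataclass
class RoutePointSet:
    """Idealized path with per-point aggregated PM statistics."""

    area_id: str
    data: pd.DataFrame  # x, y, pm_max, pm_min, pm_mean, pm_sd, n_contributing
    spacing: float
    radius: float

    def __len__(self) -> int:
        return len(self.data)

    @property
    def observed(self) -> pd.DataFrame:
        """Rows with at least one contributing sample."""
        return self.data.loc[self.data["n_contributing"] >= 1].reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def _track_positions(track) -> np.ndarray:
    df = track.data if isinstance(track, SensorTrack) else track
    return np.column_stack(
        [df["x"].to_numpy(dtype=float), df["y"].to_numpy(dtype=float)]
    )


def build_ideal_route(tracks: list, spacing: float = 25.0) -> np.ndarray:
    """Mean path of all rounds of one area, resampled to uniform spacing.

    ``tracks`` are :class:`SensorTrack` objects (or DataFrames with x/y) from
    the *same* area.  Rounds whose arc length deviates by more than 20% from
    the mean indicate an incomplete or mis-assigned round and are rejected
    with an error naming the offending round.
    """
    if not tracks:
        raise ValueError("need at least one track")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    areas = {t.area_id for t in tracks if isinstance(t, SensorTrack)}
    if len(areas) > 1:
        raise ValueError(f"tracks from different areas: {sorted(areas)}")
    polys = [_track_positions(t) for t in tracks]
    lengths = np.array([polyline_length(p) for p in polys])
    mean_len = lengths.mean()
    bad = np.abs(lengths - mean_len) / mean_len > 0.20
    if bad.any():
        ids = [
            getattr(tracks[i], "round_id", i) for i in np.flatnonzero(bad)
        ]
        raise ValueError(
            f"round(s) {ids} deviate more than 20% from the mean arc length"
        )
    # common parameterization: M points equally spaced in normalized arc length
    m = max(int(round(mean_len / spacing)) + 1, 2)
    resampled = []
    for p in polys:
        seg = np.hypot(*np.diff(p, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        s = np.linspace(0.0, arc[-1], m)
        resampled.append(
            np.column_stack([np.interp(s, arc, p[:, 0]), np.interp(s, arc, p[:, 1])])
        )
    mean_path = np.mean(resampled, axis=0)
    return resample_polyline(mean_path, spacing)


def aggregate_to_route(
    route: np.ndarray, processed_rounds: list[pd.DataFrame], radius: float = 25.0,
    area_id: str = "area",
) -> RoutePointSet:
    """Pool preprocessed samples (columns x, y, pm25_local) from all rounds
    onto route points.

    A sample contributes to a route point when its Euclidean distance is
    <= ``radius`` (ties at exactly the radius are included).  Statistics are
    computed over the pooled samples of all rounds; points without any
    contributor are flagged via ``n_contributing = 0`` and NaN statistics.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pooled = pd.concat(processed_rounds, ignore_index=True)
    if "pm25_local" not in pooled.columns:
        raise ValueError("rounds must be preprocessed (pm25_local present)")
    pts = np.column_stack(
        [pooled["x"].to_numpy(dtype=float), pooled["y"].to_numpy(dtype=float)]
    )
    values = pooled["pm25_local"].to_numpy(dtype=float)
    tree = cKDTree(pts)
    route = np.asarray(route, dtype=float)
    rows = []
    for x, y in route:
        idx = tree.query_ball_point([x, y], r=radius)
        if idx:
            v = values[idx]
            rows.append(
                (x, y, v.max(), v.min(), v.mean(), v.std(ddof=0), len(v))
            )
        else:
            rows.append((x, y, np.nan, np.nan, np.nan, np.nan, 0))
    spacing = (
        float(np.median(np.hypot(*np.diff(route, axis=0).T))) if len(route) > 1 else radius
    )
    data = pd.DataFrame(
        rows,
        columns=["x", "y", "pm_max", "pm_min", "pm_mean", "pm_sd", "n_contributing"],
    )
    return RoutePointSet(area_id=area_id, data=data, spacing=spacing, radius=radius)
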