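"""Per-round preprocessing of raw mobile PM2.5 tracks.

A raw optical-particle-counter reading inflates with ambient relative
humidity because hygroscopic particles take up water.  The kappa-Koehler
mass-growth correction divides the raw mass concentration by

    C = 1 + (kappa / rho) / (1/RH - 1),        0 < RH < 1,

where ``kappa`` is the bulk hygroscopicity parameter and ``rho`` the dry
particle density (g/cm^3), so the corrected (dry) concentration is
``PM_corrected = PM_raw / C``.

The full per-round pipeline is, in this fixed order:

1. humidity correction (``correct_pm``),
2. removal of the top and bottom quantile of the corrected PM series
   (``trim_outliers``, default 5%),
3. tumbling-window temporal medians (``temporal_median``, default 30 s),
4. subtraction of the round's low-quantile background concentration
   (``subtract_background``, default 5th percentile), leaving the *local*
   PM signal.

Each round is handled independently; because a linear sensor drift shifts a
whole round by a constant, the per-round background subtraction also removes
drift-induced bias between rounds.  All quantiles use linear interpolation
(type 7); negatives after background subtraction are retained, not clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SensorTrack",
    "CorrectionParams",
    "PreprocessConfig",
    "correction_factor",
    "correct_pm",
    "trim_outliers",
    "temporal_median",
    "subtract_background",
    "preprocess_track",
]

#: Columns every raw track must carry.  Coordinates are projected meters.
TRACK_COLUMNS = ("time", "x", "y", "pm25_raw", "temp_c", "rh_pct")


@dataclass
class SensorTrack:
    """One measurement round: timestamped, geolocated PM / T / RH samples."""

    data: pd.DataFrame
    round_id: int = 0
    area_id: str = "area"

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"track is missing columns {missing}")
        t = self.data["time"].to_numpy(dtype=float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("track timestamps must be strictly increasing")
        pm = self.data["pm25_raw"].to_numpy(dtype=float)
        if np.any(pm[np.isfinite(pm)] < 0):
            raise ValueError("pm25_raw must be non-negative")
        rh = self.data["rh_pct"].to_numpy(dtype=float)
        ok = np.isfinite(rh)
        if np.any((rh[ok] <= 0) | (rh[ok] >= 100)):
            raise ValueError("rh_pct must lie strictly between 0 and 100")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["round"] = self.round_id
        out["area"] = self.area_id
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SensorTrack":
        df = pd.read_csv(path)
        round_id = int(df.pop("round").iloc[0]) if "round" in df else 0
        area_id = str(df.pop("area").iloc[0]) if "area" in df else "area"
        return cls(data=df, round_id=round_id, area_id=area_id)


@dataclass(frozen=True)
class CorrectionParams:
    """kappa-Koehler correction parameters (defaults from the correction
    literature for urban aerosol: kappa = 0.4, rho = 1.6 g/cm^3)."""

    kappa: float = 0.4
    rho: float = 1.6

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")


@dataclass(frozen=True)
class PreprocessConfig:
    trim_fraction: float = 0.05
    median_window: float = 30.0
    background_quantile: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.median_window <= 0:
            raise ValueError("median_window must be positive")
        if not 0 <= self.background_quantile < 1:
            raise ValueError("background_quantile must be in [0, 1)")


def correction_factor(rh, params: CorrectionParams) -> np.ndarray:
    """Hygroscopic-growth correction factor C at relative humidity ``rh``.

    ``rh`` is a fraction in (0, 1).  C = 1 + (kappa/rho) / (1/rh - 1);
    C >= 1 and is monotone non-decreasing in rh.
    """
    rh = np.asarray(rh, dtype=float)
    if np.any(rh <= 0) or np.any(rh >= 1):
        raise ValueError("relative humidity must lie strictly in (0, 1)")
    return 1.0 + (params.kappa / params.rho) / (1.0 / rh - 1.0)


def correct_pm(track: SensorTrack, params: CorrectionParams) -> SensorTrack:
    """Return a new track with a ``pm25_corrected`` column (= raw / C).

    Samples with missing RH cannot be corrected; they are excluded and the
    exclusion count logged.
    """
    df = track.data.copy()
    rh = df["rh_pct"].to_numpy(dtype=float)
    bad = ~np.isfinite(rh)
    if bad.any():
        logger.warning(
            "round %s: excluding %d samples with missing RH", track.round_id, bad.sum()
        )
        df = df.loc[~bad].reset_index(drop=True)
        rh = rh[~bad]
    c = correction_factor(rh / 100.0, params)
    df["pm25_corrected"] = df["pm25_raw"].to_numpy(dtype=float) / c
    return SensorTrack(data=df, round_id=track.round_id, area_id=track.area_id)


def _trim_bounds(values: np.ndarray, trim_fraction: float) -> tuple[float, float]:
    lo = np.quantile(values, trim_fraction)
    hi = np.quantile(values, 1.0 - trim_fraction)
    return float(lo), float(hi)


def trim_outliers(values, trim_fraction: float = 0.05) -> np.ndarray:
    """Drop values strictly below the ``trim_fraction`` quantile and strictly
    above the ``1 - trim_fraction`` quantile (linear-interpolation quantiles).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 20:
        raise ValueError("series too short to trim (need >= 20 samples)")
    lo, hi = _trim_bounds(values, trim_fraction)
    return values[(values >= lo) & (values <= hi)]


def temporal_median(
    samples: pd.DataFrame, window: float = 30.0, value_col: str = "pm25_corrected"
) -> pd.DataFrame:
    """Reduce samples to non-overlapping (tumbling) time windows.

    Each window is summarised by the median of ``value_col``, the mean
    position, and the window-center timestamp.  A short final window is kept
    as long as it holds at least one sample.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t = samples["time"].to_numpy(dtype=float)
    if len(t) == 0:
        return pd.DataFrame(columns=["time", "x", "y", value_col, "n"])
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    bins = np.floor((t - t[0]) / window).astype(int)
    df = samples.assign(_bin=bins)
    grouped = df.groupby("_bin", sort=True)
    out = pd.DataFrame(
        {
            "time": t[0] + (grouped["_bin"].first().to_numpy() + 0.5) * window,
            "x": grouped["x"].mean().to_numpy(),
            "y": grouped["y"].mean().to_numpy(),
            value_col: grouped[value_col].median().to_numpy(),
            "n": grouped.size().to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def subtract_background(values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Subtract the q-quantile of a series from every value.

    Returns ``(local_series, background)``.  Negatives are retained: clipping
    would bias round means.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("cannot subtract background from an empty series")
    background = float(np.quantile(values, q))
    return values - background, background


def preprocess_track(
    track: SensorTrack,
    params: CorrectionParams = CorrectionParams(),
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Run the full per-round pipeline: correct, trim, median, subtract.

    Returns a DataFrame with columns ``time, x, y, pm25_local`` (one row per
    temporal-median window) and a report dict with per-stage counts and the
    background level.  The function only ever reads this one round.
    """
    n_raw = len(track)
    corrected = correct_pm(track, params)
    n_corrected = len(corrected)

    pm = corrected.data["pm25_corrected"].to_numpy(dtype=float)
    if len(pm) < 20:
        raise ValueError("round too short to preprocess (need >= 20 samples)")
    lo, hi = _trim_bounds(pm, config.trim_fraction)
    kept = corrected.data.loc[(pm >= lo) & (pm <= hi)].reset_index(drop=True)
    n_trimmed = len(kept)

    medians = temporal_median(kept, window=config.median_window)
    local, background = subtract_background(
        medians["pm25_corrected"].to_numpy(), q=config.background_quantile
    )
    out = medians[["time", "x", "y"]].copy()
    out["pm25_local"] = local
    report = {
        "round_id": track.round_id,
        "area_id": track.area_id,
        "n_raw": n_raw,
        "n_rh_missing": n_raw - n_corrected,
        "n_removed_trim": n_corrected - n_trimmed,
        "n_median_windows": len(medians),
        "background": background,
        "negatives_clipped": False,
    }
    return out, report
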