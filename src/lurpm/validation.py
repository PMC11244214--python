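"""Hold-out and station-style validation of the model variants.

Hold-out validation (HOV) scores every ensemble member on the withheld test
split and reports per-seed metrics, their aggregate, and sorted-vs-sorted
Q-Q pairs of observed against mean-predicted targets.

Station validation mimics transferring the model to a regulatory network:
the buffer predictors extracted at each station location are fed to every
ensemble member, and predictions are compared with the station's *observed
local maximum* — the median, over the days with bicycle measurements, of the
station's daily background-subtracted concentrations (background = 5th
percentile of the series, same type-7 quantile convention as preprocessing).
Station targets are never used for training; every model variant flows
through the identical code path, only the feature subset differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import MetricSet, ModelEnsemble, evaluate
from .features import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "StationRecord",
    "ValidationReport",
    "StationValidationReport",
    "hov_validate",
    "station_observed_local_max",
    "station_validate",
    "residual_summary",
]

STATION_CLASSES = ("urban_background", "suburban", "traffic")


@dataclass
class StationRecord:
    """A reference station: location (projected meters), class, and a daily
    PM2.5 series indexed by day."""

    station_id: str
    x: float
    y: float
    classification: str
    series: pd.Series

    def __post_init__(self) -> None:
        if self.classification not in STATION_CLASSES:
            raise ValueError(f"unknown station class {self.classification!r}")
        if len(self.series) == 0:
            raise ValueError("station series must be non-empty")
        if np.any(self.series.to_numpy(dtype=float) < 0):
            raise ValueError("station PM2.5 values must be >= 0")


@dataclass
class ValidationReport:
    """One model variant's hold-out validation results."""

    model_id: str
    per_seed_metrics: pd.DataFrame  # index seed, columns mae..r2
    aggregate: MetricSet
    qq: pd.DataFrame  # sorted observed vs sorted mean prediction

    def summary(self) -> dict:
        return {"model_id": self.model_id, **self.aggregate.as_dict()}


@dataclass
class StationValidationReport:
    """One model variant's station validation results."""

    model_id: str
    observed: pd.Series  # station_id -> observed local max
    predictions: pd.DataFrame  # index seed, columns station_id
    pooled: MetricSet
    per_station_rmse: pd.Series
    abs_errors: pd.DataFrame = field(default_factory=pd.DataFrame)

    def qq(self) -> pd.DataFrame:
        obs = np.sort(self.observed.to_numpy(dtype=float))
        pred = np.sort(self.predictions.mean(axis=0).to_numpy(dtype=float))
        return pd.DataFrame({"observed": obs, "predicted": pred})


def hov_validate(
    ensemble: ModelEnsemble, test: FeatureTable, model_id: str = "model"
) -> ValidationReport:
    """Score the ensemble on the held-out test table."""
    missing = [f for f in ensemble.feature_names if f not in test.data.columns]
    if missing:
        raise ValueError(f"test table lacks model features: {missing[:5]}")
    obs = test.y
    preds = ensemble.predict_per_seed(test.data)
    rows = {s: evaluate(preds[k], obs).as_dict() for k, s in enumerate(ensemble.seeds)}
    per_seed = pd.DataFrame(rows).T
    per_seed.index.name = "seed"
    aggregate = MetricSet(**per_seed.mean(axis=0).to_dict())
    mean_pred = preds.mean(axis=0)
    qq = pd.DataFrame({"observed": np.sort(obs), "predicted": np.sort(mean_pred)})
    return ValidationReport(
        model_id=model_id, per_seed_metrics=per_seed, aggregate=aggregate, qq=qq
    )


def station_observed_local_max(
    record: StationRecord, measurement_dates, q: float = 0.05
) -> float:
    """Median over measurement days of the station's daily local maxima.

    Background (the series' q-quantile, linear interpolation) is subtracted
    from the whole series first; the median of an even day count is the mean
    of the two central values (numpy convention).
    """
    series = record.series
    dates = [d for d in measurement_dates if d in series.index]
    if not dates:
        raise ValueError(
            f"station {record.station_id}: no overlap with measurement dates"
        )
    values = series.to_numpy(dtype=float)
    background = np.quantile(values, q)
    local = series - background
    return float(np.median(local.loc[dates].to_numpy(dtype=float)))


def station_validate(
    ensembles: dict[str, ModelEnsemble],
    station_features: FeatureTable,
    records: list[StationRecord],
    measurement_dates,
    q: float = 0.05,
) -> dict[str, StationValidationReport]:
    """Validate every model variant against the station records.

    ``station_features`` rows must align with ``records`` (same order, same
    code path as the route features).  Stations whose features are missing
    (dropped rows) are skipped and logged.  Per-station RMSE is taken over
    the per-seed predictions against the single observed value.
    """
    if len(station_features) != len(records):
        kept = set(range(len(station_features)))
        raise ValueError(
            f"station features ({len(station_features)} rows) do not align "
            f"with {len(records)} station records; kept row ids: {sorted(kept)}"
        )
    observed = {}
    for rec in records:
        observed[rec.station_id] = station_observed_local_max(
            rec, measurement_dates, q=q
        )
    obs = pd.Series(observed)

    reports: dict[str, StationValidationReport] = {}
    for model_id, ensemble in ensembles.items():
        preds = ensemble.predict_per_seed(station_features.data)
        pred_df = pd.DataFrame(
            preds, index=ensemble.seeds, columns=[r.station_id for r in records]
        )
        pred_df.index.name = "seed"
        # pooled metrics over every (seed, station) pair; with a single
        # distinct observed value the range-normalised metrics are undefined
        tiled_obs = np.tile(obs.to_numpy(dtype=float), len(ensemble.seeds))
        if tiled_obs.max() > tiled_obs.min():
            pooled = evaluate(preds.ravel(), tiled_obs)
        else:
            err = preds.ravel() - tiled_obs
            mse = float(np.mean(err**2))
            pooled = MetricSet(
                mae=float(np.mean(np.abs(err))), mse=mse, rmse=float(np.sqrt(mse)),
                nrmse=float("nan"), r2=float("nan"),
            )
        err = pred_df - obs
        per_station_rmse = np.sqrt((err**2).mean(axis=0))
        reports[model_id] = StationValidationReport(
            model_id=model_id,
            observed=obs,
            predictions=pred_df,
            pooled=pooled,
            per_station_rmse=per_station_rmse,
            abs_errors=err.abs(),
        )
    return reports


def residual_summary(report: StationValidationReport) -> pd.DataFrame:
    """Per-station signed-residual statistics: mean signed error, MAE, and an
    over/under-estimation flag."""
    err = report.predictions - report.observed
    mean_signed = err.mean(axis=0)
    mae = err.abs().mean(axis=0)
    return pd.DataFrame(
        {
            "mean_signed_error": mean_signed,
            "mae": mae,
            "direction": np.where(mean_signed > 0, "over", "under"),
        }
    )
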