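"""Monte-Carlo random-forest ensembles and regression metrics.

A single random forest is already an ensemble over trees; here the *model*
uncertainty is additionally sampled by refitting the same forest
configuration under a sweep of ``random_state`` seeds (Monte-Carlo runs) and
carrying all per-seed predictions through validation.  The train/test split
is distribution-preserving: rows are stratified over target-quantile bins
and the global target minimum and maximum are forced into the training
partition so the training data span the full observed range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .features import FeatureTable

__all__ = [
    "SplitSpec",
    "MetricSet",
    "ModelEnsemble",
    "split_table",
    "make_forest",
    "train_ensemble",
    "evaluate",
]

#: Forest configuration: scikit-learn defaults with 100 trees, squared-error
#: split criterion, bootstrap aggregation.
DEFAULT_RF_PARAMS = dict(n_estimators=100, criterion="squared_error", bootstrap=True)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    n_bins: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_bins < 2:
            raise ValueError("need at least 2 stratification bins")


@dataclass(frozen=True)
class MetricSet:
    """Standard regression metrics; nrmse is RMSE over the observed range
    (scatter index), r2 the coefficient of determination."""

    mae: float
    mse: float
    rmse: float
    nrmse: float
    r2: float

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "mse": self.mse,
            "rmse": self.rmse,
            "nrmse": self.nrmse,
            "r2": self.r2,
        }


def evaluate(predictions, observations) -> MetricSet:
    """Evaluate predictions against observations.

    r2 = 1 - SS_res / SS_tot (may be negative out of sample; not clipped);
    nrmse = rmse / (max(obs) - min(obs)) and requires a non-zero range.
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predictions and observations must be equal-length 1-D")
    if len(obs) < 2:
        raise ValueError("need at least 2 observations")
    obs_range = obs.max() - obs.min()
    if obs_range == 0:
        raise ValueError("observation range is zero; nrmse undefined")
    err = pred - obs
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = float(1.0 - np.sum(err**2) / ss_tot)
    return MetricSet(
        mae=mae, mse=mse, rmse=rmse, nrmse=float(rmse / obs_range), r2=r2
    )


# ---------------------------------------------------------------------------
# distribution-preserving split


def _stratified_allocation(bin_sizes: np.ndarray, m: int) -> np.ndarray:
    """Largest-remainder allocation of ``m`` training rows over bins."""
    quota = m * bin_sizes / bin_sizes.sum()
    base = np.floor(quota).astype(int)
    remainder = quota - base
    short = m - base.sum()
    order = np.argsort(-remainder, kind="stable")
    for b in order[:short]:
        base[b] += 1
    # respect bin capacities (possible after forcing extremes)
    over = base - bin_sizes
    while np.any(over > 0):
        src = int(np.argmax(over))
        base[src] = bin_sizes[src]
        slack = bin_sizes - base
        dst = int(np.argmax(slack))
        base[dst] += min(int(over[src]), int(slack[dst]))
        over = base - bin_sizes
    return base


def split_table(
    table: FeatureTable, spec: SplitSpec = SplitSpec()
) -> tuple[FeatureTable, FeatureTable]:
    """Split a feature table 70/30 (by default) preserving the target
    distribution.

    The train partition gets exactly ``floor(train_fraction * n)`` rows,
    stratified over ``n_bins`` target-quantile bins, and always contains the
    rows with the global minimum and maximum target so that the training
    range covers the whole data set.  Tables too small to stratify fall back
    to a plain random split with a warning.
    """
    y = table.y
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    m = int(np.floor(spec.train_fraction * n))
    rng = np.random.default_rng(spec.seed)

    if n < 2 * spec.n_bins:
        warnings.warn("table too small for stratification; plain random split")
        perm = rng.permutation(n)
        return table.take_rows(perm[:m]), table.take_rows(perm[m:])

    bins = pd.qcut(y, q=spec.n_bins, labels=False, duplicates="drop")
    bins = np.asarray(bins, dtype=int)
    n_bins = bins.max() + 1
    forced = {int(np.argmin(y)), int(np.argmax(y))}

    bin_sizes = np.bincount(bins, minlength=n_bins)
    alloc = _stratified_allocation(bin_sizes, m)
    # make sure each forced row's bin has room for it
    for idx in forced:
        b = bins[idx]
        n_forced_in_b = sum(1 for i in forced if bins[i] == b)
        if alloc[b] < n_forced_in_b:
            donor = int(np.argmax(alloc - np.array(
                [sum(1 for i in forced if bins[i] == bb) for bb in range(n_bins)]
            )))
            alloc[donor] -= 1
            alloc[b] += 1

    train_idx: list[int] = []
    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        first = [i for i in members if i in forced]
        rest = rng.permutation([i for i in members if i not in forced])
        take = alloc[b]
        train_idx.extend(first[:take])
        train_idx.extend(rest[: take - len(first[:take])])
    train_mask = np.zeros(n, dtype=bool)
    train_mask[train_idx] = True
    train = table.take_rows(np.flatnonzero(train_mask))
    test = table.take_rows(np.flatnonzero(~train_mask))
    assert len(train) == m and len(test) == n - m
    return train, test


# ---------------------------------------------------------------------------
# ensemble


def make_forest(seed: int, **overrides) -> RandomForestRegressor:
    params = dict(DEFAULT_RF_PARAMS)
    params.update(overrides)
    return RandomForestRegressor(random_state=int(seed), n_jobs=1, **params)


@dataclass
class ModelEnsemble:
    """Seed-indexed collection of fitted forests over one feature set."""

    seeds: list[int]
    models: dict[int, RandomForestRegressor]
    feature_names: list[str]
    rf_params: dict = field(default_factory=dict)

    def predict_per_seed(self, X: pd.DataFrame) -> np.ndarray:
        """(n_seeds, n_rows) array of per-seed predictions."""
        Xs = X[self.feature_names]
        return np.stack([self.models[s].predict(Xs) for s in self.seeds])

    def predict_mean(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_per_seed(X).mean(axis=0)


def train_ensemble(
    train: FeatureTable, seeds, **rf_overrides
) -> ModelEnsemble:
    """Fit one forest per seed on the training table (deterministic per seed).

    ``rf_overrides`` adjust the forest configuration (e.g. ``n_estimators``)
    and are recorded on the ensemble for reproducibility.
    """
    if len(train) == 0:
        raise ValueError("empty training table")
    X = train.X
    bad = [c for c in X.columns if not np.issubdtype(X[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric feature columns: {bad}")
    y = train.y
    seeds = [int(s) for s in seeds]
    models = {s: make_forest(s, **rf_overrides).fit(X, y) for s in seeds}
    params = dict(DEFAULT_RF_PARAMS)
    params.update(rf_overrides)
    return ModelEnsemble(
        seeds=seeds, models=models, feature_names=list(train.feature_names),
        rf_params=params,
    )
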