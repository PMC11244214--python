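"""Recursive feature elimination, with and without cross-validation.

Plain RFE refits the forest repeatedly, dropping the feature with the lowest
impurity-based importance each step until ``n_keep`` survive; survivors get
rank 1 and eliminated features are ranked by reverse elimination order (the
last one out gets rank 2).  RFECV scores every candidate feature count by
k-fold cross-validated R^2 and keeps the survivor set at the best count
(ties prefer the smaller count).  Both are wrapped in Monte-Carlo seed
sweeps; features whose mean rank across runs is strictly below a threshold
(default 2) form the parsimonious set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFECV
from sklearn.model_selection import KFold

from .ensemble import make_forest
from .features import FeatureTable

__all__ = ["RankRecord", "rfe_rank", "rfecv_select", "aggregate_ranks"]


@dataclass
class RankRecord:
    """Feature ranks per Monte-Carlo run (1 = retained longest)."""

    runs: dict[int, dict[str, int]] = field(default_factory=dict)

    def add(self, seed: int, ranks: dict[str, int]) -> None:
        self.runs[int(seed)] = dict(ranks)

    @property
    def mean_rank(self) -> pd.Series:
        df = pd.DataFrame(self.runs)
        return df.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.runs)
        df["mean_rank"] = df.mean(axis=1)
        return df


def _importances(model, features: list[str]) -> dict[str, float]:
    return dict(zip(features, model.feature_importances_))


def rfe_rank(
    table: FeatureTable, seed: int, n_keep: int = 8, step: int = 1, **rf_overrides
) -> dict[str, int]:
    """One recursive-elimination run; returns feature -> rank.

    Each iteration drops the ``step`` features with the lowest impurity
    importance (never crossing ``n_keep``).  Importance ties are broken by
    dropping the lexicographically last name first — a documented, order-free
    tie rule, so permuting columns permutes ranks identically.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    features = list(table.feature_names)
    if len(features) < n_keep:
        raise ValueError("n_keep exceeds the number of features")
    if step < 1:
        raise ValueError("step must be >= 1")
    X = table.X
    y = table.y
    remaining = sorted(features)
    removed: list[str] = []
    while len(remaining) > n_keep:
        model = make_forest(seed, **rf_overrides).fit(X[remaining], y)
        imp = _importances(model, remaining)
        # lexicographically last first among importance ties (stable sort)
        order = sorted(remaining, reverse=True)
        order.sort(key=lambda f: imp[f])
        k = min(step, len(remaining) - n_keep)
        victims = order[:k]
        for v in victims:
            remaining.remove(v)
            removed.append(v)
    ranks = {f: 1 for f in remaining}
    d = len(removed)
    for i, f in enumerate(removed):  # first removed -> largest rank
        ranks[f] = d - i + 1
    return ranks


def rfecv_select(
    table: FeatureTable,
    seed: int,
    folds: int = 5,
    step: int = 1,
    min_features: int = 1,
    **rf_overrides,
) -> tuple[list[str], dict[str, int], np.ndarray]:
    """Recursive elimination with k-fold cross-validated feature-count choice.

    Returns ``(selected_features, ranking, mean_cv_score_per_count)`` for one
    run; the selected set is the survivor set at the feature count with the
    highest mean cross-validated R^2 (ties -> smaller count).  Selected
    features carry rank 1.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n = len(table)
    if n < 2 * folds and n != folds:
        raise ValueError("need at least 2 rows per fold")
    if n == folds:
        warnings.warn("folds == n rows: leave-one-out cross-validation")
    cv = KFold(n_splits=folds, shuffle=True, random_state=int(seed))
    selector = RFECV(
        estimator=make_forest(seed, **rf_overrides),
        step=step,
        cv=cv,
        scoring="r2",
        min_features_to_select=min_features,
        n_jobs=1,
    )
    X = table.X
    selector.fit(X, table.y)
    ranking = dict(zip(table.feature_names, map(int, selector.ranking_)))
    selected = [f for f, keep in zip(table.feature_names, selector.support_) if keep]
    scores = np.asarray(selector.cv_results_["mean_test_score"], dtype=float)
    return selected, ranking, scores


def aggregate_ranks(record: RankRecord, threshold: float = 2.0) -> list[str]:
    """Features whose mean rank across Monte-Carlo runs is strictly below
    ``threshold`` — the parsimonious set."""
    if not record.runs:
        raise ValueError("no runs to aggregate")
    mean = record.mean_rank
    return sorted(mean.index[mean < threshold])
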