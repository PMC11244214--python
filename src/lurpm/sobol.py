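"""Variance-based (Sobol) global sensitivity analysis of a fitted model.

The fitted forest is treated as a black-box function of its predictors.
Inputs are sampled uniformly and independently between each predictor's
observed minimum and maximum (the exact input distribution being unknown,
the uniform box covers the whole input space); integer-coded categorical
columns are rounded to the nearest valid code.  The Saltelli design draws
two quasi-random base matrices A and B from a Sobol' low-discrepancy
sequence plus the D cross matrices AB_i (column i of A replaced from B),
N * (D + 2) evaluations in total for a base sample of N (a power of two).

First-order indices use the Saltelli (2010) estimator

    S_i = mean( f(B) * (f(AB_i) - f(A)) ) / V,

total-order indices the Jansen (1999) estimator

    T_i = mean( (f(A) - f(AB_i))^2 ) / (2 V),

with V the variance of the pooled A/B evaluations.  S_i is the share of
output variance explained by input i alone; T_i includes all interactions,
so T_i - S_i signals higher-order effects.  Indices are averaged over the
Monte-Carlo model ensemble; features whose mean first-order index exceeds a
threshold (default 0.01, strict) form the GSA-parsimonious set, optionally
augmented with all street-type columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .ensemble import ModelEnsemble
from .features import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterSpace",
    "SobolDesign",
    "SensitivityResult",
    "ScreenResult",
    "build_parameter_space",
    "saltelli_sample",
    "total_evaluations",
    "round_categoricals",
    "estimate_indices",
    "aggregate_over_ensemble",
    "screen_features",
]


@dataclass(frozen=True)
class ParameterSpace:
    """Per-feature sampling bounds; constant-range features are excluded
    (and listed) because they carry no variance to apportion."""

    names: list[str]
    bounds: np.ndarray  # (D, 2)
    kinds: dict[str, str] = field(default_factory=dict)
    codes: dict[str, list[int]] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    #: observed value of each dropped constant column (models trained on the
    #: full table still need these at prediction time)
    constant_values: dict[str, float] = field(default_factory=dict)

    @property
    def D(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class SobolDesign:
    """Saltelli sample: rows [A; B; AB_1 ... AB_D], N rows per block."""

    samples: np.ndarray  # (N*(D+2), D)
    N: int
    D: int
    names: list[str]
    cv_target: float = 0.1
    ci_width: float = 0.01

    @property
    def S(self) -> int:
        return self.N * (self.D + 2)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.names)


@dataclass
class SensitivityResult:
    """Per-feature FOS/TOS for each ensemble run plus their mean and spread."""

    names: list[str]
    fos: np.ndarray  # (n_runs, D)
    tos: np.ndarray  # (n_runs, D)

    @property
    def mean_fos(self) -> pd.Series:
        return pd.Series(self.fos.mean(axis=0), index=self.names)

    @property
    def mean_tos(self) -> pd.Series:
        return pd.Series(self.tos.mean(axis=0), index=self.names)

    @property
    def spread_fos(self) -> pd.Series:
        return pd.Series(self.fos.std(axis=0, ddof=0), index=self.names)

    @property
    def spread_tos(self) -> pd.Series:
        return pd.Series(self.tos.std(axis=0, ddof=0), index=self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_fos": self.mean_fos,
                "mean_tos": self.mean_tos,
                "spread_fos": self.spread_fos,
                "spread_tos": self.spread_tos,
            }
        )


@dataclass(frozen=True)
class ScreenResult:
    parsimonious: list[str]
    streets: list[str]


def build_parameter_space(table: FeatureTable) -> ParameterSpace:
    """Bounds = observed min/max of every feature column; zero-range columns
    are dropped with a warning and recorded on the space."""
    if len(table) == 0:
        raise ValueError("empty feature table")
    X = table.X
    lo = X.min(axis=0).to_numpy(dtype=float)
    hi = X.max(axis=0).to_numpy(dtype=float)
    keep = hi > lo
    dropped = [c for c, k in zip(table.feature_names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant-range feature(s)")
    names = [c for c, k in zip(table.feature_names, keep) if k]
    if not names:
        raise ValueError("all feature columns are constant")
    kinds = {c: table.column_kind.get(c, "continuous") for c in names}
    codes = {
        c: list(table.codes_for(c))
        for c in names
        if kinds[c] == "categorical" and table.column_layer.get(c) in table.codebook
    }
    constant_values = {
        c: float(v) for c, v, k in zip(table.feature_names, lo, keep) if not k
    }
    return ParameterSpace(
        names=names,
        bounds=np.column_stack([lo[keep], hi[keep]]),
        kinds=kinds,
        codes=codes,
        dropped=dropped,
        constant_values=constant_values,
    )


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


def total_evaluations(N: int, D: int) -> int:
    """Size S of a Saltelli design: S = N * (D + 2) model evaluations."""
    if not _is_power_of_two(N):
        raise ValueError("N must be a power of two")
    if D < 1:
        raise ValueError("need at least one sampled feature")
    return int(N) * (int(D) + 2)


def saltelli_sample(
    space: ParameterSpace, N: int, seed: int | None = None, scramble: bool = True
) -> SobolDesign:
    """Draw the Saltelli design over the parameter space.

    ``N`` must be a power of two (Sobol' sequences lose their balance
    properties otherwise).  Row layout: N rows of A, N rows of B, then D
    blocks AB_i of N rows each — S = N * (D + 2) rows in total.
    """
    if not _is_power_of_two(N):
        nxt = 1 << max(int(N) - 1, 1).bit_length()
        raise ValueError(f"N={N} is not a power of two (next valid: {nxt})")
    D = space.D
    sampler = qmc.Sobol(d=2 * D, scramble=scramble, seed=seed)
    u = sampler.random(N)
    lo = space.bounds[:, 0]
    hi = space.bounds[:, 1]
    A = lo + u[:, :D] * (hi - lo)
    B = lo + u[:, D:] * (hi - lo)
    blocks = [A, B]
    for i in range(D):
        ab = A.copy()
        ab[:, i] = B[:, i]
        blocks.append(ab)
    samples = np.concatenate(blocks, axis=0)
    return SobolDesign(samples=samples, N=int(N), D=D, names=list(space.names))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def round_categoricals(design: SobolDesign, space: ParameterSpace) -> SobolDesign:
    """Round categorical columns half-away-from-zero to the nearest integer,
    then clamp to the nearest valid code of the layer's code set."""
    samples = design.samples.copy()
    for i, name in enumerate(design.names):
        if space.kinds.get(name) != "categorical":
            continue
        col = _round_half_away(samples[:, i])
        codes = np.asarray(
            sorted(space.codes.get(name, [])), dtype=float
        )
        if len(codes):
            pos = np.searchsorted(codes, col)
            pos = np.clip(pos, 0, len(codes) - 1)
            left = codes[np.clip(pos - 1, 0, len(codes) - 1)]
            right = codes[pos]
            col = np.where(np.abs(col - left) < np.abs(right - col), left, right)
        samples[:, i] = col
    return SobolDesign(
        samples=samples, N=design.N, D=design.D, names=list(design.names)
    )


def estimate_indices(
    evaluations: np.ndarray, D: int, N: int
) -> tuple[np.ndarray, np.ndarray]:
    """Saltelli-2010 first-order and Jansen total-order indices from model
    evaluations over a Saltelli design (layout [A; B; AB_1..AB_D])."""
    y = np.asarray(evaluations, dtype=float)
    if y.shape != (N * (D + 2),):
        raise ValueError(f"expected {N * (D + 2)} evaluations, got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("evaluations must be finite")
    f_a = y[:N]
    f_b = y[N : 2 * N]
    v = float(np.var(np.concatenate([f_a, f_b]), ddof=0))
    if v == 0.0:
        warnings.warn("zero total variance: all indices set to 0")
        return np.zeros(D), np.zeros(D)
    fos = np.empty(D)
    tos = np.empty(D)
    for i in range(D):
        f_ab = y[(2 + i) * N : (3 + i) * N]
        fos[i] = np.mean(f_b * (f_ab - f_a)) / v
        tos[i] = 0.5 * np.mean((f_a - f_ab) ** 2) / v
    return fos, tos


def aggregate_over_ensemble(
    ensemble: ModelEnsemble,
    design: SobolDesign,
    constants: dict[str, float] | None = None,
) -> SensitivityResult:
    """Estimate FOS/TOS per fitted model on the same design and aggregate.

    The indices are computed on *predictions* — no observed targets are
    involved.  Model features excluded from the design as constant-range are
    filled from ``constants`` (see ``ParameterSpace.constant_values``).  A
    model that fails to predict is skipped and logged.
    """
    if not ensemble.models:
        raise ValueError("ensemble holds no fitted models")
    X = design.frame()
    for name, value in (constants or {}).items():
        if name not in X.columns:
            X[name] = value
    X = X[ensemble.feature_names]
    fos_runs = []
    tos_runs = []
    for s in ensemble.seeds:
        try:
            y = ensemble.models[s].predict(X)
        except Exception:  # pragma: no cover - defensive
            logger.exception("model seed %s failed to predict; run skipped", s)
            continue
        fos, tos = estimate_indices(y, D=design.D, N=design.N)
        fos_runs.append(fos)
        tos_runs.append(tos)
    if not fos_runs:
        raise ValueError("no ensemble member produced predictions")
    result = SensitivityResult(
        names=list(design.names), fos=np.stack(fos_runs), tos=np.stack(tos_runs)
    )
    strongly_negative = result.mean_fos[result.mean_fos < -0.05]
    if len(strongly_negative):
        logger.warning(
            "strongly negative first-order estimates (check N): %s",
            dict(strongly_negative),
        )
    return result


def screen_features(
    result: SensitivityResult,
    threshold: float = 0.01,
    street_prefix: str = "street",
) -> ScreenResult:
    """GSA-parsimonious set: features with mean FOS strictly above the
    threshold; the street-augmented set adds every street-type column."""
    mean_fos = result.mean_fos
    if not np.all(np.isfinite(mean_fos)):
        raise ValueError("non-finite sensitivity estimates")
    parsimonious = [f for f in result.names if mean_fos[f] > threshold]
    if not parsimonious:
        warnings.warn("GSA screening selected no features")
    streets = sorted(
        set(parsimonious) | {f for f in result.names if f.startswith(street_prefix)}
    )
    return ScreenResult(parsimonious=parsimonious, streets=streets)
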