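"""Buffer-based predictor extraction: grids -> named feature table.

For each point of interest (route point or station) and each buffer radius,
continuous layers contribute the maximum, minimum and mean of all cell
values whose cell centers lie within the radius; categorical layers
contribute the most frequent (``cat_max``) and least frequent (``cat_min``)
code among the cells present in the buffer.  Frequency ties break to the
smallest code; ``cat_min`` considers only codes actually present.  Columns
follow the ``name_stat_buffer`` convention (e.g. ``DTV_min_750``), ordered
by layer, then statistic, then radius.  Predictors are deliberately left
unscaled — random forests are insensitive to monotone rescaling — and rows
with any missing predictor are dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Grid

__all__ = [
    "BufferSpec",
    "FeatureTable",
    "continuous_buffer_stats",
    "categorical_buffer_stats",
    "build_feature_table",
]

DEFAULT_RADII = (25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 250.0, 500.0, 750.0, 1000.0)
CONTINUOUS_STATS = ("max", "min", "mean")
CATEGORICAL_STATS = ("cat_max", "cat_min")
TARGET_COLUMN = "pm25_local_max"


@dataclass(frozen=True)
class BufferSpec:
    radii: tuple[float, ...] = DEFAULT_RADII

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if len(r) == 0 or np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("radii must be strictly increasing and positive")


def _radius_label(radius: float) -> str:
    return f"{radius:g}"


def _column_name(layer: str, stat: str, radius: float) -> str:
    return f"{layer}_{stat}_{_radius_label(radius)}"


@dataclass
class FeatureTable:
    """Named predictor columns plus (optionally) the modelling target.

    ``data`` holds one row per route point or station; ``feature_names``
    fixes the deterministic column order; ``codebook`` maps each categorical
    layer to its integer code set; ``column_kind``/``column_layer`` map each
    feature column back to its layer.
    """

    data: pd.DataFrame
    feature_names: list[str]
    codebook: dict[str, list[int]] = field(default_factory=dict)
    column_kind: dict[str, str] = field(default_factory=dict)
    column_layer: dict[str, str] = field(default_factory=dict)
    target: str | None = TARGET_COLUMN

    def __post_init__(self) -> None:
        missing = [c for c in self.feature_names if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature columns missing from data: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def y(self) -> np.ndarray:
        if self.target is None or self.target not in self.data.columns:
            raise ValueError("table has no target column")
        return self.data[self.target].to_numpy(dtype=float)

    def subset(self, columns: list[str]) -> "FeatureTable":
        """Restrict to a feature subset (target and metadata preserved)."""
        columns = [c for c in self.feature_names if c in set(columns)]
        keep = columns + (
            [self.target] if self.target and self.target in self.data.columns else []
        )
        return FeatureTable(
            data=self.data[keep].copy(),
            feature_names=columns,
            codebook=self.codebook,
            column_kind={c: self.column_kind[c] for c in columns},
            column_layer={c: self.column_layer[c] for c in columns},
            target=self.target,
        )

    def take_rows(self, index) -> "FeatureTable":
        return FeatureTable(
            data=self.data.iloc[index].reset_index(drop=True),
            feature_names=list(self.feature_names),
            codebook=self.codebook,
            column_kind=self.column_kind,
            column_layer=self.column_layer,
            target=self.target,
        )

    def codes_for(self, column: str) -> list[int]:
        return self.codebook[self.column_layer[column]]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = {
            "feature_names": self.feature_names,
            "codebook": self.codebook,
            "column_kind": self.column_kind,
            "column_layer": self.column_layer,
            "target": self.target,
        }
        path.with_suffix(".codebook.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        meta = json.loads(path.with_suffix(".codebook.json").read_text())
        return cls(
            data=pd.read_csv(path),
            feature_names=meta["feature_names"],
            codebook={k: list(map(int, v)) for k, v in meta["codebook"].items()},
            column_kind=meta["column_kind"],
            column_layer=meta["column_layer"],
            target=meta["target"],
        )


# ---------------------------------------------------------------------------
# buffer statistics


def _buffer_values(grid: Grid, center: tuple[float, float], radius: float) -> np.ndarray:
    """Values of all finite cells whose centers lie within ``radius`` of
    ``center`` (inclusive).  Window-limited scan; exact for any radius."""
    x, y = float(center[0]), float(center[1])
    if not bool(np.all(grid.contains(x, y))):
        raise ValueError(f"center {center} outside grid extent")
    res = grid.resolution
    xs, ys = grid.cell_centers()
    j0 = max(int(np.floor((x - radius - grid.x0) / res)), 0)
    j1 = min(int(np.ceil((x + radius - grid.x0) / res)) + 1, grid.nx)
    i0 = max(int(np.floor((y - radius - grid.y0) / res)), 0)
    i1 = min(int(np.ceil((y + radius - grid.y0) / res)) + 1, grid.ny)
    dx = xs[j0:j1] - x
    dy = ys[i0:i1] - y
    mask = dy[:, None] ** 2 + dx[None, :] ** 2 <= radius**2
    vals = grid.values[i0:i1, j0:j1][mask]
    return vals[np.isfinite(vals)]


def continuous_buffer_stats(
    grid: Grid, center: tuple[float, float], radius: float
) -> tuple[float, float, float]:
    """(max, min, mean) over buffer cells; NaNs when the buffer is empty."""
    vals = _buffer_values(grid, center, radius)
    if len(vals) == 0:
        return (np.nan, np.nan, np.nan)
    return (float(vals.max()), float(vals.min()), float(vals.mean()))


def _cat_max_min(vals: np.ndarray) -> tuple[float, float]:
    codes, counts = np.unique(vals, return_counts=True)
    # ties break to the smallest code: np.unique returns codes ascending and
    # argmax/argmin take the first occurrence of the extreme count
    return (float(codes[np.argmax(counts)]), float(codes[np.argmin(counts)]))


def categorical_buffer_stats(
    grid: Grid, center: tuple[float, float], radius: float
) -> tuple[float, float]:
    """(cat_max, cat_min): modal and least-frequent code in the buffer."""
    vals = _buffer_values(grid, center, radius)
    if len(vals) == 0:
        return (np.nan, np.nan)
    return _cat_max_min(vals)


# ---------------------------------------------------------------------------
# feature table construction


def feature_column_names(layers: list[tuple[str, str]], spec: BufferSpec) -> list[str]:
    """Deterministic column order: layer, then statistic, then radius."""
    names: list[str] = []
    for layer, kind in layers:
        stats = CONTINUOUS_STATS if kind == "continuous" else CATEGORICAL_STATS
        for stat in stats:
            for radius in spec.radii:
                names.append(_column_name(layer, stat, radius))
    if len(set(names)) != len(names):
        raise ValueError("column name collision in feature table")
    return names


def build_feature_table(
    points: pd.DataFrame,
    layers: dict[str, tuple[str, Grid]],
    spec: BufferSpec = BufferSpec(),
    codebook: dict[str, list[int]] | None = None,
    target: str | None = TARGET_COLUMN,
) -> FeatureTable:
    """Compute buffer statistics of every layer at every point.

    ``points`` needs columns x, y and, for route points, the target column.
    ``layers`` maps layer name -> ("continuous" | "categorical", Grid); all
    grids must share the common scene grid.  The grid resolution must be at
    most half the smallest radius so even the smallest buffer holds cells.
    Rows with any missing predictor (empty buffer) are dropped.  Station and
    route tables are produced by this same code path.
    """
    kinds = {}
    grids = {}
    for name, (kind, grid) in layers.items():
        if kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {kind!r} for {name}")
        kinds[name] = kind
        grids[name] = grid
    ref = next(iter(grids.values()))
    for name, g in grids.items():
        if (g.x0, g.y0, g.resolution, g.values.shape) != (
            ref.x0,
            ref.y0,
            ref.resolution,
            ref.values.shape,
        ):
            raise ValueError(f"layer {name} not on the common grid")
    rmin = min(spec.radii)
    if ref.resolution > rmin / 2.0:
        raise ValueError(
            f"grid resolution {ref.resolution} too coarse for the smallest "
            f"buffer radius {rmin} (need <= radius/2)"
        )

    layer_items = [(n, kinds[n]) for n in layers]
    columns = feature_column_names(layer_items, spec)
    xs, ys = ref.cell_centers()
    rmax = max(spec.radii)
    res = ref.resolution

    px = points["x"].to_numpy(dtype=float)
    py = points["y"].to_numpy(dtype=float)
    n_pts = len(px)
    out = np.full((n_pts, len(columns)), np.nan)

    col_of = {c: k for k, c in enumerate(columns)}
    for p in range(n_pts):
        x, y = px[p], py[p]
        j0 = max(int(np.floor((x - rmax - ref.x0) / res)), 0)
        j1 = min(int(np.ceil((x + rmax - ref.x0) / res)) + 1, ref.nx)
        i0 = max(int(np.floor((y - rmax - ref.y0) / res)), 0)
        i1 = min(int(np.ceil((y + rmax - ref.y0) / res)) + 1, ref.ny)
        d2 = (ys[i0:i1, None] - y) ** 2 + (xs[None, j0:j1] - x) ** 2
        for radius in spec.radii:
            mask = d2 <= radius**2
            if not mask.any():
                continue
            for name, kind in layer_items:
                vals = grids[name].values[i0:i1, j0:j1][mask]
                vals = vals[np.isfinite(vals)]
                if len(vals) == 0:
                    continue
                if kind == "continuous":
                    out[p, col_of[_column_name(name, "max", radius)]] = vals.max()
                    out[p, col_of[_column_name(name, "min", radius)]] = vals.min()
                    out[p, col_of[_column_name(name, "mean", radius)]] = vals.mean()
                else:
                    cmax, cmin = _cat_max_min(vals)
                    out[p, col_of[_column_name(name, "cat_max", radius)]] = cmax
                    out[p, col_of[_column_name(name, "cat_min", radius)]] = cmin

    data = pd.DataFrame(out, columns=columns)
    data.insert(0, "x", px)
    data.insert(1, "y", py)
    has_target = target is not None and target in points.columns
    if has_target:
        data[target] = points[target].to_numpy(dtype=float)
    keep = ~data[columns + ([target] if has_target else [])].isna().any(axis=1)
    data = data.loc[keep].reset_index(drop=True)

    if codebook is None:
        codebook = {
            name: sorted(int(c) for c in np.unique(grids[name].values))
            for name, kind in layer_items
            if kind == "categorical"
        }
    column_kind = {}
    column_layer = {}
    for name, kind in layer_items:
        stats = CONTINUOUS_STATS if kind == "continuous" else CATEGORICAL_STATS
        for stat in stats:
            for radius in spec.radii:
                c = _column_name(name, stat, radius)
                column_kind[c] = kind
                column_layer[c] = name
    return FeatureTable(
        data=data,
        feature_names=columns,
        codebook=codebook,
        column_kind=column_kind,
        column_layer=column_layer,
        target=target if has_target else None,
    )
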