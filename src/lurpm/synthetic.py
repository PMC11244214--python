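"""Synthetic measurement campaign generator.

Everything the pipeline consumes — gridded predictor layers, bicycle-style
sensor tracks, and reference-station records — is generated here from a known
ground truth, so every downstream stage can be tested for *recovery* of that
truth without any external data.

The generative model
--------------------
Continuous layers are Gaussian-filtered white-noise fields rescaled to a
value range; categorical layers are contiguous patches obtained by argmax
over one smoothed field per code.  The "true" PM2.5 concentration at a
point is

    conc = background + sum_a  effect_a * scaled01(layer_a)  + round * drift + eps,

where ``scaled01`` min-max scales a layer to [0, 1] over the grid (so a
location where every active layer sits at its minimum reads exactly the
background level), ``drift`` is a linear per-round sensor drift and
``eps ~ N(0, noise_sd)``.  The concentration is floored at zero.  The *raw*
sensor reading additionally inflates the dry concentration by the
hygroscopic-growth factor C(RH; kappa_true, rho) — the exact inverse of the
preprocessing correction, making the correction round-trip testable.

Stations sample the same deterministic field without drift or humidity
inflation (reference-grade contract).  Day-to-day variation couples a
regional additive term with a ventilation-like multiplier on the local
contribution; with ``noise_sd = 0`` all stochastic terms vanish and the
daily series is constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .grids import Grid
from .preprocess import CorrectionParams, SensorTrack, correction_factor
from .validation import StationRecord

__all__ = [
    "PredictorLayerSpec",
    "GroundTruthModel",
    "SyntheticScene",
    "generate_grids",
    "serpentine_route",
    "simulate_round",
    "simulate_station",
    "default_layer_specs",
    "default_truth",
    "build_scene",
    "default_scene",
]

MAX_SPEED_KMH = 15.0


@dataclass(frozen=True)
class PredictorLayerSpec:
    """One predictor layer: continuous with a value range, or categorical
    with an integer code set; ``spatial_correlation_length`` in meters."""

    name: str
    kind: str  # "continuous" | "categorical"
    value_range: tuple[float, float] | None = None
    codes: tuple[int, ...] | None = None
    spatial_correlation_length: float = 200.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.spatial_correlation_length <= 0:
            raise ValueError("correlation length must be positive")
        if self.kind == "continuous":
            if self.value_range is None or self.value_range[0] > self.value_range[1]:
                raise ValueError(f"layer {self.name}: need value_range low <= high")
        else:
            if not self.codes:
                raise ValueError(f"layer {self.name}: categorical code set is empty")
            if any(int(c) != c for c in self.codes):
                raise ValueError(f"layer {self.name}: codes must be integers")


@dataclass(frozen=True)
class GroundTruthModel:
    """The known data-generating model a scene is built from."""

    active_layers: tuple[str, ...]
    effect_sizes: dict  # layer name -> ug/m3 per min-max-scaled unit
    background_level: float = 10.0
    noise_sd: float = 1.0
    drift_per_round: float = 0.5
    kappa_true: float = 0.4
    particle_density: float = 1.6

    def __post_init__(self) -> None:
        if not self.active_layers:
            raise ValueError("active_layers must be non-empty")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise_sd and background_level must be >= 0")
        if set(self.active_layers) != set(self.effect_sizes):
            raise ValueError("effect_sizes must cover exactly the active layers")


@dataclass
class SyntheticScene:
    """A complete synthetic campaign on a common projected grid (meters)."""

    specs: list[PredictorLayerSpec]
    grids: dict[str, Grid]
    routes: dict[str, np.ndarray]  # area_id -> (n, 2) polyline
    rounds: list[SensorTrack]
    stations: list[StationRecord]
    truth: GroundTruthModel
    seed: int
    extent: float
    resolution: float
    round_days: list[int] = field(default_factory=list)

    @property
    def inactive_layers(self) -> list[str]:
        return [s.name for s in self.specs if s.name not in self.truth.active_layers]

    def scaled_layer(self, name: str) -> Grid:
        """Layer min-max scaled to [0, 1] over the grid (constant -> 0)."""
        g = self.grids[name]
        lo, hi = float(g.values.min()), float(g.values.max())
        scaled = np.zeros_like(g.values) if hi == lo else (g.values - lo) / (hi - lo)
        return Grid(values=scaled, x0=g.x0, y0=g.y0, resolution=g.resolution)

    def local_field(self, x, y) -> np.ndarray:
        """Deterministic local (above-background) concentration at points."""
        x = np.asarray(x, dtype=float)
        total = np.zeros(x.shape, dtype=float)
        for name in self.truth.active_layers:
            total = total + self.truth.effect_sizes[name] * self.scaled_layer(
                name
            ).value_at(x, y)
        return total

    def true_concentration(self, x, y, round_index: int = 0) -> np.ndarray:
        conc = (
            self.truth.background_level
            + self.local_field(x, y)
            + round_index * self.truth.drift_per_round
        )
        return np.maximum(conc, 0.0)


# ---------------------------------------------------------------------------
# grids


def _layer_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def generate_grids(
    specs: list[PredictorLayerSpec], extent: float, resolution: float, seed: int
) -> dict[str, Grid]:
    """Generate one raster per layer spec on a common ``extent`` x ``extent``
    grid with square cells of side ``resolution`` (both meters).

    Deterministic for a given (specs, seed).  Continuous layers are smoothed
    random fields clipped (rescaled) to their value range; categorical layers
    are contiguous patches drawn from the code set.
    """
    if not specs:
        raise ValueError("empty layer spec list")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    n = int(round(extent / resolution))
    if n < 40:
        raise ValueError("extent must divide into at least 40x40 cells")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate layer names")

    grids: dict[str, Grid] = {}
    for i, spec in enumerate(specs):
        rng = _layer_rng(seed, i)
        sigma = spec.spatial_correlation_length / resolution
        if spec.kind == "continuous":
            f = gaussian_filter(rng.standard_normal((n, n)), sigma=sigma, mode="reflect")
            lo, hi = spec.value_range
            fmin, fmax = f.min(), f.max()
            if fmax == fmin or hi == lo:
                values = np.full((n, n), (lo + hi) / 2.0)
            else:
                values = lo + (f - fmin) / (fmax - fmin) * (hi - lo)
        else:
            codes = np.asarray(spec.codes, dtype=float)
            if len(codes) == 1:
                values = np.full((n, n), codes[0])
            else:
                fields = gaussian_filter(
                    rng.standard_normal((len(codes), n, n)),
                    sigma=(0, sigma, sigma),
                    mode="reflect",
                )
                values = codes[np.argmax(fields, axis=0)]
        grids[spec.name] = Grid(values=values, x0=0.0, y0=0.0, resolution=resolution)
    return grids


# ---------------------------------------------------------------------------
# routes and tracks


def serpentine_route(
    extent: float, margin: float = 100.0, lanes: int = 11
) -> np.ndarray:
    """A boustrophedon polyline covering the square extent — a compact stand-in
    for a designed bicycle transect of known length."""
    if lanes < 2:
        raise ValueError("need at least 2 lanes")
    xs = (margin, extent - margin)
    ys = np.linspace(margin, extent - margin, lanes)
    pts = []
    for i, y in enumerate(ys):
        pair = [(xs[0], y), (xs[1], y)] if i % 2 == 0 else [(xs[1], y), (xs[0], y)]
        pts.extend(pair)
    return np.asarray(pts, dtype=float)


def polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(points, axis=0).T)))


def resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length ``spacing`` (keeps both ends'
    spacing <= nominal by construction of the arc grid)."""
    seg = np.hypot(*np.diff(points, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        raise ValueError("degenerate polyline")
    n = int(np.floor(total / spacing)) + 1
    s = np.arange(n) * spacing
    x = np.interp(s, arc, points[:, 0])
    y = np.interp(s, arc, points[:, 1])
    return np.column_stack([x, y])


def _diurnal_met(time_of_day: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Smooth diurnal temperature (degC) and relative humidity (%) curves."""
    phase = 2.0 * np.pi * (time_of_day / 86400.0 - 0.30)
    temp = 18.0 + 6.0 * np.sin(phase)
    rh = 62.0 - 18.0 * np.sin(phase)
    return temp, np.clip(rh, 20.0, 95.0)


def simulate_round(
    scene: SyntheticScene,
    route_id: str,
    round_index: int,
    logging_interval: float = 2.0,
    speed: float = MAX_SPEED_KMH,
    gps_noise_sd: float = 2.0,
) -> SensorTrack:
    """Simulate one bicycle round along a scene route.

    Samples are taken every ``logging_interval`` seconds at constant
    ``speed`` (km/h, at most 15).  The raw PM reading is the true (dry)
    concentration inflated by the hygroscopic factor implied by the scene's
    ``kappa_true`` and the local RH, so preprocessing with the same kappa
    recovers the dry signal exactly.
    """
    if route_id not in scene.routes:
        raise KeyError(f"unknown route {route_id!r}")
    if speed > MAX_SPEED_KMH:
        raise ValueError(f"speed {speed} km/h exceeds the {MAX_SPEED_KMH} km/h maximum")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(scene.seed), 1000 + int(round_index)])
    )
    step = speed / 3.6 * logging_interval
    pos = resample_polyline(scene.routes[route_id], step)

    # smooth GPS jitter (correlated over ~5 samples keeps arc length stable)
    jitter = gaussian_filter1d(
        rng.normal(0.0, gps_noise_sd, size=pos.shape), sigma=5.0, axis=0, mode="nearest"
    )
    pos = pos + jitter
    lo = 0.51 * scene.resolution
    hi = scene.extent - 0.51 * scene.resolution
    pos = np.clip(pos, lo, hi)

    n = len(pos)
    t = np.arange(n, dtype=float) * logging_interval
    start = 8.0 * 3600.0 + (round_index % 5) * 3600.0
    temp, rh = _diurnal_met(start + t)

    conc = scene.true_concentration(pos[:, 0], pos[:, 1], round_index=round_index)
    if scene.truth.noise_sd > 0:
        conc = np.maximum(conc + rng.normal(0.0, scene.truth.noise_sd, size=n), 0.0)
    params = CorrectionParams(
        kappa=scene.truth.kappa_true, rho=scene.truth.particle_density
    )
    raw = conc * correction_factor(rh / 100.0, params)

    data = pd.DataFrame(
        {
            "time": t,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "pm25_raw": raw,
            "temp_c": temp,
            "rh_pct": rh,
        }
    )
    return SensorTrack(data=data, round_id=round_index, area_id=route_id)


# ---------------------------------------------------------------------------
# stations


def _day_effects(scene: SyntheticScene, days: int) -> tuple[np.ndarray, np.ndarray]:
    """Regional day effects shared by every station of a scene: an additive
    background term and a ventilation-like multiplier on the local part."""
    rng = np.random.default_rng(np.random.SeedSequence([int(scene.seed), 2000]))
    if scene.truth.noise_sd == 0:
        return np.zeros(days), np.zeros(days)
    delta = rng.normal(0.0, scene.truth.noise_sd, size=days)
    u = rng.uniform(0.0, 2.0, size=days)
    return delta, u


def simulate_station(
    scene: SyntheticScene,
    location: tuple[float, float],
    days: int,
    station_id: str = "station",
    classification: str = "urban_background",
    seed: int | None = None,
) -> StationRecord:
    """Daily reference-station series from the scene's generative model.

    No sensor drift and no humidity inflation (reference-grade contract).
    Day d reads ``background + local * (1 + u_d) + delta_d + eps_d`` floored
    at zero, with regional effects ``(delta, u)`` shared across stations and
    station noise ``eps``.  With ``noise_sd = 0`` the series is the constant
    deterministic field.
    """
    x, y = float(location[0]), float(location[1])
    anygrid = next(iter(scene.grids.values()))
    if not bool(np.all(anygrid.contains(x, y))):
        raise ValueError(f"station location {location} outside grid extent")
    if seed is None:
        seed = int(1e6 + abs(hash((round(x, 3), round(y, 3)))) % 100000)
    rng = np.random.default_rng(np.random.SeedSequence([int(scene.seed), int(seed)]))
    local = float(scene.local_field(x, y))
    delta, u = _day_effects(scene, days)
    eps = (
        rng.normal(0.0, scene.truth.noise_sd / 2.0, size=days)
        if scene.truth.noise_sd > 0
        else np.zeros(days)
    )
    values = np.maximum(
        scene.truth.background_level + local * (1.0 + u) + delta + eps, 0.0
    )
    series = pd.Series(values, index=pd.RangeIndex(days, name="day"))
    return StationRecord(
        station_id=station_id, x=x, y=y, classification=classification, series=series
    )


# ---------------------------------------------------------------------------
# default scene


def default_layer_specs() -> list[PredictorLayerSpec]:
    """Nine layers mirroring a typical urban land-use inventory: four
    continuous (LAI, DTV, PD_ha, BH) and five categorical (LCZ, LUC, BT and
    two street-type classifications)."""
    return [
        PredictorLayerSpec("LAI", "continuous", value_range=(0.0, 5.0),
                           spatial_correlation_length=200.0),
        PredictorLayerSpec("DTV", "continuous", value_range=(0.0, 30000.0),
                           spatial_correlation_length=150.0),
        PredictorLayerSpec("PD_ha", "continuous", value_range=(0.0, 500.0),
                           spatial_correlation_length=200.0),
        PredictorLayerSpec("BH", "continuous", value_range=(0.0, 40.0),
                           spatial_correlation_length=150.0),
        PredictorLayerSpec("LCZ", "categorical", codes=tuple(range(1, 12)),
                           spatial_correlation_length=250.0),
        PredictorLayerSpec("LUC", "categorical", codes=tuple(range(1, 9)),
                           spatial_correlation_length=250.0),
        PredictorLayerSpec("BT", "categorical", codes=tuple(range(1, 7)),
                           spatial_correlation_length=200.0),
        PredictorLayerSpec("street_StEP", "categorical", codes=tuple(range(1, 6)),
                           spatial_correlation_length=150.0),
        PredictorLayerSpec("street_RBS", "categorical", codes=tuple(range(1, 8)),
                           spatial_correlation_length=150.0),
    ]


def default_truth(**overrides) -> GroundTruthModel:
    """Population density, leaf area (negative) and traffic drive the field."""
    kwargs = dict(
        active_layers=("PD_ha", "LAI", "DTV"),
        effect_sizes={"PD_ha": 8.0, "LAI": -4.0, "DTV": 6.0},
        background_level=10.0,
        noise_sd=1.0,
        drift_per_round=0.5,
        kappa_true=0.4,
        particle_density=1.6,
    )
    kwargs.update(overrides)
    return GroundTruthModel(**kwargs)


#: classifications of the twelve default stations (3 background, 3 suburban,
#: 6 traffic, mirroring a regulatory urban network)
_STATION_CLASSES = (
    ["urban_background"] * 3 + ["suburban"] * 3 + ["traffic"] * 6
)


def build_scene(
    seed: int,
    specs: list[PredictorLayerSpec] | None = None,
    truth: GroundTruthModel | None = None,
    extent: float = 2000.0,
    resolution: float = 10.0,
    n_rounds: int = 8,
    n_stations: int = 12,
    station_days: int = 60,
    route_lanes: int = 12,
    logging_interval: float = 2.0,
    speed: float = MAX_SPEED_KMH,
    gps_noise_sd: float = 2.0,
) -> SyntheticScene:
    """Assemble a full synthetic scene: grids, one serpentine route, sensor
    rounds, and station records.  Deterministic for a given configuration."""
    specs = specs if specs is not None else default_layer_specs()
    truth = truth if truth is not None else default_truth()
    grids = generate_grids(specs, extent=extent, resolution=resolution, seed=seed)
    route = serpentine_route(extent, margin=100.0, lanes=route_lanes)
    scene = SyntheticScene(
        specs=specs,
        grids=grids,
        routes={"area1": route},
        rounds=[],
        stations=[],
        truth=truth,
        seed=int(seed),
        extent=float(extent),
        resolution=float(resolution),
        round_days=[3 + 5 * r for r in range(n_rounds)],
    )
    # per-round cruising speed varies below the 15 km/h cap, as real rides do;
    # this also staggers the 30 s median windows along the route across rounds
    speed_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 500]))
    round_speeds = speed * speed_rng.uniform(0.75, 1.0, size=n_rounds)
    for r in range(n_rounds):
        scene.rounds.append(
            simulate_round(
                scene,
                "area1",
                r,
                logging_interval=logging_interval,
                speed=float(round_speeds[r]),
                gps_noise_sd=gps_noise_sd,
            )
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3000]))
    margin = 150.0
    for k in range(n_stations):
        loc = tuple(rng.uniform(margin, extent - margin, size=2))
        scene.stations.append(
            simulate_station(
                scene,
                loc,
                days=station_days,
                station_id=f"S{k:02d}",
                classification=_STATION_CLASSES[k % len(_STATION_CLASSES)],
                seed=4000 + k,
            )
        )
    return scene


def default_scene(seed: int = 0, **overrides) -> SyntheticScene:
    """The package's reference study conditions: 9 layers (3 active), a
    ~23.4 km transect yielding roughly 930 route points at 25 m spacing,
    8 rounds, 12 stations."""
    return build_scene(seed, **overrides)


# ---------------------------------------------------------------------------
# scene I/O (text artifacts)


def scene_to_dir(scene: SyntheticScene, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, grid in scene.grids.items():
        grid.to_csv(path / f"grid_{name}.csv")
    for track in scene.rounds:
        track.to_csv(path / f"track_{track.area_id}_round{track.round_id:03d}.csv")
    stations = pd.DataFrame(
        {
            "station_id": [s.station_id for s in scene.stations],
            "x": [s.x for s in scene.stations],
            "y": [s.y for s in scene.stations],
            "classification": [s.classification for s in scene.stations],
        }
    )
    stations.to_csv(path / "stations.csv", index=False)
    series = pd.DataFrame(
        {s.station_id: s.series for s in scene.stations}
    )
    series.to_csv(path / "station_series.csv", index_label="day")
    for area, poly in scene.routes.items():
        pd.DataFrame(poly, columns=["x", "y"]).to_csv(
            path / f"route_{area}.csv", index=False
        )
    manifest = {
        "seed": scene.seed,
        "extent": scene.extent,
        "resolution": scene.resolution,
        "round_days": list(map(int, scene.round_days)),
        "active_layers": list(scene.truth.active_layers),
        "layers": [
            {
                "name": s.name,
                "kind": s.kind,
                "value_range": list(s.value_range) if s.value_range else None,
                "codes": list(s.codes) if s.codes else None,
                "correlation_length": s.spatial_correlation_length,
            }
            for s in scene.specs
        ],
        "truth": {
            "effect_sizes": {k: float(v) for k, v in scene.truth.effect_sizes.items()},
            "background_level": scene.truth.background_level,
            "noise_sd": scene.truth.noise_sd,
            "drift_per_round": scene.truth.drift_per_round,
            "kappa_true": scene.truth.kappa_true,
            "particle_density": scene.truth.particle_density,
        },
    }
    with (path / "scene.yaml").open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
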