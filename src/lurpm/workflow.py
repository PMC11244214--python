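"""Convenience compositions of the pipeline stages for scripted use.

These helpers run the standard stage sequence on an in-memory synthetic
scene and return the in-memory objects — handy for notebooks, examples and
experiments; the artifact-writing orchestration lives in
:mod:`lurpm.pipeline`.
"""

from __future__ import annotations

import pandas as pd

from .features import BufferSpec, FeatureTable, TARGET_COLUMN, build_feature_table
from .preprocess import CorrectionParams, PreprocessConfig, preprocess_track
from .routes import RoutePointSet, aggregate_to_route, build_ideal_route
from .synthetic import SyntheticScene

__all__ = ["route_point_set", "route_feature_table", "station_feature_table"]


def route_point_set(
    scene: SyntheticScene,
    params: CorrectionParams | None = None,
    config: PreprocessConfig = PreprocessConfig(),
    spacing: float = 25.0,
    radius: float = 25.0,
) -> RoutePointSet:
    """Preprocess every round of a scene and aggregate onto the ideal route.

    By default the humidity correction uses the scene's true kappa/rho — the
    calibrated-sensor setting.
    """
    if params is None:
        params = CorrectionParams(
            kappa=scene.truth.kappa_true, rho=scene.truth.particle_density
        )
    processed = [preprocess_track(t, params, config)[0] for t in scene.rounds]
    route = build_ideal_route(scene.rounds, spacing=spacing)
    return aggregate_to_route(
        route, processed, radius=radius, area_id=next(iter(scene.routes))
    )


def route_feature_table(
    scene: SyntheticScene,
    spec: BufferSpec = BufferSpec(),
    max_rows: int | None = None,
    **kwargs,
) -> FeatureTable:
    """Scene -> preprocessed route points -> buffer feature table with the
    per-point maximum local PM2.5 as target."""
    points = route_point_set(scene, **kwargs)
    pts = points.observed.rename(columns={"pm_max": TARGET_COLUMN})
    if max_rows is not None:
        pts = pts.iloc[:max_rows].reset_index(drop=True)
    layers = {s.name: (s.kind, scene.grids[s.name]) for s in scene.specs}
    return build_feature_table(pts, layers, spec)


def station_feature_table(
    scene: SyntheticScene, spec: BufferSpec = BufferSpec()
) -> FeatureTable:
    """Buffer features at the scene's station locations (no target) — the
    exact code path used for route points."""
    pts = pd.DataFrame(
        {"x": [s.x for s in scene.stations], "y": [s.y for s in scene.stations]}
    )
    layers = {s.name: (s.kind, scene.grids[s.name]) for s in scene.specs}
    return build_feature_table(pts, layers, spec, target=None)
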