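"""End-to-end orchestration: one config, reproducible seeds, text artifacts.

The pipeline executes, in order: simulate -> preprocess -> route -> features
-> train (baseline ensemble + hold-out validation) -> select-rfe ->
select-gsa -> validate (all requested variants, hold-out and stations) ->
report.  Every stage writes plain-text artifacts into the run directory,
stamped with a hash of the canonical config, and all randomness is routed
through seeds derived from the single config seed — the same config run
twice produces identical outputs.

The default configuration is a *demo scale* that completes in about a
minute (20 Monte-Carlo seeds, 20-tree forests with ``max_features = 1/3``,
Sobol base sample N = 128); the full-study constants (1000 seeds, N = 2048,
100-tree forests) are plain config values away.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .ensemble import SplitSpec, split_table, train_ensemble
from .features import BufferSpec, TARGET_COLUMN, build_feature_table
from .preprocess import CorrectionParams, PreprocessConfig, preprocess_track
from .rfe import RankRecord, aggregate_ranks, rfe_rank, rfecv_select
from .routes import aggregate_to_route, build_ideal_route
from .sobol import (
    aggregate_over_ensemble,
    build_parameter_space,
    round_categoricals,
    saltelli_sample,
    screen_features,
)
from .synthetic import build_scene, scene_to_dir
from .validation import hov_validate, residual_summary, station_validate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "STAGES", "MODEL_VARIANTS"]

STAGES = (
    "simulate",
    "preprocess",
    "route",
    "features",
    "train",
    "select-rfe",
    "select-gsa",
    "validate",
    "report",
)

MODEL_VARIANTS = (
    "baseline",
    "GSA_parsimonious",
    "GSA_streets",
    "RFE",
    "RFECV_baseline",
    "RFECV_parsimonious",
)


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    seed: int = 0
    # scene
    extent: float = 2000.0
    resolution: float = 10.0
    n_rounds: int = 8
    n_stations: int = 12
    station_days: int = 60
    route_lanes: int = 12
    # preprocessing
    kappa: float = 0.4
    rho: float = 1.6
    trim_fraction: float = 0.05
    median_window: float = 30.0
    background_quantile: float = 0.05
    # route aggregation
    spacing: float = 25.0
    radius: float = 25.0
    # features
    buffer_radii: tuple = (25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 250.0, 500.0, 750.0, 1000.0)
    max_rows: int | None = None  # optionally truncate the feature table
    # modelling
    train_fraction: float = 0.7
    n_seeds: int = 20
    rf_n_estimators: int = 20
    rf_max_features: float = 0.33
    # RFE / RFECV
    rfe_n_keep: int = 8
    rfe_step: int = 22
    rfecv_folds: int = 5
    rfecv_runs: int = 3
    rank_threshold: float = 2.0
    # GSA
    gsa_n_base: int = 128
    fos_threshold: float = 0.01
    # variants
    variants: tuple = MODEL_VARIANTS

    def validate(self) -> None:
        if self.n_seeds < 1:
            raise ConfigError("n_seeds must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must be in (0, 1)")
        if not 0 <= self.fos_threshold < 1:
            raise ConfigError("fos_threshold must be in [0, 1)")
        if self.rank_threshold <= 1:
            raise ConfigError("rank_threshold must exceed 1 (survivor rank)")
        if self.gsa_n_base & (self.gsa_n_base - 1):
            raise ConfigError("gsa_n_base must be a power of two")
        unknown = set(self.variants) - set(MODEL_VARIANTS)
        if unknown:
            raise ConfigError(f"unknown model variants: {sorted(unknown)}")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["buffer_radii"] = list(self.buffer_radii)
        d["variants"] = list(self.variants)
        return d

    def hash(self) -> str:
        canonical = yaml.safe_dump(self.as_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("buffer_radii", "variants"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, seed: int, **kw) -> None:
    with path.open("w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, **kw)


def run_pipeline(
    config: RunConfig, out_dir: str | Path, stages: tuple[str, ...] | None = None
) -> dict:
    """Execute the pipeline through the last requested stage.

    Returns the in-memory results dict; artifacts land in ``out_dir``.  Any
    stage failure halts with the stage name in the exception; artifacts of
    completed stages are retained.
    """
    config.validate()
    requested = STAGES if stages is None else tuple(stages)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    last = max(STAGES.index(s) for s in requested)
    todo = STAGES[: last + 1]

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    results: dict = {"config_hash": chash}
    stage = "setup"
    try:
        for stage in todo:
            _STAGE_FUNCS[stage](config, out, results)
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig, out: Path, res: dict) -> None:
    scene = build_scene(
        cfg.seed,
        extent=cfg.extent,
        resolution=cfg.resolution,
        n_rounds=cfg.n_rounds,
        n_stations=cfg.n_stations,
        station_days=cfg.station_days,
        route_lanes=cfg.route_lanes,
    )
    scene_to_dir(scene, out / "scene")
    res["scene"] = scene


def _stage_preprocess(cfg: RunConfig, out: Path, res: dict) -> None:
    scene = res["scene"]
    params = CorrectionParams(kappa=cfg.kappa, rho=cfg.rho)
    pconf = PreprocessConfig(
        trim_fraction=cfg.trim_fraction,
        median_window=cfg.median_window,
        background_quantile=cfg.background_quantile,
    )
    processed, reports = [], []
    for track in scene.rounds:
        df, report = preprocess_track(track, params, pconf)
        processed.append(df)
        reports.append(report)
    res["processed"] = processed
    res["preprocess_reports"] = reports
    _write_csv(pd.DataFrame(reports), out / "preprocess_report.csv",
               chash(res), cfg.seed, index=False)


def _stage_route(cfg: RunConfig, out: Path, res: dict) -> None:
    scene = res["scene"]
    route = build_ideal_route(scene.rounds, spacing=cfg.spacing)
    points = aggregate_to_route(route, res["processed"], radius=cfg.radius,
                                area_id=next(iter(scene.routes)))
    res["route_points"] = points
    _write_csv(points.data, out / "route_points.csv", chash(res), cfg.seed,
               index=False)


def _stage_features(cfg: RunConfig, out: Path, res: dict) -> None:
    scene = res["scene"]
    layers = {s.name: (s.kind, scene.grids[s.name]) for s in scene.specs}
    spec = BufferSpec(radii=tuple(cfg.buffer_radii))
    pts = res["route_points"].observed.rename(columns={"pm_max": TARGET_COLUMN})
    if cfg.max_rows is not None:
        pts = pts.iloc[: cfg.max_rows].reset_index(drop=True)
    table = build_feature_table(pts, layers, spec)
    station_pts = pd.DataFrame(
        {"x": [s.x for s in scene.stations], "y": [s.y for s in scene.stations]}
    )
    station_table = build_feature_table(station_pts, layers, spec, target=None)
    res["table"] = table
    res["station_table"] = station_table
    _write_csv(table.data, out / "features.csv", chash(res), cfg.seed, index=False)
    _write_csv(station_table.data, out / "station_features.csv", chash(res),
               cfg.seed, index=False)
    (out / "codebook.json").write_text(json.dumps(table.codebook, indent=1))


def _rf_params(cfg: RunConfig) -> dict:
    return dict(n_estimators=cfg.rf_n_estimators, max_features=cfg.rf_max_features)


def _stage_train(cfg: RunConfig, out: Path, res: dict) -> None:
    table = res["table"]
    train, test = split_table(
        table, SplitSpec(train_fraction=cfg.train_fraction, seed=cfg.seed)
    )
    res["train"], res["test"] = train, test
    ensemble = train_ensemble(train, seeds=range(cfg.n_seeds), **_rf_params(cfg))
    res["ensembles"] = {"baseline": ensemble}
    report = hov_validate(ensemble, test, "baseline")
    res["hov_reports"] = {"baseline": report}
    _write_csv(report.per_seed_metrics, out / "train_metrics_baseline.csv",
               chash(res), cfg.seed)


def _stage_select_rfe(cfg: RunConfig, out: Path, res: dict) -> None:
    if not {"RFE", "RFECV_parsimonious"} & set(cfg.variants):
        logger.info("no RFE-based variant requested; stage skipped")
        return
    train = res["train"]
    rf = _rf_params(cfg)
    ranks_rfe = rfe_rank(train, seed=cfg.seed, n_keep=cfg.rfe_n_keep,
                         step=cfg.rfe_step, **rf)
    res["rfe_set"] = sorted(f for f, r in ranks_rfe.items() if r == 1)
    record = RankRecord()
    for k in range(cfg.rfecv_runs):
        _, ranking, _ = rfecv_select(
            train, seed=cfg.seed * 1000 + k, folds=cfg.rfecv_folds,
            step=cfg.rfe_step, **rf,
        )
        record.add(cfg.seed * 1000 + k, ranking)
    res["rfecv_record"] = record
    res["rfecv_set"] = aggregate_ranks(record, threshold=cfg.rank_threshold)
    _write_csv(record.to_frame(), out / "rfecv_ranks.csv", chash(res), cfg.seed)
    (out / "selected_rfe.json").write_text(
        json.dumps({"RFE": res["rfe_set"], "RFECV_parsimonious": res["rfecv_set"]},
                   indent=1)
    )


def _stage_select_gsa(cfg: RunConfig, out: Path, res: dict) -> None:
    if not {"GSA_parsimonious", "GSA_streets"} & set(cfg.variants):
        logger.info("no GSA-based variant requested; stage skipped")
        return
    table = res["table"]
    space = build_parameter_space(table)
    design = round_categoricals(
        saltelli_sample(space, N=cfg.gsa_n_base, seed=cfg.seed), space
    )
    result = aggregate_over_ensemble(res["ensembles"]["baseline"], design,
                                 constants=space.constant_values)
    screen = screen_features(result, threshold=cfg.fos_threshold)
    res["gsa_result"] = result
    res["gsa_set"] = screen.parsimonious
    res["gsa_streets_set"] = screen.streets
    _write_csv(result.to_frame(), out / "sobol_indices.csv", chash(res), cfg.seed)
    (out / "selected_gsa.json").write_text(
        json.dumps({"GSA_parsimonious": screen.parsimonious,
                    "GSA_streets": screen.streets}, indent=1)
    )


def _variant_features(cfg: RunConfig, res: dict, variant: str) -> list[str]:
    table = res["table"]
    if variant in ("baseline", "RFECV_baseline"):
        return list(table.feature_names)
    if variant == "GSA_parsimonious":
        return res["gsa_set"]
    if variant == "GSA_streets":
        return res["gsa_streets_set"]
    if variant == "RFE":
        return res["rfe_set"]
    if variant == "RFECV_parsimonious":
        return res["rfecv_set"]
    raise ConfigError(f"unknown variant {variant}")


def _stage_validate(cfg: RunConfig, out: Path, res: dict) -> None:
    scene = res["scene"]
    train, test = res["train"], res["test"]
    rf = _rf_params(cfg)
    hov_rows = []
    for variant in cfg.variants:
        feats = _variant_features(cfg, res, variant)
        if not feats:
            logger.warning("variant %s selected no features; skipped", variant)
            continue
        if variant not in res["ensembles"]:
            res["ensembles"][variant] = train_ensemble(
                train.subset(feats), seeds=range(cfg.n_seeds), **rf
            )
        report = hov_validate(res["ensembles"][variant], test, variant)
        res["hov_reports"][variant] = report
        hov_rows.append({"model_id": variant, "n_features": len(feats),
                         **report.aggregate.as_dict()})
    hov_df = pd.DataFrame(hov_rows).set_index("model_id")
    res["hov_summary"] = hov_df
    _write_csv(hov_df, out / "hov_summary.csv", chash(res), cfg.seed)

    station_reports = station_validate(
        {v: res["ensembles"][v] for v in res["hov_reports"]},
        res["station_table"],
        scene.stations,
        scene.round_days,
        q=cfg.background_quantile,
    )
    res["station_reports"] = station_reports
    rows = []
    rmse_rows = {}
    for variant, rep in station_reports.items():
        rows.append({"model_id": variant, **rep.pooled.as_dict()})
        rmse_rows[variant] = rep.per_station_rmse
        _write_csv(residual_summary(rep), out / f"residuals_{variant}.csv",
                   chash(res), cfg.seed)
        _write_csv(rep.qq(), out / f"qq_station_{variant}.csv", chash(res),
                   cfg.seed, index=False)
    from .plots import plot_qq, plot_station_abs_errors

    for variant, rep in res["hov_reports"].items():
        plot_qq(rep.qq, out / f"qq_hov_{variant}.png", title=variant)
    plot_station_abs_errors(station_reports, out / "station_abs_errors.png")
    station_df = pd.DataFrame(rows).set_index("model_id")
    res["station_summary"] = station_df
    res["station_rmse_table"] = pd.DataFrame(rmse_rows)
    _write_csv(station_df, out / "station_summary.csv", chash(res), cfg.seed)
    _write_csv(res["station_rmse_table"], out / "station_rmse_table.csv",
               chash(res), cfg.seed)


def _stage_report(cfg: RunConfig, out: Path, res: dict) -> None:
    summary = {
        "config_hash": res["config_hash"],
        "seed": cfg.seed,
        "n_rows": len(res["table"]),
        "n_features_baseline": len(res["table"].feature_names),
        "selected": {
            v: _variant_features(cfg, res, v)
            for v in cfg.variants
            if v in res.get("hov_reports", {}) and v not in ("baseline", "RFECV_baseline")
        },
        "hov": {k: dict(r) for k, r in res["hov_summary"].round(6).iterrows()},
        "stations": {
            k: dict(r) for k, r in res["station_summary"].round(6).iterrows()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    cfg.to_yaml(out / "config.yaml")


def chash(res: dict) -> str:
    return res["config_hash"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "route": _stage_route,
    "features": _stage_features,
    "train": _stage_train,
    "select-rfe": _stage_select_rfe,
    "select-gsa": _stage_select_gsa,
    "validate": _stage_validate,
    "report": _stage_report,
}
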