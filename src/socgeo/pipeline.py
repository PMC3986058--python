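"""End-to-end pipeline: simulate/load -> describe -> scale -> krige -> stocks.

A run is driven by a :class:`RunConfig` (optionally parsed from TOML).
One master seed feeds every stochastic stage through deterministically
derived substreams, so identical configurations produce byte-identical
reports and individual stages can be re-run in isolation.  Each stage
records its summary numbers and any warnings in the JSON report;
failures mark the stage and skip its dependents, and the run exits
nonzero.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset_io, descriptives, geostat, relationships, scaling, stocks
from .dataset_io import LAYERS, LocationGrid
from .errors import ConfigError, SocgeoError
from .synthetic_data import default_survey_params, simulate_survey

log = logging.getLogger("socgeo")

STAGES = ("simulate", "describe", "scaling", "variogram", "krige",
          "crossval", "relate", "stocks")

_COVARIATE_COLUMNS = ("stones", "sand", "silt", "clay", "bd")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "socgeo_out"
    input_path: str | None = None  #: CSV to load; None -> simulate
    layers: tuple[str, ...] = LAYERS
    area_width_km: int = 5
    area_height_km: int = 8
    grid_spacing_m: float = 500.0
    scale: str = "ln"               #: variogram/kriging analysis scale
    lag_width_m: float = 500.0
    max_dist_m: float = 4700.0
    weighting: str = "npairs"
    cell_size_m: float = 500.0
    back_transform: str = "lognormal"
    alpha_in: float = 0.05
    alpha_out: float = 0.10
    delta_percent: float = 5.0
    confidence: float = 0.95
    nrs_areas_km2: tuple[float, ...] = (1.0, 100.0, 1000.0)
    area_km2: float = 40.0
    apply_cf: bool = True
    enabled: tuple[str, ...] = STAGES

    def validate(self) -> None:
        bad = [ly for ly in self.layers if ly not in LAYERS]
        if bad:
            raise ConfigError(f"unknown layer label(s) {bad}; expected {LAYERS}")
        bad = [s for s in self.enabled if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stage(s) {bad}; expected {STAGES}")
        if self.scale not in ("ln", "raw"):
            raise ConfigError("scale must be 'ln' or 'raw'")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Parse a TOML run configuration.

    Recognised tables: ``[run]`` (seed, outdir, input, layers, stages),
    ``[variogram]``, ``[krige]``, ``[scaling]``, ``[stepwise]``,
    ``[stocks]``; unknown keys raise a :class:`ConfigError`.
    """
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    mapping = {
        ("run", "seed"): "seed",
        ("run", "outdir"): "outdir",
        ("run", "input"): "input_path",
        ("run", "layers"): "layers",
        ("run", "stages"): "enabled",
        ("run", "area_width_km"): "area_width_km",
        ("run", "area_height_km"): "area_height_km",
        ("run", "grid_spacing_m"): "grid_spacing_m",
        ("variogram", "scale"): "scale",
        ("variogram", "lag_width_m"): "lag_width_m",
        ("variogram", "max_dist_m"): "max_dist_m",
        ("variogram", "weighting"): "weighting",
        ("krige", "cell_size_m"): "cell_size_m",
        ("krige", "back_transform"): "back_transform",
        ("stepwise", "alpha_in"): "alpha_in",
        ("stepwise", "alpha_out"): "alpha_out",
        ("scaling", "delta_percent"): "delta_percent",
        ("scaling", "confidence"): "confidence",
        ("scaling", "nrs_areas_km2"): "nrs_areas_km2",
        ("stocks", "area_km2"): "area_km2",
        ("stocks", "apply_cf"): "apply_cf",
    }
    kwargs = {}
    for section, table in raw.items():
        if not isinstance(table, dict):
            raise ConfigError(f"top-level key {section!r} must be a table")
        for key, value in table.items():
            target = mapping.get((section, key))
            if target is None:
                raise ConfigError(f"unknown config key [{section}] {key}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[target] = value
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def _stage_logger(report, name):
    """Context manager capturing warnings into the report block."""
    import contextlib

    @contextlib.contextmanager
    def ctx():
        block = {"status": "ok", "warnings": []}
        report["stages"][name] = block
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                yield block
            except SocgeoError as exc:
                block["status"] = "failed"
                block["error"] = f"{type(exc).__name__}: {exc}"
                log.warning("stage %s failed: %s", name, exc)
            finally:
                block["warnings"] = sorted({str(w.message) for w in caught})
    return ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages in dependency order; returns the report.

    Artifacts (sample CSV, summary CSV, semivariogram CSV, prediction
    and variance rasters, report JSON) are written under
    ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    grid = LocationGrid(config.area_width_km * 1000.0,
                        config.area_height_km * 1000.0,
                        config.grid_spacing_m)

    samples = None
    with _stage_logger(report, "simulate") as block:
        if config.input_path:
            samples = dataset_io.read_samples(config.input_path)
            block["source"] = "file"
            block["path"] = str(config.input_path)
        else:
            params = {ly: default_survey_params()[ly] for ly in config.layers}
            samples = simulate_survey(params, seed=config.seed, grid=grid)
            block["source"] = "simulated"
        block["n_records"] = int(len(samples))
        block["n_locations"] = int(
            samples.groupby(["x", "y"]).ngroups
        )
        dataset_io.write_samples(samples, outdir / "samples.csv")

    if samples is None:
        report["status"] = "failed"
        return report

    per_layer = {ly: samples[samples["layer"] == ly] for ly in config.layers}

    if "describe" in config.enabled:
        with _stage_logger(report, "describe") as block:
            rows = []
            for ly, sub in per_layer.items():
                s = descriptives.summarize(sub["soc"])
                rows.append({"layer": ly, **dataclasses.asdict(s)})
                block[ly] = {
                    "mean": s.mean, "cv_percent": s.cv_percent,
                    "skewness": s.skewness, "ks_p": s.ks_p,
                    "log_transform": s.log_transform,
                }
            groups = [per_layer[ly]["soc"].to_numpy() for ly in config.layers]
            if len(groups) >= 2:
                lsd = descriptives.anova_lsd(groups)
                block["anova"] = {
                    "f": lsd.f, "p": lsd.p,
                    "letters": dict(zip(config.layers, lsd.letters)),
                }
            pd.DataFrame(rows).to_csv(outdir / "summary.csv", index=False)

    if "scaling" in config.enabled:
        with _stage_logger(report, "scaling") as block:
            for ly, sub in per_layer.items():
                curve = scaling.cv_area_curve(
                    sub, config.area_width_km, config.area_height_km
                )
                fit = scaling.fit_power(curve)
                nrs = {
                    str(a): scaling.required_samples(
                        fit.cv_at(a), config.delta_percent, config.confidence
                    )
                    for a in config.nrs_areas_km2
                }
                block[ly] = {"a": fit.a, "b": fit.b, "r2": fit.r2, "nrs": nrs}
                curve.to_frame().to_csv(
                    outdir / f"cv_area_{ly}.csv", index=False
                )

    models: dict[str, geostat.VariogramModel] = {}
    if "variogram" in config.enabled:
        with _stage_logger(report, "variogram") as block:
            for ly, sub in per_layer.items():
                sv = geostat.semivariogram_from_samples(
                    sub, scale=config.scale,
                    lag_width=config.lag_width_m, max_dist=config.max_dist_m,
                )
                model = geostat.select_model(sv, weighting=config.weighting)
                models[ly] = model
                block[ly] = {
                    "family": model.family,
                    "nugget": model.nugget,
                    "sill": model.sill,
                    "nugget_ratio": model.nugget_ratio,
                    "effective_range_m": model.range_m,
                    "r2": model.r2,
                    "rss": model.rss,
                    "dependence": (
                        geostat.classify_dependence(model.nugget_ratio)
                        if np.isfinite(model.nugget_ratio) else "undefined"
                    ),
                }
                pd.DataFrame({
                    "lag_m": sv.lag, "gamma": sv.gamma, "n_pairs": sv.n_pairs,
                }).to_csv(outdir / f"semivariogram_{ly}.csv", index=False)

    def _analysis_values(sub):
        vals = sub["soc"].to_numpy(float)
        return np.log(vals) if config.scale == "ln" else vals

    if "krige" in config.enabled:
        with _stage_logger(report, "krige") as block:
            if not models:
                raise SocgeoError("variogram stage did not produce models")
            for ly, sub in per_layer.items():
                coords = sub[["x", "y"]].to_numpy(float)
                kmap = geostat.krige_map(
                    coords, _analysis_values(sub), models[ly],
                    config.cell_size_m,
                    extent=(0.0, grid.width_m, 0.0, grid.height_m),
                    back_transform=(config.back_transform
                                    if config.scale == "ln" else None),
                )
                dataset_io.write_raster(
                    kmap.predictions, config.cell_size_m, (0.0, 0.0),
                    outdir / f"soc_pred_{ly}.asc",
                )
                dataset_io.write_raster(
                    kmap.variances, config.cell_size_m, (0.0, 0.0),
                    outdir / f"soc_krigvar_{ly}.asc",
                )
                block[ly] = {
                    "cell_size_m": config.cell_size_m,
                    "mean_prediction": float(np.nanmean(kmap.predictions)),
                    "back_transform": kmap.back_transform,
                }

    if "crossval" in config.enabled:
        with _stage_logger(report, "crossval") as block:
            if not models:
                raise SocgeoError("variogram stage did not produce models")
            for ly, sub in per_layer.items():
                coords = sub[["x", "y"]].to_numpy(float)
                cv = geostat.loo_cross_validate(
                    coords, _analysis_values(sub), models[ly]
                )
                block[ly] = {"me": cv.me, "rmse": cv.rmse, "rmsse": cv.rmsse}

    if "relate" in config.enabled:
        with _stage_logger(report, "relate") as block:
            for ly, sub in per_layer.items():
                cols = ["soc", *_COVARIATE_COLUMNS]
                cm = relationships.pearson_matrix(sub, cols)
                step = relationships.stepwise_regression(
                    sub["soc"].to_numpy(float), sub[list(_COVARIATE_COLUMNS)],
                    config.alpha_in, config.alpha_out,
                )
                block[ly] = {
                    "r_soc": {c: float(cm.r.loc["soc", c])
                              for c in _COVARIATE_COLUMNS},
                    "stepwise": {
                        "variables": list(step.variables),
                        "coefficients": step.coefficients,
                        "explained_variance": list(step.explained_variance),
                        "adj_r2": step.adj_r2,
                        "mse": step.mse,
                    },
                }

    if "stocks" in config.enabled:
        with _stage_logger(report, "stocks") as block:
            for flag in (True, False):
                est = stocks.survey_stocks(
                    samples, config.area_km2 * 1e6, apply_cf=flag
                )
                key = "with_cf" if flag else "without_cf"
                block[key] = {
                    "layer_density_kg_m2": list(est.layer_density_kg_m2),
                    "cumulative_kg_m2": list(est.cumulative_kg_m2),
                    "total_kg_c": est.total_kg_c,
                }
            block["applied"] = "with_cf" if config.apply_cf else "without_cf"

    failed = [s for s, b in report["stages"].items() if b["status"] != "ok"]
    report["status"] = "failed" if failed else "ok"
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
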