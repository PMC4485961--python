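"""End-to-end pipeline: simulate -> fit -> bootstrap -> kernels -> ballistic.

Configuration is a plain mapping (typically loaded from YAML/JSON) validated
against a fixed schema; every stochastic stage carries an explicit seed, and
the run manifest records inputs, seeds and SHA-256 digests of every artifact
so that identical configurations reproduce identical outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import fixtures as fx
from .ballistic_model import calibrate_from_anchors, comparison_table
from .dispersal_lmm import (
    compare_wind_covariates,
    design_from_frame,
    fit_lmm,
    read_releases_csv,
    write_fit_json,
)
from .kernel_simulation import empirical_summaries, kernel_bands, kernel_closed_form, kernel_grid, KernelRequest, write_kernel_csv
from .parametric_bootstrap import bootstrap, percentile_interval, PARAMETER_NAMES
from .synthetic_data import write_releases

logger = logging.getLogger("samaradisp")

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "default_config"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a pipeline configuration."""


_DEFAULTS: dict = {
    "out_dir": "samaradisp_run",
    "stages": ["simulate", "fit", "bootstrap", "kernels", "ballistic", "report"],
    "seed_simulate": 1,
    "seed_bootstrap": 2,
    "wind_choice": "max",
    "method": "REML",
    "bootstrap_B": 200,
    "kernel_iwl": [1, 10, 20, 30, 40, 50],
    "kernel_wind": [1, 2, 4, 6, 8, 10],
    "include_species_effect": False,
    "ballistic_height": fx.RELEASE_HEIGHT_M,
    "ballistic_wind": fx.MEAN_MAX_WIND_MS,
    "ballistic_anchors": list(fx.DEFAULT_BALLISTIC_ANCHORS),
    "releases_csv": None,  # use an existing dataset instead of simulating
}

_STAGES = ("simulate", "fit", "bootstrap", "kernels", "ballistic", "report")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected by name."""

    values: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: Mapping | None) -> "PipelineConfig":
        mapping = dict(mapping or {})
        unknown = sorted(set(mapping) - set(_DEFAULTS))
        if unknown:
            raise ConfigError(f"unknown configuration keys: {unknown}")
        values = {**_DEFAULTS, **mapping}
        bad = sorted(set(values["stages"]) - set(_STAGES))
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        if values["wind_choice"] not in ("max", "mean"):
            raise ConfigError("wind_choice must be 'max' or 'mean'")
        if int(values["bootstrap_B"]) < 1:
            raise ConfigError("bootstrap_B must be >= 1")
        return cls(values=values)

    def __getitem__(self, key):
        return self.values[key]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def default_config(**overrides) -> PipelineConfig:
    return PipelineConfig.from_mapping(overrides)


def run_pipeline(config: PipelineConfig | Mapping | None = None) -> dict:
    """Run the enabled stages in order; returns (and writes) the run manifest."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_mapping(config)
    cfg = config.values
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in _STAGES if s in cfg["stages"]]
    manifest: dict = {"config": {k: v for k, v in cfg.items()}, "stages": {}, "artifacts": {}}
    artifacts: dict[str, Path] = {}

    df = fit = boot = None
    try:
        for stage in stages:
            logger.info("stage %s starting", stage)
            if stage == "simulate":
                gen_cfg = fx.default_generator_config(rng_seed=int(cfg["seed_simulate"]))
                csv_path, truth_path = write_releases(gen_cfg, out)
                artifacts["releases.csv"] = csv_path
                artifacts["truth.json"] = truth_path
                manifest["stages"]["simulate"] = {"seed": int(cfg["seed_simulate"]), "n_obs": int(pd.read_csv(csv_path).shape[0])}
            elif stage == "fit":
                source = cfg["releases_csv"] or artifacts.get("releases.csv")
                if source is None:
                    raise ConfigError("fit stage needs a simulated or provided releases.csv")
                df = read_releases_csv(source)
                y, X, g, levels = design_from_frame(df, wind_choice=cfg["wind_choice"])
                fit = fit_lmm(y, X, g, method=cfg["method"])
                fit_path = out / "fit.json"
                write_fit_json(fit, fit_path)
                artifacts["fit.json"] = fit_path
                aic_max, aic_mean, selected = compare_wind_covariates(df)
                manifest["stages"]["fit"] = {
                    "wind_choice": cfg["wind_choice"],
                    "method": cfg["method"],
                    "aic_max_wind": aic_max,
                    "aic_mean_wind": aic_mean,
                    "aic_selected": selected,
                    "params": fit.params.to_dict(),
                }
            elif stage == "bootstrap":
                if fit is None or df is None:
                    raise ConfigError("bootstrap stage requires the fit stage")
                y, X, g, _ = design_from_frame(df, wind_choice=cfg["wind_choice"])
                boot = bootstrap(fit, X, g, B=int(cfg["bootstrap_B"]), base_seed=int(cfg["seed_bootstrap"]))
                intervals = {
                    name: percentile_interval(boot, name, 0.95, point=getattr(fit.params, name)).__dict__
                    for name in PARAMETER_NAMES
                }
                boot_path = out / "boot.json"
                with open(boot_path, "w", encoding="utf-8") as fh:
                    json.dump(
                        {
                            "B": boot.B,
                            "refit_failures": boot.refit_failures,
                            "base_seed": boot.base_seed,
                            "parameter_names": list(PARAMETER_NAMES),
                            "draws": boot.draws.tolist(),
                            "intervals": intervals,
                        },
                        fh,
                        indent=2,
                    )
                artifacts["boot.json"] = boot_path
                manifest["stages"]["bootstrap"] = {
                    "B": boot.B,
                    "refit_failures": boot.refit_failures,
                    "seed": int(cfg["seed_bootstrap"]),
                }
            elif stage == "kernels":
                if fit is None:
                    raise ConfigError("kernels stage requires the fit stage")
                kdir = out / "kernels"
                kdir.mkdir(exist_ok=True)
                summary = kernel_grid(
                    fit.params, cfg["kernel_iwl"], cfg["kernel_wind"],
                    include_species_effect=bool(cfg["include_species_effect"]),
                )
                summary_path = kdir / "kernel_summary.csv"
                summary.to_csv(summary_path, index=False)
                artifacts["kernels/kernel_summary.csv"] = summary_path
                for row in summary.itertuples():
                    req = KernelRequest(
                        iwl=float(row.iwl), wind=float(row.wind),
                        include_species_effect=bool(cfg["include_species_effect"]),
                    )
                    k = (
                        kernel_bands(boot, req)
                        if boot is not None and boot.n_retained >= 40
                        else kernel_closed_form(fit.params, req)
                    )
                    rel = f"kernels/kernel_iwl{row.iwl:g}_wind{row.wind:g}.csv"
                    write_kernel_csv(k, out / rel)
                    artifacts[rel] = out / rel
                manifest["stages"]["kernels"] = {
                    "n_kernels": int(summary.shape[0]),
                    "banded": boot is not None,
                }
            elif stage == "ballistic":
                if fit is None:
                    raise ConfigError("ballistic stage requires the fit stage")
                t3 = fx.table3()
                anchors = [
                    (float(r.sqrt_wl_printed), float(r.ballistic_m))
                    for r in t3.itertuples()
                    if r.species in set(cfg["ballistic_anchors"])
                ]
                bal = calibrate_from_anchors(
                    anchors,
                    wind_speed=float(cfg["ballistic_wind"]),
                    release_height=float(cfg["ballistic_height"]),
                )
                rows = [
                    (r.species, float(r.mean_iwl), float(r.sqrt_wl_printed) if r.mean_iwl > 0 else None)
                    for r in t3.itertuples()
                ]
                comp = comparison_table(fit.params, bal, rows)
                comp_path = out / "comparison.csv"
                comp.to_csv(comp_path, index=False)
                artifacts["comparison.csv"] = comp_path
                manifest["stages"]["ballistic"] = {
                    "vt_intercept": bal.vt_intercept,
                    "vt_slope": bal.vt_slope,
                    "height_m": bal.release_height,
                    "wind_ms": bal.wind_speed,
                }
            elif stage == "report":
                if df is None:
                    raise ConfigError("report stage requires data (fit stage)")
                per, pooled = empirical_summaries(df)
                report_path = out / "summary.csv"
                per.to_csv(report_path, index=False)
                artifacts["summary.csv"] = report_path
                manifest["stages"]["report"] = {"pooled": pooled}
            logger.info("stage %s done", stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest["artifacts"] = {k: _sha256(p) for k, p in artifacts.items()}
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    manifest["artifacts"] = {k: _sha256(p) for k, p in artifacts.items()}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
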