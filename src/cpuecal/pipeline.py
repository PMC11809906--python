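"""Pipeline driver: simulate -> census -> cpue -> rarefy -> fit -> evaluate.

A run configuration (dict or YAML) drives a deterministic artifact directory:
captures.csv, effort.csv, truth_panel.csv, panel.csv, per-scheme rarefied
panels, fits.json, predictions.csv, evaluation.csv and run.json. Re-running
the same config reproduces identical numbers; all randomness flows from the
single config seed.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .census import CensusConfig, census_panel
from .cpue import build_panel
from .evaluation import scheme_grid_report
from .glm import predict_density, select_terms
from .io import (
    read_captures,
    read_effort,
    validate_tables,
    write_captures,
    write_effort,
    write_fits,
    write_table,
)
from .rarefaction import TEMPORAL_CODES, rebuild_panel, spatial_scheme_from_spec
from .simulate import SimConfig, paper_like_config, simulate_dataset

logger = logging.getLogger(__name__)

DEFAULT_SCHEMES = [{"temporal": code, "coverage": 29} for code in TEMPORAL_CODES]


class PipelineError(RuntimeError):
    """A stage failed; message carries the stage name and offending record."""


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _sim_config(config: dict) -> SimConfig:
    block = dict(config.get("simulate", {}))
    preset = block.pop("preset", "paper-like")
    block.setdefault("seed", config.get("seed", 0))
    if "removal_schedule" in block:
        block["removal_schedule"] = tuple(tuple(x) for x in block["removal_schedule"])
    if preset == "paper-like":
        return paper_like_config(**block)
    return SimConfig(**block)


def _census_config(config: dict) -> CensusConfig:
    return CensusConfig(**config.get("census", {}))


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the full pipeline into *out_dir*; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    meta = {"seed": seed, "cpuecal_version": __version__}
    sim_cfg = _sim_config(config)
    include_trapping = config.get("trapping", True)

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        name = stage("simulate")
        paths = config.get("paths", {})
        if "captures" in paths and "effort" in paths:
            captures = read_captures(paths["captures"])
            effort = read_effort(paths["effort"])
            growth_rates = {
                int(k): float(v) for k, v in config.get("growth_rates", {}).items()
            }
            removals = {
                int(k): v for k, v in config.get("removals", {}).items()
            }
        else:
            dataset = simulate_dataset(
                sim_cfg,
                nights_per_week=config.get("nights_per_week", 4),
                include_trapping=include_trapping,
            )
            captures, effort = dataset.captures, dataset.effort
            growth_rates, removals = dataset.growth_rates, dataset.removals
            write_table(dataset.truth, out / "true_panel.csv", meta)
        write_captures(captures, out / "captures.csv", meta)
        write_effort(effort, out / "effort.csv", meta)

        name = stage("validate")
        report = validate_tables(captures, effort, sim_cfg)
        if not report:
            first = report.errors[0]
            raise PipelineError(f"stage {name}: row {first[1]}: {first[2]}")

        name = stage("census")
        census_cfg = _census_config(config)
        truth = census_panel(
            captures,
            growth_rates,
            census_cfg,
            removals=removals,
            censor_month=sim_cfg.months[-1],
            months=sim_cfg.months,
        )
        write_table(truth, out / "truth_panel.csv", meta)

        name = stage("cpue")
        panel = build_panel(truth, captures, effort)
        write_table(panel, out / "panel.csv", meta)

        name = stage("fit")
        family = config.get("family", "poisson")
        area = census_cfg.enclosure_area_ha
        fits = {}
        sel = select_terms(panel, family=family, response="total",
                           predictor="visual", area_ha=area)
        fits["visual"] = sel["fit"].to_dict()
        full_fit = sel["fit"]
        trap_rows = panel[["N_gt900", "cpue_trap"]].dropna()
        if include_trapping and len(trap_rows) >= 4:
            trap_sel = select_terms(panel, family=family, response="gt900",
                                    predictor="trap", area_ha=area)
            fits["trap"] = trap_sel["fit"].to_dict()
        write_fits(fits, out / "fits.json", meta)

        vis_rows = panel[["month", "cpue_visual", "density"]].dropna()
        preds = predict_density(full_fit, vis_rows["cpue_visual"].to_numpy())
        preds.insert(0, "month", vis_rows["month"].to_numpy())
        write_table(preds, out / "predictions.csv", meta)

        name = stage("rarefy+evaluate")
        schemes = config.get("schemes", DEFAULT_SCHEMES)
        panels = {}
        for sch in schemes:
            temporal = sch.get("temporal")
            coverage = sch.get("coverage", sim_cfg.n_transects)
            spatial = spatial_scheme_from_spec(coverage, sim_cfg)
            label = f"{temporal or 'full'}-{spatial.label}"
            panels[label] = rebuild_panel(
                truth, captures, effort,
                temporal=temporal, spatial=spatial, config=sim_cfg, seed=seed,
            )
        eval_family = config.get("eval_family", "negative_binomial")
        eval_terms = config.get("eval_terms", "quadratic")
        report_df = scheme_grid_report(
            panels, family=eval_family, terms=eval_terms, area_ha=area, seed=seed
        )
        write_table(report_df, out / "evaluation.csv", meta)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage {name} failed: {err}") from err

    run_info = {
        **meta,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": _jsonable(config),
    }
    (out / "run.json").write_text(json.dumps(run_info, indent=2, sort_keys=True))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (pd.Period, pd.Timestamp)):
        return str(obj)
    return obj
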