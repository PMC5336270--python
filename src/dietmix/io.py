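"""Run-table CSV and config readers, and the end-to-end pipeline driver.

The run-table schema (one row per experimental run) is::

    run_id,mixture_no,yeast_pct,cornflour_pct,corncob_pct,n_larvae,
    pupation,duration_days,pupal_weight_mg,emergence,excluded_responses

Empty cells are missing values (never zero); ``excluded_responses`` is a
semicolon-separated list of response names, or empty.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cost as cost_mod
from . import optimize as opt_mod
from .design import (
    BLEND_COLUMNS,
    RESPONSE_COLUMNS,
    RUN_TABLE_COLUMNS,
    STUDY_SPACE,
    MixtureSpace,
    validate_blend,
)
from .diagnostics import FlagThresholds, exclusion_workflow
from .scheffe import backward_eliminate, fit, ladder_termset, sequential_selection

__all__ = [
    "read_run_table",
    "write_run_table",
    "load_config",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("dietmix")

#: default transform per response: proportions with heteroscedastic spread
#: (emergence) are arcsine-square-root transformed, everything else fitted raw.
DEFAULT_TRANSFORMS = {
    "pupation": "none",
    "duration_days": "none",
    "pupal_weight_mg": "none",
    "emergence": "arcsine_sqrt",
}


def read_run_table(path, space: MixtureSpace = STUDY_SPACE) -> pd.DataFrame:
    """Read and validate a run-table CSV.

    Raises ``ValueError`` listing missing columns, duplicate run ids,
    out-of-range proportions (with the offending run id) or blend-bound
    violations.
    """
    df = pd.read_csv(path)
    missing = [c for c in RUN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"run table is missing columns: {missing}")
    df = df[RUN_TABLE_COLUMNS].copy()
    if df.empty:
        raise ValueError("run table has no rows")
    if df["run_id"].duplicated().any():
        dups = df.loc[df["run_id"].duplicated(), "run_id"].tolist()
        raise ValueError(f"duplicate run_id values: {dups}")
    df["excluded_responses"] = df["excluded_responses"].fillna("").astype(str)
    df.loc[df["excluded_responses"].str.lower() == "nan", "excluded_responses"] = ""
    for _, row in df.iterrows():
        validate_blend(row[BLEND_COLUMNS].to_numpy(float), space)
    for prop in ("pupation", "emergence"):
        vals = df[prop]
        bad = df.loc[vals.notna() & ((vals < 0) | (vals > 1)), "run_id"]
        if len(bad):
            raise ValueError(f"{prop} outside [0, 1] for run_id {bad.tolist()}")
    for pos in ("duration_days", "pupal_weight_mg"):
        vals = df[pos]
        bad = df.loc[vals.notna() & (vals <= 0), "run_id"]
        if len(bad):
            raise ValueError(f"{pos} must be positive; bad run_id {bad.tolist()}")
    return df


def write_run_table(runs: pd.DataFrame, path) -> None:
    """Write a run table to CSV in the documented schema."""
    runs[RUN_TABLE_COLUMNS].to_csv(path, index=False)


@dataclasses.dataclass
class PipelineConfig:
    """Everything the end-to-end analysis needs besides the run table."""

    space: MixtureSpace = dataclasses.field(default_factory=MixtureSpace)
    responses: tuple[str, ...] = tuple(RESPONSE_COLUMNS)
    transforms: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    directions: dict = dataclasses.field(
        default_factory=lambda: dict(opt_mod.RESPONSE_DIRECTIONS)
    )
    alpha: float = 0.05
    thresholds: FlagThresholds = dataclasses.field(default_factory=FlagThresholds)
    max_exclusions: int = 1
    cost: cost_mod.CostSpec | None = None
    grid_step: float = 0.01
    seed: int = 0
    criteria_overrides: dict = dataclasses.field(default_factory=dict)


def load_config(path) -> PipelineConfig:
    """Parse a YAML pipeline config; absent keys keep the study defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw = {}
    if "space" in raw:
        s = raw["space"]
        kw["space"] = MixtureSpace(
            component_names=tuple(s.get("component_names", MixtureSpace().component_names)),
            lower_bounds=tuple(s["lower_bounds"]),
            upper_bounds=tuple(s["upper_bounds"]),
            mixture_total=float(s["mixture_total"]),
        )
    for key in ("responses",):
        if key in raw:
            kw[key] = tuple(raw[key])
    for key in ("transforms", "directions", "criteria_overrides"):
        if key in raw:
            kw[key] = dict(raw[key])
    for key, cast in (("alpha", float), ("max_exclusions", int),
                      ("grid_step", float), ("seed", int)):
        if key in raw:
            kw[key] = cast(raw[key])
    if "thresholds" in raw:
        kw["thresholds"] = FlagThresholds(**raw["thresholds"])
    if "cost" in raw:
        c = raw["cost"]
        if "unit_prices" in c:
            kw["cost"] = cost_mod.CostSpec(
                unit_prices=tuple(c["unit_prices"]),
                annual_tonnage=float(c.get("annual_tonnage", 1730.29)),
                reference_blend=tuple(c.get("reference_blend", (6.0, 5.3, 19.0))),
            )
        elif "anchors" in c:
            a = c["anchors"]
            anchors = cost_mod.CostAnchors(**a)
            kw["cost"] = cost_mod.CostSpec(
                unit_prices=tuple(cost_mod.solve_unit_prices(anchors)),
                annual_tonnage=anchors.annual_tonnage,
                reference_blend=tuple(anchors.reference_blend),
            )
    cfg = PipelineConfig(**kw)
    unknown_resp = set(cfg.responses) - set(RESPONSE_COLUMNS)
    if unknown_resp:
        raise ValueError(f"unknown responses in config: {sorted(unknown_resp)}")
    return cfg


def run_pipeline(config: PipelineConfig, runs: pd.DataFrame) -> dict:
    """Full analysis: selection, diagnostics/exclusion, reduction, optimization.

    For every configured response the model ladder is walked (Type I
    sequential F tests), the chosen parent model screened for outlying and
    influential runs (at most ``max_exclusions`` dropped), and the surviving
    fit backward-eliminated.  Acceptance criteria are then derived from the
    reference blend's prediction CIs, the savings and response surfaces are
    evaluated on a lattice, and the operability region extracted.

    Returns a JSON-serializable bundle (plus ``_fits`` with the live model
    objects); deterministic given (config, data).
    """
    if runs.empty:
        raise ValueError("empty run table")
    bundle: dict = {"models": {}, "diagnostics": {}, "selection": {}}
    fits = {}
    for resp in config.responses:
        transform = config.transforms.get(resp, "none")
        log.info("response %s: sequential model selection", resp)
        sel = sequential_selection(
            runs, resp, config.space, transform, alpha=config.alpha
        )
        bundle["selection"][resp] = {
            "chosen": sel.chosen,
            "rationale": sel.rationale,
            "table": sel.table.replace({np.nan: None}).to_dict(orient="records"),
        }
        parent_ts = ladder_termset(sel.chosen)
        mf, excluded, trail = exclusion_workflow(
            runs, resp, parent_ts, config.space, transform,
            thresholds=config.thresholds, max_exclusions=config.max_exclusions,
        )
        reduced = backward_eliminate(mf, runs, alpha=config.alpha)
        fits[resp] = reduced
        bundle["models"][resp] = reduced.to_dict()
        bundle["diagnostics"][resp] = {
            "excluded_runs": excluded,
            "steps": trail.steps,
        }
        log.info(
            "response %s: %s, %d terms, excluded runs %s",
            resp, reduced.termset.label, len(reduced.termset), excluded,
        )

    costspec = config.cost or cost_mod.study_cost_spec()
    overrides = {
        r: opt_mod.Criterion(r, v["bound_type"], float(v["limit"]), source="user")
        for r, v in config.criteria_overrides.items()
    }
    criteria = opt_mod.criteria_from_reference(
        fits,
        reference_blend=costspec.reference_blend,
        directions=config.directions,
        overrides=overrides,
    )
    grid = opt_mod.evaluate_grid(fits, costspec, config.space, step=config.grid_step)
    region = opt_mod.operability_region(grid, criteria)
    bundle["criteria"] = {
        r: {"bound_type": c.bound_type, "limit": c.limit, "source": c.source}
        for r, c in criteria.items()
    }
    bundle["region"] = region.to_dict()
    if not region.empty:
        bundle["max_savings"] = opt_mod.max_savings_report(region, costspec)
    bundle["cost"] = {
        "unit_prices": list(costspec.unit_prices),
        "annual_tonnage": costspec.annual_tonnage,
        "reference_blend": list(costspec.reference_blend),
    }
    bundle["_fits"] = fits
    bundle["_region_obj"] = region
    return bundle


def _round_floats(obj, sig: int = 6):
    """Round floats to ``sig`` significant digits for stable JSON reports."""
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}") if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return _round_floats(obj.item(), sig)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_bundle(bundle: dict, outdir) -> None:
    """Serialize a pipeline bundle to JSON files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    public = {k: v for k, v in bundle.items() if not k.startswith("_")}
    with open(outdir / "report.json", "w") as fh:
        json.dump(_round_floats(public), fh, indent=2)
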