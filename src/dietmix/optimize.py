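"""Graphical multi-response optimization over the mixture design space.

The published workflow overlays the contour plots of every fitted response
surface, shades the sub-region where all acceptance criteria hold (the
*area of operability*) and reads off the blend with the largest cost
savings.  Here the overlay is formalized as an exhaustive lattice search:
blends are enumerated on a fine percentage-point grid, every surface is
evaluated at each blend, and the feasible set, its per-component bounding
ranges and the maximum-savings blend are extracted exactly.

Acceptance criteria default to the 95% confidence band of each response
predicted at the standard (reference) blend: responses to keep high
(pupation, pupal weight, adult emergence) must stay above the lower CI
endpoint, the response to keep low (larval duration) below the upper one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cost import CostSpec, blend_cost_per_ton
from .design import BLEND_COLUMNS, STUDY_SPACE, MixtureSpace

__all__ = [
    "Criterion",
    "CriteriaSet",
    "OperabilityResult",
    "RESPONSE_DIRECTIONS",
    "simplex_lattice",
    "criteria_from_reference",
    "evaluate_grid",
    "operability_region",
    "max_savings_report",
    "overlay_export",
]

#: optimization direction per response: benefits are kept high, larval
#: duration is kept low.
RESPONSE_DIRECTIONS = {
    "pupation": "maximize",
    "duration_days": "minimize",
    "pupal_weight_mg": "maximize",
    "emergence": "maximize",
}


@dataclass(frozen=True)
class Criterion:
    """One acceptance bound on a response, on the original response scale."""

    response: str
    bound_type: str  # "minimum" (response must be >= limit) or "maximum"
    limit: float
    source: str = "reference-CI"

    def __post_init__(self):
        if self.bound_type not in ("minimum", "maximum"):
            raise ValueError("bound_type must be 'minimum' or 'maximum'")
        if not np.isfinite(self.limit):
            raise ValueError("criterion limit must be finite")

    def satisfied(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, float)
        return v >= self.limit if self.bound_type == "minimum" else v <= self.limit


CriteriaSet = dict[str, Criterion]


def criteria_from_reference(
    fits: dict[str, object],
    reference_blend=None,
    confidence: float = 0.95,
    directions: dict[str, str] | None = None,
    overrides: dict[str, Criterion] | None = None,
) -> CriteriaSet:
    """Build acceptance criteria from prediction CIs at the reference blend.

    ``fits`` maps response name to a fitted model exposing
    ``predict(blends, ci=True, confidence=...)``.  For maximize-type
    responses the limit is the lower CI endpoint of the prediction at the
    reference blend, for minimize-type the upper endpoint; transformed
    responses are compared on the original (back-transformed) scale.
    ``overrides`` replace individual criteria (e.g. a stated limit).
    """
    directions = directions or RESPONSE_DIRECTIONS
    reference_blend = (
        np.asarray(reference_blend, float)
        if reference_blend is not None
        else np.array([6.0, 5.3, 19.0])
    )
    crit: CriteriaSet = {}
    for resp, mf in fits.items():
        if overrides and resp in overrides:
            continue
        _, lo, hi = mf.predict([reference_blend], ci=True, confidence=confidence)
        if directions.get(resp, "maximize") == "maximize":
            crit[resp] = Criterion(resp, "minimum", float(lo[0]))
        else:
            crit[resp] = Criterion(resp, "maximum", float(hi[0]))
    if overrides:
        for resp, c in overrides.items():
            crit[resp] = c
    return crit


def simplex_lattice(space: MixtureSpace, step: float) -> np.ndarray:
    """All blends on the percentage-point lattice inside the design space.

    The first two components run over their bounds in increments of ``step``;
    the third is the mixture total minus the other two and must respect its
    own bounds.  Coordinates are rounded to the lattice to avoid float drift.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    lo = np.asarray(space.lower_bounds)
    hi = np.asarray(space.upper_bounds)
    decimals = max(0, int(np.ceil(-np.log10(step))) + 2)
    a = np.round(np.arange(lo[0], hi[0] + step / 2, step), decimals)
    b = np.round(np.arange(lo[1], hi[1] + step / 2, step), decimals)
    A, B = np.meshgrid(a, b, indexing="ij")
    C = np.round(space.mixture_total - A - B, decimals)
    ok = (C >= lo[2] - 1e-9) & (C <= hi[2] + 1e-9)
    return np.column_stack([A[ok], B[ok], C[ok]])


def evaluate_grid(
    fits: dict[str, object],
    costspec: CostSpec,
    space: MixtureSpace = STUDY_SPACE,
    step: float = 0.01,
) -> pd.DataFrame:
    """Annotate every lattice blend with model predictions and savings.

    ``fits`` values need a ``predict(blends)`` returning original-scale
    values (both :class:`~dietmix.scheffe.ModelFit` and
    :class:`~dietmix.scheffe.CoefficientSurface` qualify).
    """
    blends = simplex_lattice(space, step)
    out = pd.DataFrame(blends, columns=BLEND_COLUMNS)
    for resp, mf in fits.items():
        out[resp] = np.asarray(mf.predict(blends), float)
    cost = 10.0 * blends @ np.asarray(costspec.unit_prices)
    c_ref = blend_cost_per_ton(costspec.reference_blend, costspec, space)
    out["cost_per_ton"] = cost
    out["savings_percent"] = 100.0 * (c_ref - cost) / c_ref
    out["savings_annual"] = (c_ref - cost) * costspec.annual_tonnage
    return out


@dataclass
class OperabilityResult:
    """Feasible sub-region of the design space under all criteria."""

    grid_step: float
    criteria: CriteriaSet
    feasible: pd.DataFrame
    component_ranges: dict[str, tuple[float, float]]
    argmax_blend: tuple[float, float, float] | None
    max_savings_percent: float | None
    max_savings_annual: float | None
    binding_constraints: dict[str, bool] = field(default_factory=dict)
    most_restrictive: str | None = None
    empty: bool = False
    n_grid: int = 0

    def to_dict(self) -> dict:
        return {
            "grid_step": self.grid_step,
            "criteria": {
                r: {"bound_type": c.bound_type, "limit": c.limit, "source": c.source}
                for r, c in self.criteria.items()
            },
            "empty": self.empty,
            "n_feasible": len(self.feasible),
            "n_grid": self.n_grid,
            "component_ranges": self.component_ranges,
            "argmax_blend": self.argmax_blend,
            "max_savings_percent": self.max_savings_percent,
            "max_savings_annual": self.max_savings_annual,
            "binding_constraints": self.binding_constraints,
            "most_restrictive": self.most_restrictive,
        }


def operability_region(grid: pd.DataFrame, criteria: CriteriaSet) -> OperabilityResult:
    """Extract the area of operability and its maximum-savings blend.

    Component ranges are reported rounded half-up to two decimals.  The
    savings argmax is tie-broken deterministically (lowest yeast, then
    highest corn flour).  A criterion is *binding* when relaxing it alone
    would enlarge the feasible set.
    """
    masks = {r: c.satisfied(grid[r].to_numpy()) for r, c in criteria.items()}
    combined = np.logical_and.reduce(list(masks.values())) if masks else np.ones(len(grid), bool)
    step = _infer_step(grid)
    feas = grid.loc[combined].reset_index(drop=True)
    if feas.empty:
        return OperabilityResult(
            grid_step=step, criteria=criteria, feasible=feas,
            component_ranges={}, argmax_blend=None, max_savings_percent=None,
            max_savings_annual=None, empty=True, n_grid=len(grid),
        )
    ranges = {
        col: (
            float(np.floor(feas[col].min() * 100 + 0.5) / 100),
            float(np.floor(feas[col].max() * 100 + 0.5) / 100),
        )
        for col in BLEND_COLUMNS
    }
    sav = feas["savings_percent"].to_numpy()
    best = sav.max()
    tied = feas.loc[np.isclose(sav, best, rtol=0, atol=1e-12)]
    tied = tied.sort_values(["yeast_pct", "cornflour_pct"], ascending=[True, False])
    row = tied.iloc[0]
    def _without(r):
        others = [m for q, m in masks.items() if q != r]
        return np.logical_and.reduce(others) if others else np.ones(len(grid), bool)

    binding = {r: bool(_without(r).sum() > len(feas)) for r in masks}
    areas = {r: int(m.sum()) for r, m in masks.items()}
    most = min(areas, key=areas.get) if areas else None
    return OperabilityResult(
        grid_step=step,
        criteria=criteria,
        feasible=feas,
        component_ranges=ranges,
        argmax_blend=(float(row["yeast_pct"]), float(row["cornflour_pct"]), float(row["corncob_pct"])),
        max_savings_percent=float(row["savings_percent"]),
        max_savings_annual=float(row["savings_annual"]),
        binding_constraints=binding,
        most_restrictive=most,
        n_grid=len(grid),
    )


def _infer_step(grid: pd.DataFrame) -> float:
    a = np.unique(grid["yeast_pct"].to_numpy())
    return float(np.min(np.diff(a))) if len(a) > 1 else 0.0


def max_savings_report(result: OperabilityResult, costspec: CostSpec) -> dict:
    """Savings summary at the maximum-savings feasible blend."""
    if result.empty:
        raise ValueError("operability region is empty; no savings to report")
    blend = result.argmax_blend
    row = result.feasible.loc[
        (result.feasible["yeast_pct"] == blend[0])
        & (result.feasible["cornflour_pct"] == blend[1])
    ].iloc[0]
    preds = {
        r: float(row[r]) for r in result.criteria if r in result.feasible.columns
    }
    return {
        "blend": blend,
        "savings_percent": result.max_savings_percent,
        "savings_annual": result.max_savings_annual,
        "savings_per_ton": result.max_savings_annual / costspec.annual_tonnage,
        "predicted_responses": preds,
    }


def overlay_export(
    grid: pd.DataFrame, criteria: CriteriaSet, result: OperabilityResult
) -> dict:
    """Per-response feasibility masks and the combined overlay, for plotting."""
    masks = {r: c.satisfied(grid[r].to_numpy()) for r, c in criteria.items()}
    combined = np.logical_and.reduce(list(masks.values())) if masks else np.ones(len(grid), bool)
    return {
        "blends": grid[BLEND_COLUMNS].to_numpy(),
        "masks": masks,
        "combined": combined,
        "mask_areas": {r: int(m.sum()) for r, m in masks.items()},
        "argmax_blend": result.argmax_blend,
    }


def plot_overlay(grid, criteria, result, path):
    """Render the overlay as a 2-simplex scatter (optional convenience)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ov = overlay_export(grid, criteria, result)
    b = ov["blends"]
    # project onto the 2-simplex: x = zB + zC/2, y = zC * sqrt(3)/2
    from .design import to_pseudo

    z = to_pseudo(b)
    x = z[:, 1] + z[:, 2] / 2
    y = z[:, 2] * np.sqrt(3) / 2
    fig, ax = plt.subplots(figsize=(6, 5.5))
    ax.scatter(x, y, c="lightgray", s=2, label="infeasible")
    m = ov["combined"]
    ax.scatter(x[m], y[m], c="gold", s=2, label="area of operability")
    if result.argmax_blend is not None:
        za = to_pseudo(np.asarray(result.argmax_blend))
        ax.plot(za[1] + za[2] / 2, za[2] * np.sqrt(3) / 2, "k*", ms=12,
                label="max savings")
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title("Overlay of response criteria on the mixture simplex")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
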