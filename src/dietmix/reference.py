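"""Packaged reference analysis: published fitted surfaces and cost anchors.

The package ships the reference study's fitted Scheffé coefficients (on the
pseudo-component scale, original response units), its cost anchors and its
stated acceptance limits, so the full graphical-optimization stage can be
reproduced without the raw run-level data.  Coefficients for adult emergence
were published back-transformed to the proportion scale; the packaged
surface therefore lives on that scale directly (see docs/methods.md for why
this is a reporting approximation that does not affect the optimization).
"""

from __future__ import annotations

import numpy as np

from .cost import STUDY_ANCHORS, CostSpec, study_cost_spec
from .design import STUDY_SPACE
from .optimize import (
    Criterion,
    evaluate_grid,
    max_savings_report,
    operability_region,
    overlay_export,
)
from .scheffe import CoefficientSurface, ScheffeTerm, TermSet, ladder_termset

__all__ = [
    "REFERENCE_COEFFICIENTS",
    "REFERENCE_CI",
    "REFERENCE_CRITERIA",
    "reference_surfaces",
    "reference_criteria",
    "reference_analysis",
]


def _term(name: str) -> ScheffeTerm:
    """Look up a term by name across the ladder orders."""
    for label in ("quartic", "special_quartic", "cubic", "special_cubic", "quadratic"):
        for t in ladder_termset(label):
            if t.name == name:
                return t
    raise KeyError(name)


def _termset(label: str, names: list[str]) -> TermSet:
    return TermSet(label, tuple(_term(n) for n in names))


#: published model coefficients per response (pseudo scale, original units;
#: emergence on the back-transformed proportion scale).
REFERENCE_COEFFICIENTS = {
    "pupation": {
        "model": "linear",
        "transform": "none",
        "terms": {"A": 0.83, "B": 0.70, "C": 0.42},
    },
    "duration_days": {
        "model": "reduced:special_quartic",
        "transform": "none",
        "terms": {
            "A": 9.10, "B": 10.81, "C": 11.30,
            "A*B": -0.32, "A*C": -0.92, "B*C": -0.70,
            "A^2*B*C": 59.32, "A*B^2*C": -52.62,
        },
    },
    "pupal_weight_mg": {
        "model": "reduced:quadratic",
        "transform": "none",
        "terms": {"A": 17.98, "B": 17.59, "C": 15.64, "A*C": 3.94, "B*C": -8.44},
    },
    "emergence": {
        "model": "reduced:quadratic",
        "transform": "none",  # published values already back-transformed
        "terms": {"A": 0.90, "B": 0.83, "C": 0.99, "B*C": -0.81},
    },
}

#: published 95% CIs for the linear (vertex) coefficients, original units.
REFERENCE_CI = {
    "pupation": {"A": (0.70, 0.96), "B": (0.57, 0.84), "C": (0.29, 0.55)},
    "duration_days": {"A": (8.47, 9.46), "B": (10.45, 11.17), "C": (10.93, 11.66)},
    "pupal_weight_mg": {"A": (16.39, 19.56), "B": (15.84, 19.35), "C": (13.89, 17.39)},
    "emergence": {"A": (0.0, 0.97), "B": (0.69, 0.93), "C": (0.96, 0.98)},
}

#: acceptance limits of the reference optimization.  Pupation, weight and
#: duration limits are the relevant 95% CI endpoints of term A (the standard
#: blend's vertex); the emergence limit 0.8 is the study's stated value (its
#: printed back-transformed CI for term A is degenerate and cannot supply it).
REFERENCE_CRITERIA = {
    "pupation": Criterion("pupation", "minimum", 0.70, source="reference-CI"),
    "duration_days": Criterion("duration_days", "maximum", 9.46, source="reference-CI"),
    "pupal_weight_mg": Criterion("pupal_weight_mg", "minimum", 16.39, source="reference-CI"),
    "emergence": Criterion("emergence", "minimum", 0.80, source="stated"),
}


def reference_surfaces() -> dict[str, CoefficientSurface]:
    """The four published response surfaces as coefficient-only models."""
    out = {}
    for resp, spec in REFERENCE_COEFFICIENTS.items():
        names = list(spec["terms"])
        out[resp] = CoefficientSurface(
            response=resp,
            termset=_termset(spec["model"], names),
            coef=tuple(spec["terms"][n] for n in names),
            transform=spec["transform"],
            space=STUDY_SPACE,
        )
    return out


def reference_criteria() -> dict[str, Criterion]:
    return dict(REFERENCE_CRITERIA)


def reference_analysis(step: float = 0.01, costspec: CostSpec | None = None) -> dict:
    """Reproduce the cost-optimization stage from packaged constants.

    Builds the four surfaces, derives unit prices from the cost anchors,
    grid-searches the design space at ``step`` percentage points and returns
    the operability region, the maximum-savings blend and the criteria used.
    """
    spec = costspec or study_cost_spec()
    fits = reference_surfaces()
    criteria = reference_criteria()
    grid = evaluate_grid(fits, spec, STUDY_SPACE, step=step)
    region = operability_region(grid, criteria)
    report = {
        "unit_prices": list(np.round(spec.unit_prices, 6)),
        "annual_tonnage": spec.annual_tonnage,
        "criteria": {r: {"bound_type": c.bound_type, "limit": c.limit, "source": c.source}
                     for r, c in criteria.items()},
        "region": region.to_dict(),
    }
    if not region.empty:
        report["max_savings"] = max_savings_report(region, spec)
    report["_region_obj"] = region
    report["_grid"] = grid
    return report
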