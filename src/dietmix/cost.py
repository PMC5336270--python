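"""Linear ingredient-cost model for diet blends.

Only the three variable mixture components are costed; the fixed 69.7% of
the diet is identical across blends and cancels in every savings figure.
For a blend x in percent of the whole diet and prices p in $/kg,

    cost per ton of finished diet = 1000 kg * sum_i (x_i / 100) * p_i.

Cost is therefore affine in the blend, and exactly linear on the pseudo
simplex.  When per-kg prices are not known they can be recovered from three
published cost anchors (annual cost of two vertex blends plus the savings
percentage of the third), which form a full-rank 3x3 linear system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import STUDY_SPACE, MixtureSpace, validate_blend

__all__ = [
    "CostSpec",
    "CostAnchors",
    "STUDY_ANCHORS",
    "blend_cost_per_ton",
    "savings_vs_reference",
    "solve_unit_prices",
    "cost_surface",
    "study_cost_spec",
]


@dataclass(frozen=True)
class CostSpec:
    """Per-kg component prices, annual diet tonnage and the reference blend."""

    unit_prices: tuple[float, float, float]  # $/kg for yeast, corn flour, corncob
    annual_tonnage: float = 1730.29
    reference_blend: tuple[float, float, float] = (6.0, 5.3, 19.0)
    currency_label: str = "USD"

    def __post_init__(self):
        if any(p < 0 for p in self.unit_prices):
            raise ValueError("unit prices must be non-negative")
        if self.annual_tonnage <= 0:
            raise ValueError("annual tonnage must be positive")


@dataclass(frozen=True)
class CostAnchors:
    """Published cost figures sufficient to recover the unit prices.

    Two blends with known annual ingredient cost plus one blend with a known
    savings percentage relative to the first (reference) blend.
    """

    reference_blend: tuple[float, float, float]
    reference_annual_cost: float
    alt_blend: tuple[float, float, float]
    alt_annual_cost: float
    third_blend: tuple[float, float, float]
    third_savings_percent: float
    annual_tonnage: float = 1730.29


#: printed anchors of the mass-rearing study
STUDY_ANCHORS = CostAnchors(
    reference_blend=(6.0, 5.3, 19.0),
    reference_annual_cost=791_716.0,
    alt_blend=(3.0, 8.3, 19.0),
    alt_annual_cost=596_525.0,
    third_blend=(3.0, 5.3, 22.0),
    third_savings_percent=21.29,
)


def blend_cost_per_ton(blend, spec: CostSpec, space: MixtureSpace = STUDY_SPACE) -> float:
    """Ingredient cost (currency per ton of finished diet) of a blend."""
    x = validate_blend(blend, space)
    return float(10.0 * x @ np.asarray(spec.unit_prices))  # 1000 kg * x/100


def savings_vs_reference(blend, spec: CostSpec, space: MixtureSpace = STUDY_SPACE) -> dict:
    """Percent and annual-currency savings of a blend vs the reference blend."""
    c_ref = blend_cost_per_ton(spec.reference_blend, spec, space)
    if c_ref == 0:
        raise ZeroDivisionError("reference blend has zero cost")
    c = blend_cost_per_ton(blend, spec, space)
    return {
        "savings_percent": 100.0 * (c_ref - c) / c_ref,
        "savings_annual": (c_ref - c) * spec.annual_tonnage,
        "savings_per_ton": c_ref - c,
    }


def solve_unit_prices(
    anchors: CostAnchors = STUDY_ANCHORS, space: MixtureSpace = STUDY_SPACE
) -> np.ndarray:
    """Recover per-kg unit prices from three cost anchors.

    Raises ``numpy.linalg.LinAlgError`` when the anchor blends are affinely
    dependent (singular system).  The returned prices reproduce all three
    anchors to numerical precision.
    """
    T = anchors.annual_tonnage
    c_ref = anchors.reference_annual_cost / T
    c_alt = anchors.alt_annual_cost / T
    c_third = c_ref * (1.0 - anchors.third_savings_percent / 100.0)
    X = 10.0 * np.array(
        [anchors.reference_blend, anchors.alt_blend, anchors.third_blend], float
    )
    b = np.array([c_ref, c_alt, c_third])
    if np.linalg.matrix_rank(X) < 3:
        raise np.linalg.LinAlgError("anchor blends are collinear; prices not identifiable")
    prices = np.linalg.solve(X, b)
    resid = X @ prices - b
    if np.max(np.abs(resid)) > 1e-9 * max(1.0, np.max(np.abs(b))):
        raise np.linalg.LinAlgError("anchor system inconsistent")
    return prices


def study_cost_spec() -> CostSpec:
    """Cost specification with prices recovered from the printed anchors."""
    return CostSpec(
        unit_prices=tuple(solve_unit_prices(STUDY_ANCHORS)),
        annual_tonnage=STUDY_ANCHORS.annual_tonnage,
        reference_blend=STUDY_ANCHORS.reference_blend,
    )


def cost_surface(
    spec: CostSpec,
    space: MixtureSpace = STUDY_SPACE,
    resolution: float = 0.1,
) -> pd.DataFrame:
    """Cost and savings on a regular lattice over the design space.

    ``resolution`` is the lattice step in percentage points of the first two
    components; the third is implied by the mixture total.
    """
    from .optimize import simplex_lattice

    blends = simplex_lattice(space, resolution)
    prices = np.asarray(spec.unit_prices)
    cost = 10.0 * blends @ prices
    c_ref = blend_cost_per_ton(spec.reference_blend, spec, space)
    sav_pct = 100.0 * (c_ref - cost) / c_ref
    out = pd.DataFrame(blends, columns=["yeast_pct", "cornflour_pct", "corncob_pct"])
    out["cost_per_ton"] = cost
    out["savings_pct"] = sav_pct
    out["savings_annual"] = (c_ref - cost) * spec.annual_tonnage
    return out
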