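"""Constrained three-component mixture design space.

The diet experiment varies three ingredients — brewer's/torula yeast (A),
corn flour (B) and corncob fractions (C) — inside a fixed share of the whole
diet.  All proportions in this package are **percent of the whole diet**
(e.g. the standard blend is 6.0 / 5.3 / 19.0, summing to the mixture total
30.3); the remaining 69.7% of the diet (sugar, preservatives, gum, water) is
held constant and never enters the model.

Because each component has a lower bound, the constrained region is mapped
onto the unit simplex with L-pseudocomponent coding

    z_i = (x_i - L_i) / (T - sum(L)),

under which the three extreme ("corner") blends become the unit vectors and
Scheffé linear coefficients equal the predicted responses at those corners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MixtureSpace",
    "BlendError",
    "STUDY_SPACE",
    "TESTED_BLENDS",
    "DEFAULT_REPLICATE_PLAN",
    "validate_blend",
    "to_pseudo",
    "from_pseudo",
    "blend_key",
    "reference_design",
    "leverage_profile",
]

SUM_TOL = 1e-9
#: decimals used when grouping replicate runs by blend (guards CSV float drift)
BLEND_KEY_DECIMALS = 4


class BlendError(ValueError):
    """A blend violates the mixture-sum or a component bound."""


@dataclass(frozen=True)
class MixtureSpace:
    """Bounded simplex slice occupied by the variable mixture components.

    Bounds and ``mixture_total`` are percent of the whole diet.  The
    ``non_mixture_fraction`` is purely descriptive (the fixed 69.7%).
    """

    component_names: tuple[str, ...] = ("yeast", "corn flour", "corncob fractions")
    lower_bounds: tuple[float, ...] = (3.0, 5.3, 19.0)
    upper_bounds: tuple[float, ...] = (6.0, 8.3, 22.0)
    mixture_total: float = 30.3
    non_mixture_fraction: dict = field(
        default_factory=lambda: {
            "sugar": 8.2,
            "sodium benzoate": 0.4,
            "methylparaben": 0.1,
            "citric acid": 0.44,
            "guar gum": 0.1,
            "water": 60.46,
        }
    )

    def __post_init__(self):
        lo = np.asarray(self.lower_bounds, float)
        hi = np.asarray(self.upper_bounds, float)
        if len(lo) != len(hi) or len(lo) != len(self.component_names):
            raise ValueError("bounds and component names must have equal length")
        if np.any(lo <= 0) or np.any(hi <= 0):
            raise ValueError("all bounds must be positive")
        if not (lo.sum() < self.mixture_total < hi.sum()):
            raise ValueError("mixture_total must lie strictly between the bound sums")
        if np.any(hi - lo > self.mixture_total - lo.sum() + SUM_TOL):
            raise ValueError("a component range exceeds the available mixture room")

    @property
    def n_components(self) -> int:
        return len(self.component_names)

    @property
    def range_total(self) -> float:
        """Width of the pseudo simplex in percent units, T - sum(L)."""
        return self.mixture_total - float(np.sum(self.lower_bounds))

    @property
    def corners(self) -> np.ndarray:
        """Extreme blends (one per component) in percent units, rows = corners."""
        return from_pseudo(np.eye(self.n_components), self)


#: design space of the mass-rearing diet study
STUDY_SPACE = MixtureSpace()

#: the 19 tested blends (percent of diet), mixture numbers 1..19; no. 1 is the
#: standard mass-rearing formulation.
TESTED_BLENDS: dict[int, tuple[float, float, float]] = {
    1: (6.0, 5.3, 19.0),
    2: (5.0, 5.3, 20.0),
    3: (5.0, 5.8, 19.5),
    4: (5.0, 6.3, 19.0),
    5: (4.5, 5.3, 20.5),
    6: (4.5, 6.8, 19.0),
    7: (4.3, 5.7, 20.3),
    8: (4.3, 6.5, 19.5),
    9: (4.0, 5.3, 21.0),
    10: (4.0, 6.3, 20.0),
    11: (4.0, 7.3, 19.0),
    12: (3.5, 5.8, 21.0),
    13: (3.5, 6.5, 20.3),
    14: (3.5, 7.3, 19.5),
    15: (3.0, 5.3, 22.0),
    16: (3.0, 6.3, 21.0),
    17: (3.0, 6.8, 20.5),
    18: (3.0, 7.3, 20.0),
    19: (3.0, 8.3, 19.0),
}

# 40 runs: the three vertices four-fold, four interior singletons, the rest
# duplicated -> 19 distinct blends and 40 - 19 = 21 pure-error df.
DEFAULT_REPLICATE_PLAN: dict[int, int] = {
    m: (4 if m in (1, 15, 19) else 1 if m in (7, 8, 12, 13) else 2)
    for m in TESTED_BLENDS
}


def validate_blend(blend, space: MixtureSpace = STUDY_SPACE, *, atol: float = SUM_TOL):
    """Check a blend (percent units) against the mixture-sum and bounds.

    Returns the blend as an ndarray, or raises :class:`BlendError` naming the
    violated constraint.
    """
    x = np.asarray(blend, dtype=float)
    if x.shape != (space.n_components,):
        raise BlendError(
            f"blend has {x.size} proportions, space has {space.n_components} components"
        )
    total = float(x.sum())
    if abs(total - space.mixture_total) > max(atol, 1e-9 * space.mixture_total):
        raise BlendError(
            f"blend proportions sum to {total:g}, not the mixture total "
            f"{space.mixture_total:g}"
        )
    lo = np.asarray(space.lower_bounds)
    hi = np.asarray(space.upper_bounds)
    bad = np.nonzero((x < lo - 1e-9) | (x > hi + 1e-9))[0]
    if bad.size:
        i = int(bad[0])
        raise BlendError(
            f"component '{space.component_names[i]}' = {x[i]:g}% outside "
            f"[{lo[i]:g}, {hi[i]:g}]"
        )
    return x


def to_pseudo(blend, space: MixtureSpace = STUDY_SPACE) -> np.ndarray:
    """Map blend(s) in percent units to L-pseudocomponent simplex coordinates.

    Accepts a single blend or an (n, q) array of blends; rows are not
    re-validated here.
    """
    x = np.asarray(blend, dtype=float)
    lo = np.asarray(space.lower_bounds)
    return (x - lo) / space.range_total


def from_pseudo(z, space: MixtureSpace = STUDY_SPACE) -> np.ndarray:
    """Inverse of :func:`to_pseudo`; raises on points off the simplex."""
    z = np.asarray(z, dtype=float)
    sums = z.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise BlendError("pseudo coordinates must sum to 1")
    if np.any(z < -1e-12):
        raise BlendError("pseudo coordinates must be non-negative")
    return np.asarray(space.lower_bounds) + z * space.range_total


def blend_key(blend) -> tuple:
    """Canonical replicate-grouping key: proportions rounded to 4 decimals."""
    return tuple(np.round(np.asarray(blend, float), BLEND_KEY_DECIMALS))


RUN_TABLE_COLUMNS = [
    "run_id",
    "mixture_no",
    "yeast_pct",
    "cornflour_pct",
    "corncob_pct",
    "n_larvae",
    "pupation",
    "duration_days",
    "pupal_weight_mg",
    "emergence",
    "excluded_responses",
]

BLEND_COLUMNS = ["yeast_pct", "cornflour_pct", "corncob_pct"]
RESPONSE_COLUMNS = ["pupation", "duration_days", "pupal_weight_mg", "emergence"]


def reference_design(
    replicate_plan: dict[int, int] | None = None,
    *,
    n_larvae: int = 25,
    seed: int | None = None,
    space: MixtureSpace = STUDY_SPACE,
) -> pd.DataFrame:
    """Build the study's run table (responses empty) from a replicate plan.

    ``replicate_plan`` maps mixture number (1-19) to a replicate count >= 1;
    the default plan yields the study's 40 runs.  Run order is randomized
    when ``seed`` is given, otherwise kept in mixture order.
    """
    plan = dict(DEFAULT_REPLICATE_PLAN if replicate_plan is None else replicate_plan)
    unknown = set(plan) - set(TESTED_BLENDS)
    if unknown:
        raise KeyError(f"unknown mixture number(s): {sorted(unknown)}")
    if any(c < 1 for c in plan.values()):
        raise ValueError("replicate counts must be >= 1")
    rows = []
    for m in sorted(plan):
        blend = validate_blend(TESTED_BLENDS[m], space)
        for _ in range(plan[m]):
            rows.append((m, *blend))
    df = pd.DataFrame(rows, columns=["mixture_no", *BLEND_COLUMNS])
    if seed is not None:
        rng = np.random.default_rng(seed)
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "run_id", np.arange(1, len(df) + 1))
    df["n_larvae"] = n_larvae
    for col in RESPONSE_COLUMNS:
        df[col] = np.nan
    df["excluded_responses"] = ""
    return df


def design_points(runs: pd.DataFrame) -> np.ndarray:
    """Blend matrix (percent units) of a run table, shape (n_runs, 3)."""
    return runs[BLEND_COLUMNS].to_numpy(float)


def leverage_profile(runs: pd.DataFrame, termset, space: MixtureSpace = STUDY_SPACE) -> np.ndarray:
    """Diagonal of the hat matrix H = X (X'X)^-1 X' for a term set.

    Raises ``numpy.linalg.LinAlgError`` when the term set is aliased
    (rank-deficient) on this design.
    """
    from .scheffe import design_matrix  # local import avoids a cycle

    X = design_matrix(runs, termset, space)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"term set '{termset.label}' is aliased on this design "
            f"(rank {np.linalg.matrix_rank(X)} < {X.shape[1]} terms)"
        )
    Q, _ = np.linalg.qr(X)
    return np.einsum("ij,ij->i", Q, Q)
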