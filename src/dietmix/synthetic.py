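"""Seedable synthetic run tables with the experiment's statistical structure.

The generator emulates the layout of the real experiment: 40 runs over 19
distinct blends, cohorts of 25 larvae per dish.  Responses are drawn from
configurable "truth" Scheffé surfaces (defaults: the packaged reference
coefficients) with noise models chosen for the biology of each response:

* pupation   — Binomial(n_larvae, p(z)) / n_larvae
* emergence  — Binomial(n_pupae, q(z)) / n_pupae, n_pupae the simulated
  pupal count (emergence is defined per recovered pupa)
* duration   — surface + Normal(0, 0.45 d)
* pupal wt   — surface + Normal(0, 1.6 mg)

With ``noise=False`` responses equal the truth surfaces exactly, which makes
noise-free fits recover the coefficients to machine precision — the basis of
several oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import RESPONSE_COLUMNS, STUDY_SPACE, MixtureSpace
from .scheffe import CoefficientSurface, design_matrix, fit

__all__ = ["TruthModel", "default_truth", "simulate_runs", "recovery_experiment", "contaminate"]

#: default residual scales, chosen so simulated fits show the moderate
#: signal-to-noise (R² roughly 0.3-0.8) typical of dish-level rearing data.
DEFAULT_NOISE = {"duration_days": 0.45, "pupal_weight_mg": 1.6}

#: proportion surfaces are clamped here before binomial sampling
PROB_CLAMP = (0.001, 0.999)


@dataclass(frozen=True)
class TruthModel:
    """Generative surfaces and noise scales for every response."""

    surfaces: dict[str, CoefficientSurface]
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE))
    clamp: tuple[float, float] = PROB_CLAMP

    def __post_init__(self):
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ValueError("noise standard deviations must be positive")


def default_truth() -> TruthModel:
    """Truth model built from the packaged reference coefficients."""
    from .reference import reference_surfaces

    return TruthModel(surfaces=reference_surfaces())


def simulate_runs(
    design: pd.DataFrame,
    truth: TruthModel | None = None,
    seed: int | None = 0,
    noise: bool = True,
    space: MixtureSpace = STUDY_SPACE,
) -> pd.DataFrame:
    """Fill a design's response columns by sampling from the truth model.

    ``design`` is a run table (e.g. from
    :func:`~dietmix.design.reference_design`); blends must be valid.  The
    result is reproducible under ``seed``; with ``noise=False`` every
    response equals its truth surface exactly.
    """
    truth = truth or default_truth()
    rng = np.random.default_rng(seed)
    runs = design.copy()
    blends = runs[["yeast_pct", "cornflour_pct", "corncob_pct"]].to_numpy(float)
    n_larvae = runs["n_larvae"].to_numpy(int)

    mu = {r: np.asarray(s.predict(blends), float) for r, s in truth.surfaces.items()}
    for r in ("pupation", "emergence"):
        if r in mu:
            lo, hi = truth.clamp
            if np.any((mu[r] < 0) | (mu[r] > 1)):
                if np.any((mu[r] < lo - 0.5) | (mu[r] > hi + 0.5)):
                    raise ValueError(f"truth surface for {r} far outside [0, 1]")
            mu[r] = np.clip(mu[r], lo, hi)

    if not noise:
        for r in RESPONSE_COLUMNS:
            if r in mu:
                runs[r] = mu[r]
        return runs

    if "pupation" in mu:
        k_pup = rng.binomial(n_larvae, mu["pupation"])
        runs["pupation"] = k_pup / n_larvae
    else:
        k_pup = n_larvae.copy()
    if "duration_days" in mu:
        runs["duration_days"] = mu["duration_days"] + rng.normal(
            0.0, truth.noise_sd["duration_days"], len(runs)
        )
    if "pupal_weight_mg" in mu:
        runs["pupal_weight_mg"] = mu["pupal_weight_mg"] + rng.normal(
            0.0, truth.noise_sd["pupal_weight_mg"], len(runs)
        )
    if "emergence" in mu:
        n_pupae = np.maximum(k_pup, 1)
        runs["emergence"] = rng.binomial(n_pupae, mu["emergence"]) / n_pupae
    return runs


def recovery_experiment(
    truth: TruthModel,
    design: pd.DataFrame,
    response: str,
    termset,
    n_reps: int = 200,
    seed: int = 0,
    transform: str = "none",
    space: MixtureSpace = STUDY_SPACE,
) -> dict:
    """Monte-Carlo check that fitting recovers the truth coefficients.

    Simulates ``n_reps`` tables, fits ``termset`` to ``response`` each time
    and summarizes per-coefficient bias, RMSE and 95% CI coverage.  The truth
    surface must use exactly ``termset`` (otherwise coefficients are not
    comparable term by term).
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    surf = truth.surfaces[response]
    names = termset.names
    if surf.termset.names != names:
        raise ValueError("truth term set differs from the fitted term set")
    X = design_matrix(design, termset, space)
    if np.linalg.matrix_rank(X) < len(names):
        raise ValueError("term set aliased on this design; truth not identifiable")
    true_coef = np.asarray(surf.coef, float)

    rng = np.random.default_rng(seed)
    est = np.empty((n_reps, len(names)))
    cover = np.zeros((n_reps, len(names)), bool)
    for k in range(n_reps):
        runs = simulate_runs(design, truth, seed=int(rng.integers(2**31 - 1)), space=space)
        mf = fit(runs, response, termset, space, transform)
        est[k] = mf.coef
        cover[k] = (mf.ci[:, 0] <= true_coef) & (true_coef <= mf.ci[:, 1])
    bias = est.mean(axis=0) - true_coef
    se_bias = est.std(axis=0, ddof=1) / np.sqrt(n_reps)
    return {
        "terms": names,
        "true_coef": true_coef,
        "bias": bias,
        "bias_se": se_bias,
        "rmse": np.sqrt(np.mean((est - true_coef) ** 2, axis=0)),
        "coverage": cover.mean(axis=0),
        "n_reps": n_reps,
    }


def contaminate(runs: pd.DataFrame, run_id: int, response: str, shift: float) -> pd.DataFrame:
    """Return a copy with ``shift`` added to one response of one run.

    Used to exercise the outlier diagnostics with a known contamination.
    Raises if the run does not exist or the response is missing there.
    """
    if response not in RESPONSE_COLUMNS:
        raise KeyError(f"unknown response {response!r}")
    out = runs.copy()
    idx = out.index[out["run_id"] == run_id]
    if len(idx) == 0:
        raise KeyError(f"run_id {run_id} not found")
    val = out.loc[idx[0], response]
    if pd.isna(val):
        raise ValueError(f"run {run_id} has no recorded {response}")
    out.loc[idx[0], response] = val + shift
    return out
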