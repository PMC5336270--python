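"""Residual and influence diagnostics with an outlier-exclusion workflow.

All influence statistics are the standard closed-form leave-one-out
quantities of linear regression:

    r_i      internally studentized residual  e_i / (s sqrt(1 - h_ii))
    t_i      externally studentized ("outlier-t")
    D_i      Cook's distance  r_i² h_ii / (p (1 - h_ii))
    DFFITS_i t_i sqrt(h_ii / (1 - h_ii))
    DFBETAS  per-coefficient deleted change scaled by its deleted se

Every one of them equals what an explicit refit without run i would give;
the test suite verifies that identity.  Flag thresholds are conventional
(the workflow that produced the published fits does not state its own):
|t| > 3, D > 1, |DFFITS| > 2 sqrt(p/n), |DFBETAS| > 2/sqrt(n).  A run is an
exclusion candidate only when the outlier-t rule fires together with at
least one influence rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scheffe import ModelFit, TermSet, backward_eliminate, fit

__all__ = [
    "FlagThresholds",
    "DiagnosticsReport",
    "residual_diagnostics",
    "box_cox_profile",
    "exclusion_workflow",
]


@dataclass(frozen=True)
class FlagThresholds:
    outlier_t: float = 3.0
    cooks_d: float = 1.0
    dffits_factor: float = 2.0  # threshold 2 sqrt(p/n)
    dfbetas_factor: float = 2.0  # threshold 2 / sqrt(n)


@dataclass
class DiagnosticsReport:
    response: str
    stats: pd.DataFrame  # per-run: leverage, r_int, t_ext, cooks_d, dffits
    dfbetas: pd.DataFrame  # per-run x per-term
    flags: pd.DataFrame  # per-run boolean rule columns + candidate
    thresholds: FlagThresholds

    @property
    def candidates(self) -> list[int]:
        """Run ids flagged as outlier + influential, worst first."""
        c = self.flags.loc[self.flags["exclusion_candidate"]]
        order = self.stats.loc[c.index, "t_ext"].abs().sort_values(ascending=False)
        return [int(self.stats.loc[i, "run_id"]) for i in order.index]

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "stats": self.stats.to_dict(orient="list"),
            "dfbetas": self.dfbetas.to_dict(orient="list"),
            "flags": self.flags.to_dict(orient="list"),
        }


def residual_diagnostics(
    fit_: ModelFit, thresholds: FlagThresholds | None = None
) -> DiagnosticsReport:
    """Closed-form leave-one-out influence statistics for every run in a fit."""
    th = thresholds or FlagThresholds()
    if fit_.df_resid < 2:
        raise ValueError("influence diagnostics need at least 2 residual df")
    e = fit_.resid
    h = fit_.leverage
    n, p = fit_.n_obs, len(fit_.termset)
    s = fit_.sigma
    df = fit_.df_resid

    one_minus_h = np.clip(1.0 - h, 1e-12, None)
    # an exact interpolation (sigma at machine-precision zero) has no
    # meaningful studentization: report all statistics as zero
    if s <= 1e-10 * max(1.0, float(np.max(np.abs(fit_.y)))):
        s = 0.0
    if s == 0:
        r = np.zeros(n)
        t = np.zeros(n)
    else:
        r = e / (s * np.sqrt(one_minus_h))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((df - 1) / np.clip(df - r**2, 1e-12, None))
    cooks = r**2 * h / (p * one_minus_h)
    dffits = t * np.sqrt(h / one_minus_h)

    # DFBETAS via the rank-one downdate: b - b(i) = (X'X)^-1 x_i e_i/(1-h_ii)
    XtX_inv = np.linalg.pinv(fit_.X.T @ fit_.X)
    delta = (XtX_inv @ fit_.X.T) * (e / one_minus_h)  # (p, n)
    # deleted residual variance s(i)^2
    with np.errstate(invalid="ignore"):
        s_i2 = np.clip((df * s**2 - e**2 / one_minus_h) / (df - 1), 0, None)
    diag = np.sqrt(np.diag(XtX_inv))
    denom = np.sqrt(s_i2)[None, :] * diag[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        dfb = np.where(denom > 0, delta / denom, 0.0)

    run_ids = fit_.run_ids
    stats_df = pd.DataFrame(
        {
            "run_id": run_ids,
            "leverage": h,
            "r_int": r,
            "t_ext": t,
            "cooks_d": cooks,
            "dffits": dffits,
        }
    )
    dfb_df = pd.DataFrame(dfb.T, columns=fit_.termset.names)
    dfb_df.insert(0, "run_id", run_ids)

    flags = pd.DataFrame({"run_id": run_ids})
    flags["outlier_t"] = np.abs(t) > th.outlier_t
    flags["cooks_d"] = cooks > th.cooks_d
    flags["dffits"] = np.abs(dffits) > th.dffits_factor * np.sqrt(p / n)
    flags["dfbetas"] = (np.abs(dfb) > th.dfbetas_factor / np.sqrt(n)).any(axis=0)
    flags["exclusion_candidate"] = flags["outlier_t"] & (
        flags["cooks_d"] | flags["dffits"] | flags["dfbetas"]
    )
    return DiagnosticsReport(fit_.response, stats_df, dfb_df, flags, th)


# ---------------------------------------------------------------------------
# Box-Cox

def box_cox_profile(
    fit_: ModelFit,
    lambdas: np.ndarray | None = None,
    confidence: float = 0.95,
) -> dict:
    """Profile log-likelihood of the Box-Cox power family for a fitted model.

    The response is transformed as y(λ) = (y^λ - 1)/(λ ġ^{λ-1}) (ġ the
    geometric mean; λ=0 gives ġ log y), the model refitted at each grid λ and
    the profile log-likelihood -n/2 log(RSS(λ)/n) recorded.  The
    recommendation is *no transform* when λ=1 lies inside the 95% profile CI.
    """
    if fit_.transform != "none":
        raise ValueError("Box-Cox applies to untransformed responses only")
    y = fit_.y
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive responses")
    grid = np.arange(-3.0, 3.0001, 0.1) if lambdas is None else np.asarray(lambdas, float)
    X = fit_.X
    H_proj = X @ np.linalg.pinv(X.T @ X) @ X.T
    n = len(y)
    gmean = float(np.exp(np.mean(np.log(y))))
    loglik = np.empty(len(grid))
    for k, lam in enumerate(grid):
        if abs(lam) < 1e-12:
            yt = gmean * np.log(y)
        else:
            yt = (y**lam - 1.0) / (lam * gmean ** (lam - 1.0))
        resid = yt - H_proj @ yt
        rss = float(resid @ resid)
        loglik[k] = -0.5 * n * np.log(max(rss, 1e-300) / n)
    best_idx = int(np.argmax(loglik))
    best = float(grid[best_idx])
    if len(grid) == 1:
        ci = (best, best)
    else:
        cut = loglik[best_idx] - stats.chi2.ppf(confidence, 1) / 2
        inside = grid[loglik >= cut]
        ci = (float(inside.min()), float(inside.max()))
    return {
        "lambda_grid": grid,
        "loglik": loglik,
        "best_lambda": best,
        "ci": ci,
        "recommend_transform": not (ci[0] <= 1.0 <= ci[1]),
    }


# ---------------------------------------------------------------------------
# exclusion workflow

@dataclass
class ExclusionTrail:
    response: str
    excluded: list[int] = field(default_factory=list)
    steps: list[dict] = field(default_factory=list)


def exclusion_workflow(
    runs: pd.DataFrame,
    response: str,
    termset: TermSet,
    space=None,
    transform: str = "none",
    thresholds: FlagThresholds | None = None,
    max_exclusions: int = 1,
    alpha: float = 0.05,
    reduce: bool = False,
) -> tuple[ModelFit, list[int], ExclusionTrail]:
    """Iteratively drop the worst outlying-and-influential run and refit.

    At each step the run with the largest |outlier-t| among exclusion
    candidates is removed, the model refitted, and the loop stops when no
    candidate remains or ``max_exclusions`` is reached (default one run, the
    cap used in the reference analysis).  With ``reduce=True`` the final fit
    is backward-eliminated at ``alpha``.
    """
    from .design import STUDY_SPACE

    space = space or STUDY_SPACE
    trail = ExclusionTrail(response)
    excluded: list[int] = []
    while True:
        mf = fit(runs, response, termset, space, transform, exclude=tuple(excluded))
        report = residual_diagnostics(mf, thresholds)
        cands = report.candidates
        trail.steps.append(
            {
                "excluded_so_far": list(excluded),
                "candidates": cands,
                "max_abs_t": float(report.stats["t_ext"].abs().max()),
            }
        )
        if not cands or len(excluded) >= max_exclusions:
            break
        excluded.append(cands[0])
    trail.excluded = list(excluded)
    if reduce:
        mf = backward_eliminate(mf, runs, alpha=alpha)
    return mf, excluded, trail
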