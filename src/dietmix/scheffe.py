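"""Scheffé polynomial response-surface models on the pseudo-component scale.

Scheffé mixture polynomials have no intercept: the constant is absorbed by
the linear blending terms because the pseudo coordinates sum to one.  The
model ladder used for sequential selection is the conventional one for three
components:

    mean -> linear -> quadratic -> special cubic -> cubic
         -> special quartic -> quartic

where *special cubic* adds ABC, *cubic* adds the difference terms
AB(A-B), AC(A-C), BC(B-C), *special quartic* adds A²BC, AB²C, ABC², and the
full quartic adds the squared-difference terms AB(A-B)², AC(A-C)², BC(B-C)².

ANOVA accounting follows the mixture convention: total SS is corrected by
the mean and df_model = p - 1, so a 3-term linear model on 40 runs reports
F with (2, 37) df.  Proportion responses may be arcsine-square-root
transformed before fitting; predictions are back-transformed with sin².
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import (
    BLEND_COLUMNS,
    STUDY_SPACE,
    MixtureSpace,
    blend_key,
    to_pseudo,
)

__all__ = [
    "ScheffeTerm",
    "TermSet",
    "ModelFit",
    "SequentialSelection",
    "MODEL_LADDER",
    "ladder_termset",
    "design_matrix",
    "fit",
    "lack_of_fit",
    "press_stats",
    "adequate_precision",
    "sequential_selection",
    "backward_eliminate",
    "predict",
    "CoefficientSurface",
    "arcsine_sqrt",
    "inv_arcsine_sqrt",
]


# ---------------------------------------------------------------------------
# transforms

def arcsine_sqrt(y):
    """Variance-stabilizing transform for proportions, arcsin(sqrt(y))."""
    y = np.asarray(y, float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("arcsine-sqrt transform requires values in [0, 1]")
    return np.arcsin(np.sqrt(y))


def inv_arcsine_sqrt(v):
    """Back-transform sin²(v), clamping to the principal branch [0, pi/2]."""
    return np.sin(np.clip(np.asarray(v, float), 0.0, np.pi / 2)) ** 2


TRANSFORMS = {
    "none": (lambda y: np.asarray(y, float), lambda v: np.asarray(v, float)),
    "arcsine_sqrt": (arcsine_sqrt, inv_arcsine_sqrt),
}


# ---------------------------------------------------------------------------
# terms

@dataclass(frozen=True)
class ScheffeTerm:
    """One model term: a weighted sum of monomials in the pseudo coordinates.

    Plain terms (A, A×B, A²×B×C, ...) hold a single monomial with weight 1;
    the cubic/quartic difference terms AB(A-B) etc. expand to two monomials.
    """

    name: str
    monomials: tuple[tuple[float, tuple[int, ...]], ...]

    def evaluate(self, z: np.ndarray) -> np.ndarray:
        """Term value at pseudo points ``z`` of shape (..., q)."""
        z = np.asarray(z, float)
        out = np.zeros(z.shape[:-1])
        for w, exps in self.monomials:
            out = out + w * np.prod(z ** np.asarray(exps), axis=-1)
        return out

    @property
    def max_exponents(self) -> tuple[int, ...]:
        """Componentwise maximum exponent; used for the mixture hierarchy."""
        arr = np.max([e for _, e in self.monomials], axis=0)
        return tuple(int(v) for v in arr)

    @property
    def degree(self) -> int:
        return max(sum(e) for _, e in self.monomials)

    @property
    def is_linear(self) -> bool:
        return self.degree == 1

    @property
    def is_intercept(self) -> bool:
        return self.degree == 0


def _mono(name: str, exps: tuple[int, ...]) -> ScheffeTerm:
    return ScheffeTerm(name, ((1.0, exps),))


def _letters(q: int) -> list[str]:
    return list("ABCDEFG"[:q])


def _plain_name(exps: tuple[int, ...], letters) -> str:
    parts = []
    for letter, e in zip(letters, exps):
        if e == 1:
            parts.append(letter)
        elif e > 1:
            parts.append(f"{letter}^{e}")
    return "*".join(parts)


def contains(outer: ScheffeTerm, inner: ScheffeTerm) -> bool:
    """Mixture hierarchy: ``outer`` contains ``inner`` when the exponent
    envelope of ``inner`` is dominated componentwise (A×B ⊂ A²×B×C)."""
    if outer is inner or outer == inner:
        return False
    a = np.asarray(outer.max_exponents)
    b = np.asarray(inner.max_exponents)
    return bool(np.all(a >= b) and np.any(a > b))


@dataclass(frozen=True)
class TermSet:
    """An ordered, duplicate-free collection of Scheffé terms."""

    label: str
    terms: tuple[ScheffeTerm, ...]

    def __post_init__(self):
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate terms in term set")
        if self.label != "mean" and not all(
            any(t.is_linear and t.max_exponents[i] == 1 for t in self.terms)
            for i in range(len(self.terms[0].max_exponents))
        ):
            raise ValueError("non-mean Scheffé models must contain all linear terms")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    def drop(self, name: str, *, label: str | None = None) -> "TermSet":
        kept = tuple(t for t in self.terms if t.name != name)
        if len(kept) == len(self.terms):
            raise KeyError(name)
        return TermSet(label or f"reduced:{self.label}", kept)


MODEL_LADDER = (
    "mean",
    "linear",
    "quadratic",
    "special_cubic",
    "cubic",
    "special_quartic",
    "quartic",
)


def ladder_termset(label: str, q: int = 3) -> TermSet:
    """Canonical term set of one ladder order for ``q`` mixture components."""
    letters = _letters(q)
    if label == "mean":
        return TermSet("mean", (ScheffeTerm("1", ((1.0, (0,) * q),)),))

    def unit(i):
        e = [0] * q
        e[i] = 1
        return tuple(e)

    linear = [_mono(letters[i], unit(i)) for i in range(q)]
    pairs = list(itertools.combinations(range(q), 2))

    def pair_exps(i, j, ei, ej):
        e = [0] * q
        e[i], e[j] = ei, ej
        return tuple(e)

    quad = [_mono(f"{letters[i]}*{letters[j]}", pair_exps(i, j, 1, 1)) for i, j in pairs]
    terms = list(linear)
    if label == "linear":
        return TermSet(label, tuple(terms))
    terms += quad
    if label == "quadratic":
        return TermSet(label, tuple(terms))

    def full_product(extra: dict[int, int]) -> tuple[int, ...]:
        e = [1] * q
        for i, v in extra.items():
            e[i] = v
        return tuple(e)

    special_cubic = [_mono("*".join(letters), tuple([1] * q))] if q >= 3 else []
    if label == "special_cubic":
        return TermSet(label, tuple(terms + special_cubic))

    diff = [
        ScheffeTerm(
            f"{letters[i]}*{letters[j]}*({letters[i]}-{letters[j]})",
            ((1.0, pair_exps(i, j, 2, 1)), (-1.0, pair_exps(i, j, 1, 2))),
        )
        for i, j in pairs
    ]
    if label == "cubic":
        return TermSet(label, tuple(terms + special_cubic + diff))

    special_quartic = [
        _mono(
            _plain_name(full_product({i: 2}), letters),
            full_product({i: 2}),
        )
        for i in range(q)
    ]
    if label == "special_quartic":
        return TermSet(label, tuple(terms + special_quartic))

    diff2 = [
        ScheffeTerm(
            f"{letters[i]}*{letters[j]}*({letters[i]}-{letters[j]})^2",
            (
                (1.0, pair_exps(i, j, 3, 1)),
                (-2.0, pair_exps(i, j, 2, 2)),
                (1.0, pair_exps(i, j, 1, 3)),
            ),
        )
        for i, j in pairs
    ]
    if label == "quartic":
        return TermSet(label, tuple(terms + diff + diff2 + special_quartic))
    raise KeyError(f"unknown ladder order: {label!r}")


# ---------------------------------------------------------------------------
# fitting

def design_matrix(runs: pd.DataFrame, termset: TermSet, space: MixtureSpace = STUDY_SPACE) -> np.ndarray:
    """Evaluate every term at every run's pseudo coordinates."""
    z = to_pseudo(runs[BLEND_COLUMNS].to_numpy(float), space)
    return np.column_stack([t.evaluate(z) for t in termset])


@dataclass
class ModelFit:
    """A fitted Scheffé model with the summary statistics used for selection.

    Coefficients live on the pseudo-component scale and, for transformed
    responses, on the transformed scale; ``predict`` returns original-scale
    values.
    """

    response: str
    transform: str
    termset: TermSet
    space: MixtureSpace
    coef: np.ndarray
    se: np.ndarray
    ci: np.ndarray  # (p, 2) 95% bounds
    sigma: float
    df_model: int
    df_resid: int
    n_obs: int
    run_ids: np.ndarray
    X: np.ndarray
    y: np.ndarray  # transformed response actually fitted
    fitted: np.ndarray
    resid: np.ndarray
    leverage: np.ndarray
    cov: np.ndarray  # coefficient covariance
    r2: float
    r2_adj: float
    r2_pred: float
    press: float
    adequate_precision: float
    model_f: float
    model_p: float
    anova_partial: pd.DataFrame | None = None
    lof: dict | None = None
    excluded_runs: tuple[int, ...] = ()

    # -- coefficient access -------------------------------------------------
    def coef_named(self, name: str) -> float:
        return float(self.coef[self.termset.names.index(name)])

    def ci_named(self, name: str) -> tuple[float, float]:
        lo, hi = self.ci[self.termset.names.index(name)]
        return float(lo), float(hi)

    # -- prediction ---------------------------------------------------------
    def predict_transformed(self, blends) -> np.ndarray:
        z = to_pseudo(np.atleast_2d(np.asarray(blends, float)), self.space)
        X0 = np.column_stack([t.evaluate(z) for t in self.termset])
        return X0 @ self.coef

    def predict(self, blends, ci: bool = False, confidence: float = 0.95):
        """Point predictions (and optional CI) on the original response scale."""
        z = to_pseudo(np.atleast_2d(np.asarray(blends, float)), self.space)
        X0 = np.column_stack([t.evaluate(z) for t in self.termset])
        eta = X0 @ self.coef
        _, back = TRANSFORMS[self.transform]
        if not ci:
            return back(eta)
        se = np.sqrt(np.einsum("ij,jk,ik->i", X0, self.cov, X0))
        tval = stats.t.ppf(0.5 + confidence / 2, self.df_resid)
        lo, hi = eta - tval * se, eta + tval * se
        return back(eta), back(lo), back(hi)

    def to_dict(self) -> dict:
        """JSON-serializable summary (terms, coefficients, statistics)."""
        d = {
            "response": self.response,
            "transform": self.transform,
            "model": self.termset.label,
            "terms": self.termset.names,
            "coefficients": self.coef.tolist(),
            "se": self.se.tolist(),
            "ci95": self.ci.tolist(),
            "sigma": self.sigma,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "n_obs": self.n_obs,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "r2_pred": self.r2_pred,
            "press": self.press,
            "adequate_precision": self.adequate_precision,
            "model_f": self.model_f,
            "model_p": self.model_p,
            "excluded_runs": list(self.excluded_runs),
        }
        if self.lof is not None:
            d["lack_of_fit"] = {k: (None if v is None else float(v)) for k, v in self.lof.items()}
        if self.anova_partial is not None:
            d["anova_partial"] = self.anova_partial.to_dict(orient="list")
        return d


def _response_rows(runs: pd.DataFrame, response: str, exclude: tuple[int, ...]) -> pd.DataFrame:
    """Rows usable for one response: value present, not excluded."""
    df = runs
    mask = df[response].notna()
    if "excluded_responses" in df.columns:
        exc = df["excluded_responses"].fillna("")
        mask &= ~exc.str.split(";").apply(
            lambda lst: response in [s.strip() for s in lst] or "all" in lst
        )
    if exclude:
        mask &= ~df["run_id"].isin(exclude)
    return df.loc[mask]


def fit(
    runs: pd.DataFrame,
    response: str,
    termset: TermSet,
    space: MixtureSpace = STUDY_SPACE,
    transform: str = "none",
    exclude: tuple[int, ...] = (),
    confidence: float = 0.95,
    with_lof: bool = True,
) -> ModelFit:
    """Least-squares fit of a Scheffé term set to one response.

    Runs whose response is missing or excluded are dropped for this response
    only.  Raises ``numpy.linalg.LinAlgError`` for an aliased term set.
    """
    data = _response_rows(runs, response, tuple(exclude))
    fwd, _ = TRANSFORMS[transform]
    y = fwd(data[response].to_numpy(float))
    X = design_matrix(data, termset, space)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} usable runs cannot estimate {p} terms")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError(
            f"term set '{termset.label}' is aliased on this design"
        )

    res = sm.OLS(y, X).fit()
    coef = res.params
    sigma2 = float(res.mse_resid)
    cov = res.cov_params()
    se = res.bse
    df_resid = int(res.df_resid)
    tval = stats.t.ppf(0.5 + confidence / 2, df_resid)
    ci = np.column_stack([coef - tval * se, coef + tval * se])

    fitted = res.fittedvalues
    resid = res.resid
    hat = np.einsum("ij,ij->i", X @ np.linalg.pinv(X.T @ X), X)

    # mixture-model ANOVA: total SS corrected by the mean, df_model = p - 1
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    ss_model = ss_tot - ss_res
    df_model = p - 1
    if df_model > 0 and sigma2 > 0:
        model_f = (ss_model / df_model) / sigma2
        model_p = float(stats.f.sf(model_f, df_model, df_resid))
    else:
        model_f, model_p = np.nan, np.nan
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2_adj = 1.0 - (ss_res / df_resid) / (ss_tot / (n - 1)) if ss_tot > 0 and df_resid > 0 else np.nan

    one_minus_h = 1.0 - hat
    if np.any(one_minus_h <= 1e-10):
        press = np.nan
        r2_pred = np.nan
    else:
        press = float(np.sum((resid / one_minus_h) ** 2))
        r2_pred = 1.0 - press / ss_tot if ss_tot > 0 else np.nan

    # adequate precision: prediction range over design points vs mean
    # prediction variance sqrt(p * sigma^2 / n); exact fits (sigma ~ 0 at
    # machine precision) map to +inf, constant surfaces to 0
    denom = np.sqrt(p * sigma2 / n)
    rng = float(fitted.max() - fitted.min())
    scale = max(1.0, float(np.max(np.abs(fitted))))
    if rng < 1e-9 * scale:
        ap = 0.0
    elif denom < 1e-9 * scale:
        ap = np.inf
    else:
        ap = rng / denom

    # Type III (partial) ANOVA: single-df F = t² per term
    with np.errstate(divide="ignore", invalid="ignore"):
        fvals = (coef / se) ** 2
    pvals = stats.f.sf(fvals, 1, df_resid)
    anova = pd.DataFrame(
        {"term": termset.names, "F": fvals, "p": pvals, "coef": coef, "se": se}
    )

    mf = ModelFit(
        response=response,
        transform=transform,
        termset=termset,
        space=space,
        coef=coef,
        se=se,
        ci=ci,
        sigma=float(np.sqrt(sigma2)),
        df_model=df_model,
        df_resid=df_resid,
        n_obs=n,
        run_ids=data["run_id"].to_numpy(),
        X=X,
        y=y,
        fitted=fitted,
        resid=resid,
        leverage=hat,
        cov=cov,
        r2=r2,
        r2_adj=r2_adj,
        r2_pred=r2_pred,
        press=press,
        adequate_precision=float(ap),
        model_f=float(model_f),
        model_p=float(model_p),
        anova_partial=anova,
        excluded_runs=tuple(exclude),
    )
    if with_lof:
        try:
            mf.lof = lack_of_fit(mf, data)
        except ValueError:
            mf.lof = None
    return mf


# ---------------------------------------------------------------------------
# summary statistics

def lack_of_fit(fit_: ModelFit, runs: pd.DataFrame) -> dict:
    """Lack-of-fit F test against pure error pooled within replicate blends.

    ``runs`` must contain the rows the fit used (extra rows are ignored).
    """
    data = runs.set_index("run_id").loc[fit_.run_ids]
    groups = [blend_key(b) for b in data[BLEND_COLUMNS].to_numpy(float)]
    y = fit_.y
    df_grp = pd.DataFrame({"g": groups, "y": y})
    means = df_grp.groupby("g")["y"].transform("mean")
    ss_pe = float(np.sum((df_grp["y"] - means) ** 2))
    n_distinct = df_grp["g"].nunique()
    df_pe = len(df_grp) - n_distinct
    if df_pe == 0:
        raise ValueError("no replicated blends: pure error is not estimable")
    ss_res = float(np.sum(fit_.resid**2))
    ss_lof = max(ss_res - ss_pe, 0.0)
    df_lof = n_distinct - len(fit_.termset)
    if df_lof <= 0:
        return {"F": np.nan, "p": np.nan, "df_lof": df_lof, "df_pe": df_pe,
                "ss_lof": ss_lof, "ss_pe": ss_pe}
    if ss_pe == 0:
        F = np.inf if ss_lof > 0 else 0.0
        p = 0.0 if ss_lof > 0 else 1.0
    else:
        F = (ss_lof / df_lof) / (ss_pe / df_pe)
        p = float(stats.f.sf(F, df_lof, df_pe))
    return {"F": float(F), "p": p, "df_lof": int(df_lof), "df_pe": int(df_pe),
            "ss_lof": ss_lof, "ss_pe": ss_pe}


def press_stats(fit_: ModelFit) -> dict:
    """PRESS and predicted R² from the hat-matrix leave-one-out identity."""
    if np.any(fit_.leverage >= 1 - 1e-10):
        raise ValueError("a design point has leverage 1; cannot cross-validate")
    press = float(np.sum((fit_.resid / (1 - fit_.leverage)) ** 2))
    ss_tot = float(np.sum((fit_.y - fit_.y.mean()) ** 2))
    return {"press": press, "r2_pred": 1 - press / ss_tot if ss_tot > 0 else np.nan}


def adequate_precision(fit_: ModelFit) -> float:
    """Signal-to-noise ratio: fitted-value range over average prediction sd."""
    return fit_.adequate_precision


# ---------------------------------------------------------------------------
# sequential model selection

@dataclass
class SequentialSelection:
    """Type I (sequential) model ladder with the chosen order and rationale."""

    response: str
    transform: str
    table: pd.DataFrame
    chosen: str
    rationale: list[str] = field(default_factory=list)

    @property
    def chosen_termset(self) -> TermSet:
        return ladder_termset(self.chosen)


def sequential_selection(
    runs: pd.DataFrame,
    response: str,
    space: MixtureSpace = STUDY_SPACE,
    transform: str = "none",
    alpha: float = 0.05,
    exclude: tuple[int, ...] = (),
) -> SequentialSelection:
    """Walk the model ladder with incremental Type I F tests and pick an order.

    Selection rule (encoding the usual response-surface criteria): aliased
    orders are rejected outright; among orders whose sequential F test is
    significant at ``alpha``, those without significant lack of fit are
    preferred, ties broken by the larger predicted R², then by higher order.
    The linear model is the fallback when nothing qualifies.
    """
    rows = []
    fits: dict[str, ModelFit] = {}
    prev_ss, prev_p = 0.0, 1  # mean model: SS_model = 0, one parameter
    data = _response_rows(runs, response, tuple(exclude))
    n = len(data)
    for label in MODEL_LADDER[1:]:
        ts = ladder_termset(label)
        p = len(ts)
        aliased = False
        rec = {"order": label, "n_terms": p}
        if p >= n:
            aliased = True
        else:
            X = design_matrix(data, ts, space)
            aliased = np.linalg.matrix_rank(X) < p
        if aliased:
            rec.update(aliased=True, seq_F=np.nan, seq_p=np.nan)
            rows.append(rec)
            continue
        mf = fit(runs, response, ts, space, transform, exclude=tuple(exclude))
        fits[label] = mf
        ss_model = float(np.sum((mf.fitted - mf.y.mean()) ** 2))
        d_ss = ss_model - prev_ss
        d_p = p - prev_p
        mse = mf.sigma**2
        seq_F = (d_ss / d_p) / mse if mse > 0 else np.inf
        seq_p = float(stats.f.sf(seq_F, d_p, mf.df_resid)) if np.isfinite(seq_F) else 0.0
        rec.update(
            aliased=False,
            seq_ss=d_ss,
            seq_df=d_p,
            seq_F=seq_F,
            seq_p=seq_p,
            sigma=mf.sigma,
            r2=mf.r2,
            r2_adj=mf.r2_adj,
            r2_pred=mf.r2_pred,
            press=mf.press,
            adequate_precision=mf.adequate_precision,
            lof_F=(mf.lof or {}).get("F", np.nan),
            lof_p=(mf.lof or {}).get("p", np.nan),
        )
        rows.append(rec)
        prev_ss, prev_p = ss_model, p
    table = pd.DataFrame(rows)

    rationale = []
    ok = table.loc[~table["aliased"].astype(bool)]
    qual = ok.loc[ok["seq_p"] < alpha]
    if qual.empty:
        chosen = "linear"
        rationale.append("no order improves sequentially; falling back to linear")
    else:
        lof_ok = qual.loc[~(qual["lof_p"] < alpha)]
        pool = lof_ok if not lof_ok.empty else qual
        if lof_ok.empty:
            rationale.append("all qualifying orders show significant lack of fit")
        else:
            rationale.append("preferring orders without significant lack of fit")
        # highest qualifying order; predicted R² breaks exact ties
        top = pool.iloc[-1]
        tied = pool.loc[np.isclose(pool["n_terms"], top["n_terms"])]
        chosen = tied.loc[tied["r2_pred"].fillna(-np.inf).idxmax()]["order"]
        rationale.append(f"highest order with significant sequential F: {chosen}")
    return SequentialSelection(response, transform, table, chosen, rationale)


# ---------------------------------------------------------------------------
# backward elimination

def backward_eliminate(fit_: ModelFit, runs: pd.DataFrame, alpha: float = 0.05) -> ModelFit:
    """Hierarchical backward elimination of non-significant terms.

    Linear blending terms are never removed; a term is removable only when no
    retained higher-order term contains it.  The removable term with the
    largest partial-F p-value >= ``alpha`` is dropped and the model refitted,
    until no removable term is non-significant.
    """
    current = fit_
    while True:
        ts = current.termset
        pvals = dict(zip(ts.names, current.anova_partial["p"]))
        removable = [
            t for t in ts
            if not t.is_linear
            and not t.is_intercept
            and not any(contains(u, t) for u in ts if u.name != t.name)
        ]
        candidates = [(pvals[t.name], t.name) for t in removable if pvals[t.name] >= alpha]
        if not candidates:
            return current
        _, worst = max(candidates)
        reduced = ts.drop(worst, label=f"reduced:{fit_.termset.label}")
        current = fit(
            runs, current.response, reduced, current.space, current.transform,
            exclude=current.excluded_runs,
        )


def predict(fit_: ModelFit, blends, confidence: float = 0.95) -> pd.DataFrame:
    """Original-scale predictions with confidence intervals for blends."""
    yhat, lo, hi = fit_.predict(blends, ci=True, confidence=confidence)
    blends = np.atleast_2d(np.asarray(blends, float))
    out = pd.DataFrame(blends, columns=BLEND_COLUMNS)
    out["predicted"], out["ci_low"], out["ci_high"] = yhat, lo, hi
    return out


# ---------------------------------------------------------------------------
# coefficient-only surfaces (e.g. published fits without raw data)

@dataclass(frozen=True)
class CoefficientSurface:
    """A response surface specified only by its Scheffé coefficients.

    Used when the coefficients of a fitted model are known but the underlying
    raw data (and hence covariances) are not — for instance the packaged
    reference fits.  Supports prediction, not inference.
    """

    response: str
    termset: TermSet
    coef: tuple[float, ...]
    transform: str = "none"
    space: MixtureSpace = STUDY_SPACE

    def predict_transformed(self, blends) -> np.ndarray:
        z = to_pseudo(np.atleast_2d(np.asarray(blends, float)), self.space)
        X0 = np.column_stack([t.evaluate(z) for t in self.termset])
        return X0 @ np.asarray(self.coef)

    def predict(self, blends) -> np.ndarray:
        _, back = TRANSFORMS[self.transform]
        return back(self.predict_transformed(blends))

    def predict_pseudo(self, z) -> np.ndarray:
        z = np.asarray(z, float)
        X0 = np.column_stack([t.evaluate(z) for t in self.termset])
        _, back = TRANSFORMS[self.transform]
        return back(X0 @ np.asarray(self.coef))
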