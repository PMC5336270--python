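import numpy as np
import pandas as pd
import pytest

from dietmix.design import reference_design
from dietmix.scheffe import design_matrix, fit
from dietmix.synthetic import simulate_runs


@pytest.fixture(scope="session")
def design40():
    """The default 40-run design (19 distinct blends, 21 pure-error df)."""
    return reference_design()


@pytest.fixture(scope="session")
def noisy_runs(design40):
    """One simulated realization of the experiment (fixed seed)."""
    return simulate_runs(design40, seed=7)


@pytest.fixture(scope="session")
def noise_free_runs(design40):
    """Responses equal to the truth surfaces exactly."""
    return simulate_runs(design40, noise=False)


# ---------------------------------------------------------------------------
# independent leave-one-out oracle: explicit refits, no closed forms

def loo_oracle(mf):
    """Influence statistics recomputed by deleting each run and refitting."""
    X, y = mf.X, mf.y
    n, p = X.shape
    b_full, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ b_full
    s2 = float((y - fitted) @ (y - fitted)) / (n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    t_ext = np.empty(n)
    press = 0.0
    dffits = np.empty(n)
    cooks = np.empty(n)
    dfbetas = np.empty((n, p))
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        bi, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        ri = yi - Xi @ bi
        s2i = float(ri @ ri) / (n - 1 - p)
        XtXi_inv = np.linalg.inv(Xi.T @ Xi)
        pred = float(X[i] @ bi)
        var_pred = s2i * (1.0 + X[i] @ XtXi_inv @ X[i])
        e_del = y[i] - pred
        t_ext[i] = e_del / np.sqrt(var_pred)
        press += e_del**2
        dffits[i] = (fitted[i] - pred) / np.sqrt(s2i * h[i])
        shift = fitted - X @ bi
        cooks[i] = float(shift @ shift) / (p * s2)
        dfbetas[i] = (b_full - bi) / np.sqrt(s2i * np.diag(XtX_inv))
    return {
        "t_ext": t_ext,
        "press": press,
        "dffits": dffits,
        "cooks_d": cooks,
        "dfbetas": dfbetas,
    }


@pytest.fixture(scope="session")
def small_fits(noisy_runs):
    """A few fits of varied size/order/transform for oracle comparisons."""
    from dietmix.scheffe import ladder_termset

    return [
        fit(noisy_runs, "pupation", ladder_termset("linear")),
        fit(noisy_runs, "duration_days", ladder_termset("quadratic")),
        fit(noisy_runs, "pupal_weight_mg", ladder_termset("special_cubic")),
        fit(noisy_runs, "emergence", ladder_termset("linear"), transform="arcsine_sqrt"),
    ]
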