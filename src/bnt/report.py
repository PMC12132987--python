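"""Model-comparison summaries and the normality pre-check.

Conventions (stated in every report header): AIC = -2l + 2k and
BIC = -2l + k ln(n_eff), where k counts the nonzero coefficients of the
selected model (intercept included; +1 for sigma in the continuous part)
and n_eff is n for the binomial part and the number of nonzero rows for
the continuous part.  The combined column is the sum of the two parts.
ME is the K-fold cross-validated prediction error of the selected model
at its fixed penalties.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .data import SemicontinuousDataset
from .exceptions import DegenerateDataError
from .model import loglik_binomial, loglik_continuous
from .estimators import PenalizedBNTRegression
from . import tuning

__all__ = ["report_model", "shapiro_precheck"]

CONVENTIONS = (
    "AIC=-2l+2k, BIC=-2l+k*ln(n_eff); k = nonzero coefficients of the "
    "selected model incl. intercept (+1 for sigma, continuous part); "
    "n_eff = n (binomial) / #nonzero rows (continuous); "
    "ME = K-fold CV prediction error at the selected penalties"
)


def _me_cv(est, data: SemicontinuousDataset, K: int, seed) -> dict:
    """K-fold prediction error of the already-selected model: refit at the
    fixed penalties on each training split, score the held-out rows."""
    folds = tuning.make_folds(data.n, K, seed)
    err_b, err_n = [], []
    for j in range(K):
        hold = folds == j
        train = data.subset(~hold)
        refit = PenalizedBNTRegression(
            penalty=getattr(est, "penalty", "lasso"),
            lambda1=est.lambda1_,
            lambda2=est.lambda2_,
        ).fit(train.Z1[:, 1:], train.x, indicator=train.y)
        C = data.Z1[hold][:, 1:]
        pi = refit.predict_nonzero_proba(C)
        mu = refit.predict_positive_mean(C)
        x = data.x[hold]
        err_b.append(float(np.mean((x - pi * mu) ** 2)))
        posm = hold & (data.y == 1)
        if posm.any():
            mu_p = refit.predict_positive_mean(data.Z2[posm][:, 1:])
            err_n.append(float(np.mean((data.x[posm] - mu_p) ** 2)))
    me_b = float(np.mean(err_b))
    me_n = float(np.mean(err_n)) if err_n else float("nan")
    return {"binomial": me_b, "normal": me_n, "two_parts": me_b + me_n}


def report_model(
    est,
    data: SemicontinuousDataset,
    K: int = 10,
    seed: int = 0,
    include_me: bool = True,
) -> dict:
    """-2LogLik / AIC / BIC (and optionally the CV error ME) of a fitted
    two-part model, per part and combined."""
    beta1 = est._beta1()
    beta2 = est._beta2()
    l1 = loglik_binomial(beta1, data)
    l2 = loglik_continuous(beta2, est.sigma_, data)
    k1 = int(np.sum(beta1 != 0))
    k2 = int(np.sum(beta2 != 0)) + 1  # + sigma
    n1 = data.n
    n2 = data.n_pos
    out = {
        "conventions": CONVENTIONS,
        "binomial": {
            "neg2loglik": -2 * l1,
            "AIC": -2 * l1 + 2 * k1,
            "BIC": -2 * l1 + k1 * np.log(n1),
            "k": k1,
            "n_eff": n1,
        },
        "normal": {
            "neg2loglik": -2 * l2,
            "AIC": -2 * l2 + 2 * k2,
            "BIC": -2 * l2 + k2 * np.log(n2),
            "k": k2,
            "n_eff": n2,
        },
    }
    out["two_parts"] = {
        key: out["binomial"][key] + out["normal"][key]
        for key in ("neg2loglik", "AIC", "BIC", "k")
    }
    if include_me and hasattr(est, "lambda1_"):
        me = _me_cv(est, data, K, seed)
        for part in ("binomial", "normal", "two_parts"):
            out[part]["ME"] = me[part]
    return out


def shapiro_precheck(data: SemicontinuousDataset) -> float:
    """Shapiro-Wilk p-value on the nonzero outcomes (advisory only —
    a small p suggests the normal continuous part fits poorly and a
    transform or different continuous family may be warranted)."""
    pos = data.x[data.positive]
    if pos.size < 3:
        raise DegenerateDataError(
            f"normality test needs at least 3 nonzero outcomes, got {pos.size}"
        )
    if np.ptp(pos) == 0:
        raise DegenerateDataError("nonzero outcomes are constant")
    return float(stats.shapiro(pos).pvalue)
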