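"""Unpenalized maximum-likelihood estimation of both model parts.

The binomial part is fit by Newton iteration on the logistic
log-likelihood with a step-halving safeguard.  The continuous part has an
exact solution — least squares on the nonzero rows plus the ML variance —
which is returned directly (the Newton fixed point is identical).

These ML estimates supply the adaptive-Lasso weights omega = 1/|theta_ml|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import SemicontinuousDataset
from .exceptions import ConvergenceError, DataError, DegenerateDataError
from .model import clamp_eta, loglik_binomial, loglik_continuous, _check_dim

__all__ = [
    "NewtonTrace",
    "score_binomial",
    "info_binomial",
    "fit_mle_binomial",
    "score_continuous",
    "info_continuous",
    "fit_mle_continuous",
]


@dataclass
class NewtonTrace:
    """Iterates and log-likelihood values of a Newton fit."""

    iterates: list = field(default_factory=list)
    loglik_values: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def score_binomial(beta1, data: SemicontinuousDataset) -> np.ndarray:
    """Score U(beta1) = sum (y_i - pi_i) z1_i."""
    beta1 = _check_dim("beta1", beta1, data.Z1)
    pi = expit(clamp_eta(data.Z1 @ beta1))
    return data.Z1.T @ (data.y - pi)


def info_binomial(beta1, data: SemicontinuousDataset) -> np.ndarray:
    """Observed information I(beta1) = sum pi_i (1 - pi_i) z1_i z1_i'."""
    beta1 = _check_dim("beta1", beta1, data.Z1)
    pi = expit(clamp_eta(data.Z1 @ beta1))
    w = pi * (1.0 - pi)
    return (data.Z1 * w[:, None]).T @ data.Z1


def fit_mle_binomial(
    data: SemicontinuousDataset,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Logistic-regression MLE by safeguarded Newton iteration.

    Converges when the max-norm of the accepted update falls below
    ``tol``.  Step halving (up to 20 times) keeps the log-likelihood
    non-decreasing between accepted iterates.
    """
    data.require_both_classes()
    p = data.Z1.shape[1]
    beta = np.zeros(p)
    ll = loglik_binomial(beta, data)
    trace = NewtonTrace(iterates=[beta.copy()], loglik_values=[ll])
    for _ in range(max_iter):
        U = score_binomial(beta, data)
        info = info_binomial(beta, data)
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError as exc:
            raise DegenerateDataError(
                "singular information matrix; Z1 may be rank deficient "
                "or the fit quasi-separated"
            ) from exc
        alpha = 1.0
        for _h in range(21):
            cand = beta + alpha * step
            ll_new = loglik_binomial(cand, data)
            if ll_new >= ll - 1e-12:
                break
            alpha *= 0.5
        beta = beta + alpha * step
        ll = ll_new
        trace.iterates.append(beta.copy())
        trace.loglik_values.append(ll)
        trace.n_iter += 1
        if np.max(np.abs(alpha * step)) < tol:
            trace.converged = True
            break
    else:
        raise ConvergenceError(
            f"binomial-part Newton did not converge in {max_iter} iterations",
            trace=trace,
        )
    pi = expit(clamp_eta(data.Z1 @ beta))
    if np.max(np.abs(beta)) > 15.0 and (
        np.any(pi < 1e-8) or np.any(pi > 1 - 1e-8)
    ):
        warnings.warn(
            "quasi-separation detected in the binomial part: some fitted "
            "probabilities are within 1e-8 of 0/1; coefficients reflect the "
            "clamped linear predictor",
            RuntimeWarning,
            stacklevel=2,
        )
    return beta, trace


def score_continuous(beta2, sigma, data: SemicontinuousDataset) -> np.ndarray:
    """Concatenated score (U_beta2, U_sigma) of the continuous part."""
    beta2 = _check_dim("beta2", beta2, data.Z2)
    sigma = float(sigma)
    if sigma <= 0:
        raise DataError(f"sigma must be positive, got {sigma}")
    pos = data.positive
    Zp = data.Z2[pos]
    r = data.x[pos] - Zp @ beta2
    u_beta = Zp.T @ r / sigma**2
    u_sigma = np.sum(r * r - sigma**2) / sigma**3
    return np.concatenate([u_beta, [u_sigma]])


def info_continuous(beta2, sigma, data: SemicontinuousDataset) -> np.ndarray:
    """Observed information of (beta2, sigma): the positive-definite
    negative Hessian of l2, blockwise

        [ sum zz'/s^2          sum 2 r z / s^3 ]
        [ (sym)          sum (3 r^2/s^4 - 1/s^2) ]

    summed over nonzero rows.
    """
    beta2 = _check_dim("beta2", beta2, data.Z2)
    sigma = float(sigma)
    if sigma <= 0:
        raise DataError(f"sigma must be positive, got {sigma}")
    pos = data.positive
    if not pos.any():
        raise DegenerateDataError("no nonzero rows for the continuous part")
    Zp = data.Z2[pos]
    r = data.x[pos] - Zp @ beta2
    p = Zp.shape[1]
    info = np.empty((p + 1, p + 1))
    info[:p, :p] = Zp.T @ Zp / sigma**2
    cross = 2.0 * (Zp.T @ r) / sigma**3
    info[:p, p] = cross
    info[p, :p] = cross
    info[p, p] = np.sum(3.0 * r * r / sigma**4 - 1.0 / sigma**2)
    return info


def fit_mle_continuous(
    data: SemicontinuousDataset,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Continuous-part MLE: least squares on nonzero rows, ML variance.

    Maximizing l2 is equivalent to least squares on the nonzero
    sub-sample, so the closed form is used; the returned trace records the
    solution as a single accepted Newton iterate (``tol``/``max_iter`` are
    accepted for interface symmetry).
    """
    del tol, max_iter
    pos = data.positive
    Zp = data.Z2[pos]
    xp = data.x[pos]
    p = Zp.shape[1]
    if xp.size < p + 1:
        raise DegenerateDataError(
            f"continuous part needs at least q2+2={p + 1} nonzero rows, "
            f"got {xp.size}"
        )
    beta, _res, rank, _sv = np.linalg.lstsq(Zp, xp, rcond=None)
    if rank < p:
        raise DegenerateDataError(
            "Z2 is rank deficient on the nonzero rows"
        )
    r = xp - Zp @ beta
    sigma2 = float(np.mean(r * r))
    if sigma2 <= 0:
        raise DegenerateDataError(
            "zero residual variance in the continuous part"
        )
    sigma = float(np.sqrt(sigma2))
    trace = NewtonTrace(
        iterates=[np.concatenate([beta, [sigma]])],
        loglik_values=[loglik_continuous(beta, sigma, data)],
        converged=True,
        n_iter=1,
    )
    return beta, sigma, trace
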