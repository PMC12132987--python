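"""Lasso and adaptive-Lasso estimation of the two-part model.

Both parts are penalized separately (the log-likelihood is additive, so
the two L1 problems do not interact):

* continuous part — penalized least squares on the nonzero rows, solved
  by cyclic coordinate descent with soft-thresholding;
* binomial part — penalized logistic regression, solved by a nested
  IRLS-quadratic (external) + coordinate-descent (internal) loop.

Intercepts and the scale sigma are never penalized.  The adaptive Lasso
uses weights omega_j = 1/|beta_j_ml| from the unpenalized fit; with all
weights equal to one it reduces exactly to the Lasso.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from . import _cd
from .data import SemicontinuousDataset
from .exceptions import (
    ConvergenceError,
    DataError,
    DegenerateDataError,
)
from .mle import fit_mle_binomial, fit_mle_continuous
from .model import clamp_eta, loglik_binomial, _check_dim

__all__ = [
    "PenaltySpec",
    "PenalizedFit",
    "PartFit",
    "IRLSState",
    "soft_threshold",
    "cd_update_normal",
    "fit_cd_normal",
    "irls_quadratic",
    "cd_update_logistic",
    "fit_cd_logistic",
    "adaptive_weights",
    "fit_penalized",
    "lambda_max_normal",
    "lambda_max_logistic",
    "lambda_grid",
    "path_normal",
    "path_logistic",
    "sigma_from_beta2",
    "objective_normal",
    "objective_logistic",
]

W_FLOOR = 1e-5
WEIGHT_CAP = 1e6
TOL_INNER = 1e-7
TOL_OUTER = 1e-6
MAX_INNER = 10_000
MAX_OUTER = 50
N_LAMBDAS = 100
LAMBDA_MIN_RATIO = 1e-3


@dataclass
class PenaltySpec:
    """Penalty configuration for both parts.

    ``omega1``/``omega2`` are positive weights for the non-intercept
    coefficients (length q1/q2).  For ``method='lasso'`` they are forced
    to ones; for ``method='alasso'`` leaving them ``None`` means they are
    derived from the unpenalized MLE at fit time.
    """

    method: str
    lambda1: float
    lambda2: float
    omega1: np.ndarray | None = None
    omega2: np.ndarray | None = None

    def __post_init__(self):
        if self.method not in ("lasso", "alasso"):
            raise DataError(f"unknown penalty method {self.method!r}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise DataError("tuning parameters must be non-negative")
        for name in ("omega1", "omega2"):
            w = getattr(self, name)
            if w is not None:
                w = np.asarray(w, dtype=float).ravel()
                if np.any(w <= 0):
                    raise DataError(f"{name} must be strictly positive")
                setattr(self, name, w)
        if self.method == "lasso":
            for name in ("omega1", "omega2"):
                w = getattr(self, name)
                if w is not None and not np.all(w == 1.0):
                    raise DataError(
                        "lasso is the unit-weight special case; "
                        f"non-unit {name} requires method='alasso'"
                    )

    def resolve_weights(self, data: SemicontinuousDataset):
        if self.method == "lasso":
            return np.ones(data.q1), np.ones(data.q2)
        o1, o2 = self.omega1, self.omega2
        if o1 is None or o2 is None:
            a1, a2 = adaptive_weights(data)
            o1 = a1 if o1 is None else o1
            o2 = a2 if o2 is None else o2
        return o1, o2


@dataclass
class PartFit:
    """Solution of one penalized part."""

    beta: np.ndarray
    lambda_: float
    active_set: np.ndarray
    n_outer: int
    n_inner: int
    converged: bool


@dataclass
class PenalizedFit:
    """A regularization-path entry for the full two-part model."""

    beta1: np.ndarray
    beta2: np.ndarray
    sigma: float
    lambda1: float
    lambda2: float
    active_set1: np.ndarray
    active_set2: np.ndarray
    n_outer: int
    n_inner: int
    converged: bool


@dataclass
class IRLSState:
    """Quadratic expansion of the logistic log-likelihood at ``beta1_old``."""

    gamma: np.ndarray
    w: np.ndarray
    beta1_old: np.ndarray


def soft_threshold(a: float, b: float) -> float:
    """S(a, b) = sign(a) * max(|a| - b, 0) for b >= 0."""
    if b < 0:
        raise DataError(f"threshold must be non-negative, got {b}")
    return float(np.sign(a) * max(abs(a) - b, 0.0))


def _pen_vector(omega, q) -> np.ndarray:
    omega = np.ones(q) if omega is None else np.asarray(omega, float).ravel()
    if omega.size != q:
        raise DataError(
            f"penalty weights: expected length {q}, got {omega.size}"
        )
    return np.concatenate([[0.0], omega])  # intercept unpenalized


def _active_set(beta: np.ndarray) -> np.ndarray:
    """Indices (into the coefficient vector, 1..q) of nonzero
    non-intercept coefficients."""
    return np.flatnonzero(beta[1:] != 0.0) + 1


def _positive_design(data: SemicontinuousDataset):
    pos = data.positive
    if not pos.any():
        raise DegenerateDataError("no nonzero rows for the continuous part")
    Zp = data.Z2[pos]
    xp = data.x[pos]
    ssq = np.sum(Zp * Zp, axis=0)
    dead = np.flatnonzero(ssq == 0.0)
    if dead.size:
        raise DegenerateDataError(
            f"covariate column {dead[0]} of Z2 is identically zero on "
            "the nonzero rows"
        )
    return Zp, xp


# --------------------------------------------------------------------------
# continuous (normal) part
# --------------------------------------------------------------------------

def cd_update_normal(k, beta2, data, lambda2, omega2k) -> float:
    """One coordinate update of the penalized least-squares problem:

        b_k <- S(2 sum_i I(y=1) z_ik (x_i - z_i(-k)' b_(-k)), lam*omega_k)
               / (2 sum_i I(y=1) z_ik^2),

    with the lambda term dropped for the intercept (k = 0).
    """
    beta2 = _check_dim("beta2", beta2, data.Z2)
    Zp, xp = _positive_design(data)
    zk = Zp[:, k]
    partial = xp - Zp @ beta2 + zk * beta2[k]
    denom = 2.0 * np.sum(zk * zk)
    thr = 0.0 if k == 0 else lambda2 * omega2k
    return soft_threshold(2.0 * float(zk @ partial), thr) / denom


def fit_cd_normal(
    data: SemicontinuousDataset,
    lambda2: float,
    omega2=None,
    tol: float = TOL_INNER,
    max_iter: int = MAX_INNER,
    beta0=None,
) -> PartFit:
    """Coordinate-descent solution of the penalized normal part."""
    Zp, xp = _positive_design(data)
    pen = _pen_vector(omega2, data.q2)
    b0 = np.zeros(Zp.shape[1]) if beta0 is None else np.asarray(beta0, float)
    betas, sweeps, conv = _cd.cd_normal_path(
        np.ascontiguousarray(Zp.T), xp,
        np.array([float(lambda2)]), pen, b0, tol, max_iter,
    )
    if not conv[0]:
        raise ConvergenceError(
            f"normal-part coordinate descent did not converge in "
            f"{max_iter} sweeps (lambda2={lambda2:g})"
        )
    beta = betas[0]
    return PartFit(
        beta=beta,
        lambda_=float(lambda2),
        active_set=_active_set(beta),
        n_outer=1,
        n_inner=int(sweeps[0]),
        converged=True,
    )


def sigma_from_beta2(data: SemicontinuousDataset, beta2) -> float:
    """ML scale from the nonzero-row residuals of a (penalized) beta2;
    sigma itself is never penalized."""
    Zp, xp = _positive_design(data)
    r = xp - Zp @ np.asarray(beta2, float)
    return float(np.sqrt(np.mean(r * r)))


# --------------------------------------------------------------------------
# binomial (logistic) part
# --------------------------------------------------------------------------

def irls_quadratic(beta1_old, data: SemicontinuousDataset) -> IRLSState:
    """Work response and weights of the quadratic expansion at beta1_old:

        gamma_i = z_i' b_old + (y_i - p_i) / (p_i (1 - p_i)),
        w_i     = p_i (1 - p_i),

    with the weights floored at 1e-5 for conditioning.
    """
    beta1_old = _check_dim("beta1", beta1_old, data.Z1)
    eta = data.Z1 @ beta1_old
    p = expit(clamp_eta(eta))
    w = np.maximum(p * (1.0 - p), W_FLOOR)
    gamma = eta + (data.y - p) / w
    return IRLSState(gamma=gamma, w=w, beta1_old=beta1_old.copy())


def cd_update_logistic(k, beta1, state: IRLSState, data, lambda1, omega1k) -> float:
    """One coordinate update of the penalized weighted least squares:

        b_k <- S(2 sum_i w_i z_ik (gamma_i - z_i(-k)' b_(-k)), lam*omega_k)
               / (2 sum_i w_i z_ik^2).

    The denominator includes w_i — the curvature of the weighted
    quadratic in coordinate k.
    """
    beta1 = _check_dim("beta1", beta1, data.Z1)
    zk = data.Z1[:, k]
    w = state.w
    denom = 2.0 * np.sum(w * zk * zk)
    if denom <= 0:
        raise DegenerateDataError(
            f"covariate column {k} of Z1 is degenerate on the weighted design"
        )
    partial = state.gamma - data.Z1 @ beta1 + zk * beta1[k]
    thr = 0.0 if k == 0 else lambda1 * omega1k
    return soft_threshold(2.0 * float(np.sum(w * zk * partial)), thr) / denom


def fit_cd_logistic(
    data: SemicontinuousDataset,
    lambda1: float,
    omega1=None,
    tol_inner: float = TOL_INNER,
    tol_outer: float = TOL_OUTER,
    max_outer: int = MAX_OUTER,
    max_inner: int = MAX_INNER,
    beta0=None,
) -> PartFit:
    """Nested IRLS + coordinate-descent solution of the penalized
    logistic part."""
    data.require_both_classes()
    pen = _pen_vector(omega1, data.q1)
    p = data.Z1.shape[1]
    b0 = np.zeros(p) if beta0 is None else np.asarray(beta0, float)
    betas, outer, inner, conv = _cd.cd_logistic_path(
        np.ascontiguousarray(data.Z1.T), data.y.astype(float),
        np.array([float(lambda1)]), pen, b0,
        tol_inner, tol_outer, max_outer, max_inner, W_FLOOR,
    )
    if not conv[0]:
        raise ConvergenceError(
            f"binomial-part IRLS/coordinate descent did not converge "
            f"(lambda1={lambda1:g})"
        )
    beta = betas[0]
    return PartFit(
        beta=beta,
        lambda_=float(lambda1),
        active_set=_active_set(beta),
        n_outer=int(outer[0]),
        n_inner=int(inner[0]),
        converged=True,
    )


# --------------------------------------------------------------------------
# weights, paths, objectives
# --------------------------------------------------------------------------

def adaptive_weights(data: SemicontinuousDataset, cap: float = WEIGHT_CAP):
    """omega_j = 1/|beta_j_ml| for the non-intercept coefficients of both
    parts, capped at ``cap`` when |beta_j_ml| is numerically zero."""
    beta1, _ = fit_mle_binomial(data)
    beta2, _sigma, _ = fit_mle_continuous(data)
    omega1 = np.minimum(1.0 / np.maximum(np.abs(beta1[1:]), 1.0 / cap), cap)
    omega2 = np.minimum(1.0 / np.maximum(np.abs(beta2[1:]), 1.0 / cap), cap)
    return omega1, omega2


def lambda_max_normal(data: SemicontinuousDataset, omega2=None) -> float:
    """Smallest lambda2 shrinking every penalized coefficient to zero."""
    Zp, xp = _positive_design(data)
    pen = _pen_vector(omega2, data.q2)
    r = xp - np.mean(xp)
    grad = 2.0 * np.abs(Zp[:, 1:].T @ r)
    return float(np.max(grad / pen[1:]))


def lambda_max_logistic(data: SemicontinuousDataset, omega1=None) -> float:
    """Smallest lambda1 shrinking every penalized coefficient to zero,
    evaluated at the intercept-only fit (where the IRLS weights are
    constant and the working residual reduces to y - ybar)."""
    data.require_both_classes()
    pen = _pen_vector(omega1, data.q1)
    r = data.y - data.y.mean()
    grad = 2.0 * np.abs(data.Z1[:, 1:].T @ r)
    return float(np.max(grad / pen[1:]))


def lambda_grid(
    lambda_max: float,
    n_lambdas: int = N_LAMBDAS,
    min_ratio: float = LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Descending log-spaced grid from lambda_max to min_ratio*lambda_max."""
    if lambda_max <= 0:
        raise DataError(f"lambda_max must be positive, got {lambda_max}")
    return np.geomspace(lambda_max, lambda_max * min_ratio, n_lambdas)


def path_normal(
    data, lambdas, omega2=None, tol=TOL_INNER, max_iter=MAX_INNER, beta0=None
) -> np.ndarray:
    """Warm-started coefficient path of the normal part (rows follow
    ``lambdas``, which should be descending)."""
    Zp, xp = _positive_design(data)
    pen = _pen_vector(omega2, data.q2)
    b0 = np.zeros(Zp.shape[1]) if beta0 is None else np.asarray(beta0, float)
    betas, _sweeps, conv = _cd.cd_normal_path(
        np.ascontiguousarray(Zp.T), xp,
        np.asarray(lambdas, float), pen, b0, tol, max_iter,
    )
    if not conv.all():
        bad = np.flatnonzero(conv == 0)[0]
        raise ConvergenceError(
            f"normal-part path failed to converge at lambda={lambdas[bad]:g}"
        )
    return betas


def path_logistic(
    data, lambdas, omega1=None,
    tol_inner=TOL_INNER, tol_outer=TOL_OUTER,
    max_outer=MAX_OUTER, max_inner=MAX_INNER, beta0=None,
) -> np.ndarray:
    """Warm-started coefficient path of the binomial part."""
    data.require_both_classes()
    pen = _pen_vector(omega1, data.q1)
    p = data.Z1.shape[1]
    b0 = np.zeros(p) if beta0 is None else np.asarray(beta0, float)
    betas, _outer, _inner, conv = _cd.cd_logistic_path(
        np.ascontiguousarray(data.Z1.T), data.y.astype(float),
        np.asarray(lambdas, float), pen, b0,
        tol_inner, tol_outer, max_outer, max_inner, W_FLOOR,
    )
    if not conv.all():
        bad = np.flatnonzero(conv == 0)[0]
        raise ConvergenceError(
            f"binomial-part path failed to converge at lambda={lambdas[bad]:g}"
        )
    return betas


def objective_normal(beta2, data, lambda2, omega2=None) -> float:
    """sum_i I(y=1)(x_i - z_i'b)^2 + lambda2 sum_s omega_s |b_s|."""
    Zp, xp = _positive_design(data)
    beta2 = _check_dim("beta2", beta2, data.Z2)
    pen = _pen_vector(omega2, data.q2)
    r = xp - Zp @ beta2
    return float(np.sum(r * r) + lambda2 * np.sum(pen * np.abs(beta2)))


def objective_logistic(beta1, data, lambda1, omega1=None) -> float:
    """-2*l1(b) + lambda1 sum_j omega_j |b_j|.

    The deviance (-2 log-likelihood) scale matches the weighted
    least-squares form of the IRLS quadratic, sum_i w_i (gamma_i - z'b)^2,
    so the coordinate updates minimize exactly this objective — mirroring
    the normal part, whose sum-of-squares objective is likewise the
    deviance of its likelihood up to constants.
    """
    beta1 = _check_dim("beta1", beta1, data.Z1)
    pen = _pen_vector(omega1, data.q1)
    return float(
        -2.0 * loglik_binomial(beta1, data)
        + lambda1 * np.sum(pen * np.abs(beta1))
    )


def fit_penalized(
    data: SemicontinuousDataset,
    spec: PenaltySpec,
    tol_inner: float = TOL_INNER,
    tol_outer: float = TOL_OUTER,
) -> PenalizedFit:
    """Fit both penalized parts at the spec's (lambda1, lambda2).

    The two sub-problems are independent: changing lambda1 never affects
    beta2 and vice versa.
    """
    data.require_both_classes()
    omega1, omega2 = spec.resolve_weights(data)
    f1 = fit_cd_logistic(
        data, spec.lambda1, omega1, tol_inner=tol_inner, tol_outer=tol_outer
    )
    f2 = fit_cd_normal(data, spec.lambda2, omega2, tol=tol_inner)
    return PenalizedFit(
        beta1=f1.beta,
        beta2=f2.beta,
        sigma=sigma_from_beta2(data, f2.beta),
        lambda1=float(spec.lambda1),
        lambda2=float(spec.lambda2),
        active_set1=f1.active_set,
        active_set2=f2.active_set,
        n_outer=f1.n_outer,
        n_inner=f1.n_inner + f2.n_inner,
        converged=f1.converged and f2.converged,
    )
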