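"""The Bernoulli-Normal two-part (BNT) model and its log-likelihood.

The outcome density is

    f(x_i) = (1 - pi_i)^(1 - y_i) * [pi_i N(x_i; mu_i, sigma^2)]^(y_i),

with logit(pi_i) = z1_i' beta1 and mu_i = E[X_i | X_i > 0] = z2_i' beta2.
The log-likelihood decomposes additively into a logistic-regression part
l1(beta1) and a normal-regression part l2(beta2, sigma) over the nonzero
rows only; everything downstream (Newton fitting, penalized selection)
maximizes the two parts independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data import SemicontinuousDataset
from .exceptions import DataError, DimensionError

__all__ = [
    "ETA_CLAMP",
    "BNTParameters",
    "LinkValues",
    "clamp_eta",
    "links",
    "loglik_binomial",
    "loglik_continuous",
    "loglik_total",
    "predict_expected",
]

# Linear predictors are clamped before exponentiation: beyond |eta| = 30
# pi differs from 0/1 by < 1e-13, so this is numerically inert.
ETA_CLAMP = 30.0

_LOG_2PI = float(np.log(2.0 * np.pi))


def clamp_eta(eta: np.ndarray) -> np.ndarray:
    return np.clip(eta, -ETA_CLAMP, ETA_CLAMP)


@dataclass
class BNTParameters:
    """Coefficients of both parts plus the continuous-part scale."""

    beta1: np.ndarray
    beta2: np.ndarray
    sigma: float

    def __post_init__(self):
        self.beta1 = np.asarray(self.beta1, dtype=float).ravel()
        self.beta2 = np.asarray(self.beta2, dtype=float).ravel()
        self.sigma = float(self.sigma)
        if self.sigma <= 0:
            raise DataError(f"sigma must be positive, got {self.sigma}")


@dataclass
class LinkValues:
    """Linear predictors and their inverse-link values."""

    eta1: np.ndarray
    pi: np.ndarray
    mu: np.ndarray


def _check_dim(name: str, beta: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.size != Z.shape[1]:
        raise DimensionError(f"{name} length", Z.shape[1], beta.size)
    return beta


def links(beta1, beta2, Z1, Z2) -> LinkValues:
    beta1 = _check_dim("beta1", beta1, Z1)
    beta2 = _check_dim("beta2", beta2, Z2)
    eta1 = Z1 @ beta1
    return LinkValues(eta1=eta1, pi=expit(clamp_eta(eta1)), mu=Z2 @ beta2)


def loglik_binomial(beta1, data: SemicontinuousDataset) -> float:
    """Binomial-part log-likelihood l1(beta1) = sum y eta - ln(1 + e^eta)."""
    beta1 = _check_dim("beta1", beta1, data.Z1)
    eta = clamp_eta(data.Z1 @ beta1)
    return float(np.sum(data.y * eta - np.logaddexp(0.0, eta)))


def loglik_continuous(beta2, sigma, data: SemicontinuousDataset) -> float:
    """Continuous-part log-likelihood over nonzero rows only.

    Rows with a zero outcome contribute exactly 0, whatever ``beta2`` and
    ``sigma`` are.
    """
    beta2 = _check_dim("beta2", beta2, data.Z2)
    sigma = float(sigma)
    if sigma <= 0:
        raise DataError(f"sigma must be positive, got {sigma}")
    pos = data.positive
    if not pos.any():
        return 0.0
    r = data.x[pos] - data.Z2[pos] @ beta2
    npos = r.size
    return float(
        -0.5 * np.sum(r * r) / sigma**2 - npos * np.log(sigma) - 0.5 * npos * _LOG_2PI
    )


def loglik_total(params: BNTParameters, data: SemicontinuousDataset) -> float:
    """l(theta) = l1(beta1) + l2(beta2, sigma)."""
    return loglik_binomial(params.beta1, data) + loglik_continuous(
        params.beta2, params.sigma, data
    )


def predict_expected(params: BNTParameters, Z1, Z2) -> np.ndarray:
    """Expected outcome xhat_i = pi_i * mu_i of the two-part model."""
    Z1 = np.asarray(Z1, dtype=float)
    Z2 = np.asarray(Z2, dtype=float)
    if Z1.shape[0] != Z2.shape[0]:
        raise DimensionError("Z1/Z2 row counts", Z1.shape[0], Z2.shape[0])
    beta1 = _check_dim("beta1", params.beta1, Z1)
    beta2 = _check_dim("beta2", params.beta2, Z2)
    return expit(clamp_eta(Z1 @ beta1)) * (Z2 @ beta2)
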