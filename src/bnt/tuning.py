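"""K-fold cross-validation tuning of the penalty parameters.

lambda1 and lambda2 are tuned separately, each with its own part-specific
held-out loss: mean binomial deviance on the nonzero indicator for
lambda1, mean squared error on the held-out nonzero outcomes for lambda2.
A joint mode scoring (x_i - pi_i*mu_i)^2 on a 2-D grid is also provided.
The grid minimizer is selected by default; a 1-SE rule is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data import SemicontinuousDataset
from .exceptions import DataError, DegenerateDataError
from .model import clamp_eta
from . import penalized as pen

__all__ = ["CVResult", "make_folds", "cv_error", "select_lambda", "select_lambda_joint"]

_PROB_EPS = 1e-12


@dataclass
class CVResult:
    """Cross-validation curve and the selected tuning parameter."""

    lambda_grid: np.ndarray
    cv_errors: np.ndarray
    cv_se: np.ndarray
    lambda_selected: float
    fold_assignment: np.ndarray
    K: int


def make_folds(n: int, K: int, seed) -> np.ndarray:
    """Random partition of ``range(n)`` into K near-equal folds.

    ``seed`` may be an int or a ``numpy.random.Generator``; the same
    (n, K, seed) always yields the same assignment.
    """
    if K < 2:
        raise DataError(f"K must be at least 2, got {K}")
    if K > n:
        raise DataError(f"cannot split n={n} rows into K={K} folds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=np.int64)
    sizes = np.full(K, n // K)
    sizes[: n % K] += 1
    start = 0
    for j, sz in enumerate(sizes):
        assignment[perm[start:start + sz]] = j
        start += sz
    return assignment


def _check_training_split(train: SemicontinuousDataset, fold: int) -> None:
    if not train.both_classes_present():
        raise DegenerateDataError(
            f"training split for fold {fold} contains a single outcome "
            "class; use fewer folds or a different fold seed"
        )


def _deviance(y, pi) -> np.ndarray:
    pi = np.clip(pi, _PROB_EPS, 1.0 - _PROB_EPS)
    return -2.0 * (y * np.log(pi) + (1 - y) * np.log(1.0 - pi))


def _fold_error_matrix(data, part, grid, folds, omega):
    """Per-fold held-out error for every lambda in ``grid``.

    Returns an array of shape (K, len(grid)); folds without scorable
    held-out rows (no nonzero outcomes, normal part) are NaN.
    """
    K = int(folds.max()) + 1
    grid = np.asarray(grid, dtype=float)
    errors = np.full((K, grid.size), np.nan)
    for j in range(K):
        hold = folds == j
        train = data.subset(~hold)
        _check_training_split(train, j)
        if part == "binomial":
            betas = pen.path_logistic(train, grid, omega)
            eta = data.Z1[hold] @ betas.T
            piv = expit(clamp_eta(eta))
            dev = _deviance(data.y[hold][:, None], piv)
            errors[j] = dev.mean(axis=0)
        elif part == "normal":
            betas = pen.path_normal(train, grid, omega)
            mask = hold & (data.y == 1)
            if not mask.any():
                continue
            mu = data.Z2[mask] @ betas.T
            res = data.x[mask][:, None] - mu
            errors[j] = np.mean(res * res, axis=0)
        else:
            raise DataError(f"unknown part {part!r}")
    return errors


def cv_error(data, part, lambda_, folds, omega=None):
    """Mean and per-fold held-out error at a single lambda."""
    errors = _fold_error_matrix(data, part, [float(lambda_)], np.asarray(folds), omega)
    per_fold = errors[:, 0]
    return float(np.nanmean(per_fold)), per_fold


def select_lambda(
    data: SemicontinuousDataset,
    part: str,
    folds,
    omega=None,
    grid=None,
    rule: str = "min",
    n_lambdas: int = pen.N_LAMBDAS,
    lambda_min_ratio: float = pen.LAMBDA_MIN_RATIO,
) -> CVResult:
    """Tune one part's lambda over a (default full-data) grid by K-fold CV.

    ``rule='min'`` picks the grid minimizer (ties broken toward the larger
    lambda); ``rule='1se'`` picks the largest lambda whose CV error is
    within one standard error of the minimum.
    """
    folds = np.asarray(folds, dtype=np.int64)
    if folds.size != data.n:
        raise DataError("fold assignment length must equal n")
    if grid is None:
        lmax = (
            pen.lambda_max_logistic(data, omega)
            if part == "binomial"
            else pen.lambda_max_normal(data, omega)
        )
        grid = pen.lambda_grid(lmax, n_lambdas, lambda_min_ratio)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DataError("empty lambda grid")
    if grid.size > 1 and np.any(np.diff(grid) > 0):
        grid = np.sort(grid)[::-1]
    errors = _fold_error_matrix(data, part, grid, folds, omega)
    K = errors.shape[0]
    cv = np.nanmean(errors, axis=0)
    valid = np.sum(~np.isnan(errors), axis=0)
    with np.errstate(invalid="ignore"):
        cv_se = np.nanstd(errors, axis=0, ddof=1) / np.sqrt(np.maximum(valid, 1))
    idx = int(np.nanargmin(cv))  # first occurrence = larger lambda (grid descending)
    if rule == "1se":
        thresh = cv[idx] + cv_se[idx]
        idx = int(np.flatnonzero(cv <= thresh)[0])
    elif rule != "min":
        raise DataError(f"unknown selection rule {rule!r}")
    return CVResult(
        lambda_grid=grid,
        cv_errors=cv,
        cv_se=cv_se,
        lambda_selected=float(grid[idx]),
        fold_assignment=folds,
        K=K,
    )


def select_lambda_joint(
    data: SemicontinuousDataset,
    folds,
    omega1=None,
    omega2=None,
    grid1=None,
    grid2=None,
    n_lambdas: int = pen.N_LAMBDAS,
    lambda_min_ratio: float = pen.LAMBDA_MIN_RATIO,
):
    """Joint 2-D tuning with the combined loss (x_i - pi_i*mu_i)^2.

    Because the two parts are fit independently, the held-out predictions
    factor into pi(lambda1) and mu(lambda2), so the full error surface
    costs one path fit per part per fold.  Returns
    ``(lambda1, lambda2, surface, grid1, grid2)``.
    """
    folds = np.asarray(folds, dtype=np.int64)
    if grid1 is None:
        grid1 = pen.lambda_grid(
            pen.lambda_max_logistic(data, omega1), n_lambdas, lambda_min_ratio
        )
    if grid2 is None:
        grid2 = pen.lambda_grid(
            pen.lambda_max_normal(data, omega2), n_lambdas, lambda_min_ratio
        )
    grid1 = np.asarray(grid1, float)
    grid2 = np.asarray(grid2, float)
    K = int(folds.max()) + 1
    surface = np.zeros((grid1.size, grid2.size))
    for j in range(K):
        hold = folds == j
        train = data.subset(~hold)
        _check_training_split(train, j)
        b1 = pen.path_logistic(train, grid1, omega1)
        b2 = pen.path_normal(train, grid2, omega2)
        piv = expit(clamp_eta(data.Z1[hold] @ b1.T))      # (m, L1)
        mu = data.Z2[hold] @ b2.T                          # (m, L2)
        x = data.x[hold]
        err = (
            x[:, None, None] - piv[:, :, None] * mu[:, None, :]
        ) ** 2
        surface += err.mean(axis=0)
    surface /= K
    a, b = np.unravel_index(int(np.argmin(surface)), surface.shape)
    return float(grid1[a]), float(grid2[b]), surface, grid1, grid2
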