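"""scikit-learn style estimators for the two-part model.

``BNTRegression`` fits the unpenalized maximum-likelihood model;
``PenalizedBNTRegression`` adds Lasso / adaptive-Lasso selection with
optional per-part K-fold cross-validation of the tuning parameters.
Both take the raw covariate matrix ``X`` (no intercept column — one is
added internally, and the same covariates serve both parts) and the
semicontinuous outcome as ``y``; ``predict`` returns the expected
outcome pi_hat * mu_hat.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data import SemicontinuousDataset
from .exceptions import DataError
from .mle import fit_mle_binomial, fit_mle_continuous
from .model import clamp_eta, loglik_binomial, loglik_continuous
from . import penalized as pen
from . import tuning

__all__ = ["BNTRegression", "PenalizedBNTRegression"]


class _TwoPartPredictMixin:
    """Prediction helpers shared by both estimators."""

    def _design(self, X):
        check_is_fitted(self, "sigma_")
        X = check_array(X, dtype=float, ensure_min_features=0)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return np.hstack([np.ones((X.shape[0], 1)), X])

    def predict_nonzero_proba(self, X):
        """Probability pi_hat that the outcome is nonzero."""
        Z = self._design(X)
        eta = Z @ np.concatenate([[self.intercept_binomial_], self.coef_binomial_])
        return expit(clamp_eta(eta))

    def predict_positive_mean(self, X):
        """Conditional mean mu_hat = E[X | X nonzero]."""
        Z = self._design(X)
        return Z @ np.concatenate([[self.intercept_normal_], self.coef_normal_])

    def predict(self, X):
        """Expected outcome pi_hat * mu_hat."""
        return self.predict_nonzero_proba(X) * self.predict_positive_mean(X)

    def _beta1(self):
        return np.concatenate([[self.intercept_binomial_], self.coef_binomial_])

    def _beta2(self):
        return np.concatenate([[self.intercept_normal_], self.coef_normal_])

    def _dataset(self, X, y, indicator):
        X = check_array(X, dtype=float, ensure_min_features=0)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != X.shape[0]:
            raise DataError(
                f"outcome length {y.size} does not match n={X.shape[0]}"
            )
        ds = SemicontinuousDataset.from_covariates(
            y, X, y=indicator, log_positives=self.log_positives
        )
        self.n_features_in_ = X.shape[1]
        return ds


class BNTRegression(_TwoPartPredictMixin, RegressorMixin, BaseEstimator):
    """Unpenalized maximum-likelihood Bernoulli-Normal two-part regression.

    Parameters
    ----------
    log_positives : bool, default False
        Apply the customary log transform to the nonzero outcomes once at
        fit time (skewed real data); off for data already on a normal scale.
    tol, max_iter
        Newton convergence controls for the binomial part.

    Attributes
    ----------
    coef_binomial_, intercept_binomial_ : logistic-part coefficients.
    coef_normal_, intercept_normal_ : continuous-part coefficients.
    sigma_ : ML scale of the continuous part.
    loglik_ : maximized total log-likelihood.
    """

    def __init__(self, log_positives: bool = False, tol: float = 1e-8,
                 max_iter: int = 100):
        self.log_positives = log_positives
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, indicator=None):
        ds = self._dataset(X, y, indicator)
        beta1, trace1 = fit_mle_binomial(ds, tol=self.tol, max_iter=self.max_iter)
        beta2, sigma, trace2 = fit_mle_continuous(ds)
        self.intercept_binomial_ = float(beta1[0])
        self.coef_binomial_ = beta1[1:]
        self.intercept_normal_ = float(beta2[0])
        self.coef_normal_ = beta2[1:]
        self.sigma_ = sigma
        self.loglik_ = loglik_binomial(beta1, ds) + loglik_continuous(
            beta2, sigma, ds
        )
        self.n_iter_ = trace1.n_iter
        self.trace_binomial_ = trace1
        self.trace_normal_ = trace2
        return self


class PenalizedBNTRegression(_TwoPartPredictMixin, RegressorMixin, BaseEstimator):
    """Lasso / adaptive-Lasso penalized two-part regression.

    With ``lambda1``/``lambda2`` left as ``None`` the tuning parameters
    are chosen by K-fold cross-validation on a 100-point descending
    log-grid per part (deviance loss for the binomial part, squared error
    on nonzero rows for the normal part; ``cv_joint=True`` switches to a
    2-D grid under the combined squared-error loss).

    Parameters
    ----------
    penalty : {'alasso', 'lasso'}
        Adaptive Lasso uses weights 1/|beta_ml| from the unpenalized fit
        (capped at ``weight_cap``); the Lasso is the unit-weight special
        case.
    standardize : bool, default False
        Scale covariates to unit variance for fitting and report
        coefficients on the original scale.  Off by default — simulated
        covariates are variance-1 by construction.
    random_state : int or None
        Seed for the fold assignment; independent of any data generation.

    Attributes
    ----------
    coef_binomial_, coef_normal_ : penalized coefficients (exact zeros
        for excluded covariates), plus ``intercept_*_`` and ``sigma_``.
    lambda1_, lambda2_ : penalties actually used.
    active_binomial_, active_normal_ : 1-based indices of retained
        coefficients (positions in the full coefficient vector).
    cv_binomial_, cv_normal_ : ``CVResult`` curves when CV ran.
    """

    def __init__(
        self,
        penalty: str = "alasso",
        lambda1=None,
        lambda2=None,
        cv: int = 10,
        cv_rule: str = "min",
        cv_joint: bool = False,
        n_lambdas: int = pen.N_LAMBDAS,
        lambda_min_ratio: float = pen.LAMBDA_MIN_RATIO,
        log_positives: bool = False,
        standardize: bool = False,
        weight_cap: float = pen.WEIGHT_CAP,
        random_state=None,
    ):
        self.penalty = penalty
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.cv = cv
        self.cv_rule = cv_rule
        self.cv_joint = cv_joint
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.log_positives = log_positives
        self.standardize = standardize
        self.weight_cap = weight_cap
        self.random_state = random_state

    def fit(self, X, y, indicator=None):
        if self.penalty not in ("lasso", "alasso"):
            raise DataError(f"unknown penalty {self.penalty!r}")
        X = check_array(X, dtype=float, ensure_min_features=0)
        scale = np.ones(X.shape[1])
        if self.standardize:
            scale = X.std(axis=0)
            if np.any(scale == 0):
                raise DataError("constant covariate cannot be standardized")
            X = X / scale
        ds = self._dataset(X, y, indicator)
        ds.require_both_classes()

        if self.penalty == "alasso":
            omega1, omega2 = pen.adaptive_weights(ds, cap=self.weight_cap)
        else:
            omega1, omega2 = np.ones(ds.q1), np.ones(ds.q2)
        self.omega1_, self.omega2_ = omega1, omega2

        lam1, lam2 = self.lambda1, self.lambda2
        self.cv_binomial_ = None
        self.cv_normal_ = None
        if lam1 is None or lam2 is None:
            folds = tuning.make_folds(ds.n, self.cv, self.random_state)
            if self.cv_joint:
                j1, j2, _surface, _g1, _g2 = tuning.select_lambda_joint(
                    ds, folds, omega1, omega2,
                    n_lambdas=self.n_lambdas,
                    lambda_min_ratio=self.lambda_min_ratio,
                )
                lam1 = j1 if lam1 is None else lam1
                lam2 = j2 if lam2 is None else lam2
            else:
                if lam1 is None:
                    self.cv_binomial_ = tuning.select_lambda(
                        ds, "binomial", folds, omega1,
                        rule=self.cv_rule,
                        n_lambdas=self.n_lambdas,
                        lambda_min_ratio=self.lambda_min_ratio,
                    )
                    lam1 = self.cv_binomial_.lambda_selected
                if lam2 is None:
                    self.cv_normal_ = tuning.select_lambda(
                        ds, "normal", folds, omega2,
                        rule=self.cv_rule,
                        n_lambdas=self.n_lambdas,
                        lambda_min_ratio=self.lambda_min_ratio,
                    )
                    lam2 = self.cv_normal_.lambda_selected

        spec = pen.PenaltySpec(
            method=self.penalty, lambda1=lam1, lambda2=lam2,
            omega1=None if self.penalty == "lasso" else omega1,
            omega2=None if self.penalty == "lasso" else omega2,
        )
        fit = pen.fit_penalized(ds, spec)

        # report on the original covariate scale
        beta1 = fit.beta1.copy()
        beta2 = fit.beta2.copy()
        beta1[1:] /= scale
        beta2[1:] /= scale
        self.intercept_binomial_ = float(beta1[0])
        self.coef_binomial_ = beta1[1:]
        self.intercept_normal_ = float(beta2[0])
        self.coef_normal_ = beta2[1:]
        self.sigma_ = fit.sigma
        self.lambda1_ = fit.lambda1
        self.lambda2_ = fit.lambda2
        self.active_binomial_ = fit.active_set1
        self.active_normal_ = fit.active_set2
        self.converged_ = fit.converged
        if self.standardize:
            # undo the scaling applied inside _dataset's stored design
            self._fit_scale_ = scale
        return self
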