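"""JSON round-tripping of fitted models.

Fit files embed the estimator parameters (including any seeds) that
produced them; reloading reconstructs an estimator whose predictions are
bitwise identical.
"""

from __future__ import annotations

import json

import numpy as np

from .estimators import BNTRegression, PenalizedBNTRegression
from .exceptions import DataError

__all__ = ["fit_to_dict", "fit_from_dict", "save_fit", "load_fit"]

_FITTED_FIELDS = (
    "intercept_binomial_",
    "coef_binomial_",
    "intercept_normal_",
    "coef_normal_",
    "sigma_",
    "n_features_in_",
    "loglik_",
    "lambda1_",
    "lambda2_",
    "active_binomial_",
    "active_normal_",
    "converged_",
)

_CLASSES = {
    "BNTRegression": BNTRegression,
    "PenalizedBNTRegression": PenalizedBNTRegression,
}


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer, np.floating, np.bool_)):
        return v.item()
    return v


def fit_to_dict(est) -> dict:
    d = {
        "class": type(est).__name__,
        "params": {k: _jsonable(v) for k, v in est.get_params().items()},
        "fitted": {},
    }
    for f in _FITTED_FIELDS:
        if hasattr(est, f):
            d["fitted"][f] = _jsonable(getattr(est, f))
    return d


def fit_from_dict(d: dict):
    try:
        cls = _CLASSES[d["class"]]
    except KeyError as exc:
        raise DataError(f"unknown estimator class in fit file: {exc}") from exc
    est = cls(**d["params"])
    for f, v in d["fitted"].items():
        if f in ("coef_binomial_", "coef_normal_"):
            v = np.asarray(v, dtype=float)
        elif f in ("active_binomial_", "active_normal_"):
            v = np.asarray(v, dtype=np.int64)
        setattr(est, f, v)
    return est


def save_fit(est, path, extra: dict | None = None) -> None:
    d = fit_to_dict(est)
    if extra:
        d["config"] = {k: _jsonable(v) for k, v in extra.items()}
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)


def load_fit(path):
    with open(path) as fh:
        return fit_from_dict(json.load(fh))
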