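"""Containers and I/O for semicontinuous outcome data.

A semicontinuous outcome is non-negative with a point mass at zero and a
continuous distribution on the nonzero values.  The two-part model works
with the outcome vector ``x``, the nonzero indicator ``y`` and two design
matrices: ``Z1`` for the binary (zero vs nonzero) part and ``Z2`` for the
continuous part.  Both design matrices carry an explicit leading intercept
column, so ``q1``/``q2`` always count non-intercept covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, DegenerateDataError, DimensionError

__all__ = ["SemicontinuousDataset", "add_intercept", "load_csv"]


def add_intercept(C) -> np.ndarray:
    """Prepend a column of ones to a covariate matrix."""
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.ndim != 2:
        raise DimensionError("covariate matrix", "2-d array", f"{C.ndim}-d")
    return np.hstack([np.ones((C.shape[0], 1)), C])


@dataclass
class SemicontinuousDataset:
    """Outcome, nonzero indicator and the two design matrices.

    Parameters
    ----------
    x : array of shape (n,)
        Semicontinuous outcome.
    y : array of shape (n,)
        Binary indicator of a nonzero outcome.  ``y == 0`` rows must have
        ``x == 0``.
    Z1, Z2 : arrays of shape (n, q1 + 1) and (n, q2 + 1)
        Design matrices for the binary and continuous parts; first column
        must be identically one.
    """

    x: np.ndarray
    y: np.ndarray
    Z1: np.ndarray
    Z2: np.ndarray
    outcome_name: str | None = field(default=None, compare=False)
    columns1: list | None = field(default=None, compare=False)
    columns2: list | None = field(default=None, compare=False)

    def __post_init__(self):
        self.x = np.ascontiguousarray(self.x, dtype=float).ravel()
        self.y = np.ascontiguousarray(self.y, dtype=np.int64).ravel()
        self.Z1 = np.ascontiguousarray(self.Z1, dtype=float)
        self.Z2 = np.ascontiguousarray(self.Z2, dtype=float)
        n = self.x.size
        if self.y.size != n:
            raise DimensionError("indicator length", n, self.y.size)
        for name, Z in (("Z1", self.Z1), ("Z2", self.Z2)):
            if Z.ndim != 2:
                raise DimensionError(name, "2-d array", f"{Z.ndim}-d")
            if Z.shape[0] != n:
                raise DimensionError(f"{name} row count", n, Z.shape[0])
            if not np.all(Z[:, 0] == 1.0):
                raise DataError(f"first column of {name} must be identically 1")
            if not np.all(np.isfinite(Z)):
                raise DataError(f"{name} contains non-finite values")
        if not np.all(np.isfinite(self.x)):
            raise DataError("outcome contains non-finite values")
        if not np.isin(self.y, (0, 1)).all():
            raise DataError("indicator must be binary (0/1)")
        bad = np.flatnonzero((self.y == 0) & (self.x != 0.0))
        if bad.size:
            raise DataError(
                f"rows {bad[:5].tolist()} have y=0 but a nonzero outcome"
            )
        bad = np.flatnonzero((self.y == 1) & (self.x == 0.0))
        if bad.size:
            raise DataError(
                f"rows {bad[:5].tolist()} have y=1 but a zero outcome"
            )

    # -- shape helpers ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.x.size

    @property
    def q1(self) -> int:
        return self.Z1.shape[1] - 1

    @property
    def q2(self) -> int:
        return self.Z2.shape[1] - 1

    @property
    def positive(self) -> np.ndarray:
        """Boolean mask of nonzero-outcome rows."""
        return self.y == 1

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    def both_classes_present(self) -> bool:
        return 0 < self.n_pos < self.n

    def require_both_classes(self) -> None:
        """The joint model assumes pi strictly inside (0, 1)."""
        if not self.both_classes_present():
            raise DegenerateDataError(
                "outcome must contain both zero and nonzero values "
                "(the mixing proportion is assumed strictly inside (0,1))"
            )

    def subset(self, idx) -> "SemicontinuousDataset":
        """Row subset (used for cross-validation splits)."""
        return SemicontinuousDataset(
            self.x[idx], self.y[idx], self.Z1[idx], self.Z2[idx]
        )

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_covariates(
        cls,
        x,
        C1,
        C2=None,
        y=None,
        log_positives: bool = False,
        outcome_name=None,
        columns1=None,
        columns2=None,
    ) -> "SemicontinuousDataset":
        """Build a dataset from raw covariates (intercept added here).

        If ``y`` is omitted the outcome must be non-negative and the
        indicator is derived as ``x != 0``.  An explicit ``y`` permits the
        simulation generator's convention where the nonzero event comes
        from the Bernoulli draw rather than the sign of ``x``.

        ``log_positives`` applies the customary log transform to the
        nonzero outcomes once, at construction time.
        """
        x = np.asarray(x, dtype=float).ravel()
        if y is None:
            if np.any(x < 0):
                bad = np.flatnonzero(x < 0)
                raise DataError(
                    f"negative outcome values at rows {bad[:5].tolist()}"
                )
            y = (x != 0.0).astype(np.int64)
        else:
            y = np.asarray(y, dtype=np.int64).ravel()
        if log_positives:
            x = x.copy()
            pos = y == 1
            if np.any(x[pos] <= 0):
                raise DataError(
                    "log transform requires strictly positive nonzero outcomes"
                )
            x[pos] = np.log(x[pos])
        Z1 = add_intercept(C1)
        Z2 = Z1 if C2 is None else add_intercept(C2)
        return cls(
            x, y, Z1, Z2,
            outcome_name=outcome_name, columns1=columns1, columns2=columns2,
        )


def load_csv(
    path,
    outcome: str,
    z1_cols=None,
    z2_cols=None,
    log_positives: bool = False,
) -> SemicontinuousDataset:
    """Read a dataset from a headered CSV file.

    ``outcome`` names the semicontinuous outcome column; ``z1_cols`` /
    ``z2_cols`` select covariates for the two parts (default: every
    non-outcome column, same covariates for both parts).  Missing values
    are rejected with a row-indexed error — no imputation is attempted.
    """
    df = pd.read_csv(path)
    if outcome not in df.columns:
        raise DataError(f"outcome column {outcome!r} not found in {path}")
    z1_cols = list(z1_cols) if z1_cols else [c for c in df.columns if c != outcome]
    z2_cols = list(z2_cols) if z2_cols else [c for c in df.columns if c != outcome]
    for cols in (z1_cols, z2_cols):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise DataError(f"covariate columns not found: {missing}")
    used = [outcome] + sorted(set(z1_cols) | set(z2_cols))
    sub = df[used]
    na = sub.isna()
    if na.to_numpy().any():
        rows = na.any(axis=1)
        idx = rows[rows].index[:5].tolist()
        raise DataError(f"missing values at rows {idx}; no imputation is performed")
    try:
        x = sub[outcome].to_numpy(dtype=float)
        C1 = df[z1_cols].to_numpy(dtype=float)
        C2 = df[z2_cols].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric data: {exc}") from exc
    return SemicontinuousDataset.from_covariates(
        x, C1, C2,
        log_positives=log_positives,
        outcome_name=outcome, columns1=z1_cols, columns2=z2_cols,
    )
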