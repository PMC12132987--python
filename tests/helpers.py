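"""Independent numerical oracles used across the test suite.

These deliberately avoid the code paths they check: derivatives come
from central differences, penalized optima from a bound-constrained
smooth reformulation solved by L-BFGS-B, and one-dimensional coordinate
minimizers from brute-force grid search.
"""

import numpy as np
from scipy.optimize import minimize

from bnt.data import SemicontinuousDataset


def num_grad(f, x, h=1e-5):
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def num_hess(f, x, h=1e-4):
    x = np.asarray(x, dtype=float)
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
            H[j, i] = H[i, j]
    return H


def random_dataset(rng, n=30, q=3, pi0=0.55):
    """A small random semicontinuous dataset for oracle comparisons."""
    C = rng.standard_normal((n, q))
    b1 = rng.normal(0, 0.8, q + 1)
    b2 = rng.normal(0, 0.8, q + 1)
    Z = np.hstack([np.ones((n, 1)), C])
    pi = 1 / (1 + np.exp(-(Z @ b1 + np.log(pi0 / (1 - pi0)))))
    y = (rng.random(n) < pi).astype(int)
    if y.sum() < q + 2:  # keep the continuous part well posed
        y[rng.choice(n, q + 2, replace=False)] = 1
    if y.all():
        y[rng.integers(n)] = 0
    x = y * rng.normal(Z @ b2, 1.0)
    x[(y == 1) & (x == 0.0)] = 0.5
    yy = y.copy()
    return SemicontinuousDataset(x * y, yy, Z, Z)


def solve_l1_lbfgsb(f_smooth, grad_smooth, lam, pen, p, x0=None):
    """Generic convex solution of min f(b) + lam * sum_j pen_j |b_j|.

    Splits b = u - v with u, v >= 0, making the objective smooth on a
    box, and solves with L-BFGS-B at tight tolerance.  Returns (beta,
    objective value).
    """
    def obj(uv):
        u, v = uv[:p], uv[p:]
        b = u - v
        return f_smooth(b) + lam * np.sum(pen * (u + v))

    def grad(uv):
        u, v = uv[:p], uv[p:]
        g = grad_smooth(u - v)
        return np.concatenate([g + lam * pen, -g + lam * pen])

    if x0 is None:
        x0 = np.zeros(2 * p)
    res = minimize(
        obj, x0, jac=grad, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p),
        options={"maxiter": 20000, "ftol": 1e-14, "gtol": 1e-10},
    )
    beta = res.x[:p] - res.x[p:]
    return beta, float(res.fun)


def grid_search_1d(f, lo=-5.0, hi=5.0, step=1e-4):
    grid = np.arange(lo, hi + step, step)
    vals = np.array([f(g) for g in grid])
    return float(grid[np.argmin(vals)])
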