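"""JIT-compiled coordinate-descent kernels.

Both kernels fit an entire descending lambda path with warm starts.
``pen`` carries the per-coordinate penalty multiplier (the adaptive
weight, or 1 for the plain Lasso) with ``pen[0] = 0`` so the intercept is
never penalized.  Design matrices are passed transposed (coefficients by
rows) so the per-coordinate inner loops walk contiguous memory.

Validation, warm-start policy and diagnostics live in
:mod:`bnt.penalized`; these functions assume clean inputs.
"""

import numpy as np
from numba import njit

ETA_CLAMP = 30.0


@njit(cache=False)
def _soft(a, b):
    # soft threshold S(a, b) = sign(a) * max(|a| - b, 0)
    if a > b:
        return a - b
    if a < -b:
        return a + b
    return 0.0


@njit(cache=False)
def cd_normal_path(ZT, xp, lambdas, pen, beta0, tol, max_iter):
    """Penalized least squares on the nonzero rows along a lambda path.

    Minimizes sum_i (x_i - z_i' b)^2 + lam * sum_j pen_j |b_j| by cyclic
    coordinate descent with the residual kept up to date.  Returns
    (betas, sweeps, converged) with one row per lambda.
    """
    p, n = ZT.shape
    nlam = lambdas.shape[0]
    betas = np.zeros((nlam, p))
    sweeps = np.zeros(nlam, np.int64)
    conv = np.zeros(nlam, np.uint8)
    beta = beta0.copy()
    s = np.zeros(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += ZT[j, i] * ZT[j, i]
        s[j] = acc
    r = np.zeros(n)
    for l in range(nlam):
        lam = lambdas[l]
        # refresh the residual to stop drift accumulating along the path
        for i in range(n):
            acc = 0.0
            for j in range(p):
                acc += ZT[j, i] * beta[j]
            r[i] = xp[i] - acc
        it = 0
        ok = False
        while it < max_iter:
            it += 1
            maxd = 0.0
            for j in range(p):
                acc = 0.0
                for i in range(n):
                    acc += ZT[j, i] * r[i]
                num = 2.0 * acc + 2.0 * s[j] * beta[j]
                bnew = _soft(num, lam * pen[j]) / (2.0 * s[j])
                d = bnew - beta[j]
                if d != 0.0:
                    for i in range(n):
                        r[i] -= d * ZT[j, i]
                    beta[j] = bnew
                if d < 0.0:
                    d = -d
                if d > maxd:
                    maxd = d
            if maxd < tol:
                ok = True
                break
        for j in range(p):
            betas[l, j] = beta[j]
        sweeps[l] = it
        conv[l] = 1 if ok else 0
    return betas, sweeps, conv


@njit(cache=False)
def _pen_logistic_obj(ZT, y, beta, lam, pen):
    """Penalized logistic deviance -2*l1(b) + lam sum pen |b|.

    The deviance scale matches the weighted least-squares form of the
    IRLS quadratic (sum w (gamma - z'b)^2), whose minimizer this
    iteration seeks, so this is the Lyapunov function of the outer loop.
    """
    p, n = ZT.shape
    nll = 0.0
    for i in range(n):
        eta = 0.0
        for j in range(p):
            eta += ZT[j, i] * beta[j]
        if eta > ETA_CLAMP:
            eta = ETA_CLAMP
        elif eta < -ETA_CLAMP:
            eta = -ETA_CLAMP
        # ln(1 + e^eta), computed stably
        if eta > 0.0:
            lse = eta + np.log1p(np.exp(-eta))
        else:
            lse = np.log1p(np.exp(eta))
        nll -= 2.0 * (y[i] * eta - lse)
    for j in range(p):
        b = beta[j]
        if b < 0.0:
            b = -b
        nll += lam * pen[j] * b
    return nll


@njit(cache=False)
def cd_logistic_path(
    ZT, y, lambdas, pen, beta0,
    tol_inner, tol_outer, max_outer, max_inner, w_floor,
):
    """Penalized logistic regression along a lambda path.

    External loop: IRLS quadratic expansion at the current beta (work
    response gamma_i, weights w_i = p(1-p) floored at ``w_floor``).
    Internal loop: cyclic coordinate descent on the penalized weighted
    least-squares problem, coordinate curvature 2 sum_i w_i z_ij^2.  A
    bisection safeguard keeps the penalized objective non-increasing
    across outer iterations.
    """
    p, n = ZT.shape
    nlam = lambdas.shape[0]
    betas = np.zeros((nlam, p))
    outer_counts = np.zeros(nlam, np.int64)
    inner_counts = np.zeros(nlam, np.int64)
    conv = np.zeros(nlam, np.uint8)
    beta = beta0.copy()
    beta_old = np.zeros(p)
    w = np.zeros(n)
    gamma = np.zeros(n)
    r = np.zeros(n)
    s = np.zeros(p)
    for l in range(nlam):
        lam = lambdas[l]
        obj = _pen_logistic_obj(ZT, y, beta, lam, pen)
        ot = 0
        total_inner = 0
        ok = False
        while ot < max_outer:
            ot += 1
            # IRLS expansion at the current beta
            for i in range(n):
                eta = 0.0
                for j in range(p):
                    eta += ZT[j, i] * beta[j]
                etac = eta
                if etac > ETA_CLAMP:
                    etac = ETA_CLAMP
                elif etac < -ETA_CLAMP:
                    etac = -ETA_CLAMP
                pv = 1.0 / (1.0 + np.exp(-etac))
                wv = pv * (1.0 - pv)
                if wv < w_floor:
                    wv = w_floor
                w[i] = wv
                gamma[i] = eta + (y[i] - pv) / wv
                r[i] = gamma[i] - eta
            for j in range(p):
                acc = 0.0
                for i in range(n):
                    acc += w[i] * ZT[j, i] * ZT[j, i]
                s[j] = acc
                beta_old[j] = beta[j]
            it = 0
            while it < max_inner:
                it += 1
                maxd = 0.0
                for j in range(p):
                    acc = 0.0
                    for i in range(n):
                        acc += w[i] * ZT[j, i] * r[i]
                    num = 2.0 * acc + 2.0 * s[j] * beta[j]
                    bnew = _soft(num, lam * pen[j]) / (2.0 * s[j])
                    d = bnew - beta[j]
                    if d != 0.0:
                        for i in range(n):
                            r[i] -= d * ZT[j, i]
                        beta[j] = bnew
                    if d < 0.0:
                        d = -d
                    if d > maxd:
                        maxd = d
                if maxd < tol_inner:
                    break
            total_inner += it
            # safeguard: bisect toward the expansion point if the
            # penalized objective increased
            obj_new = _pen_logistic_obj(ZT, y, beta, lam, pen)
            halvings = 0
            while obj_new > obj + 1e-10 and halvings < 10:
                for j in range(p):
                    beta[j] = 0.5 * (beta[j] + beta_old[j])
                obj_new = _pen_logistic_obj(ZT, y, beta, lam, pen)
                halvings += 1
            obj = obj_new
            maxchange = 0.0
            for j in range(p):
                c = beta[j] - beta_old[j]
                if c < 0.0:
                    c = -c
                if c > maxchange:
                    maxchange = c
            if maxchange < tol_outer:
                ok = True
                break
        for j in range(p):
            betas[l, j] = beta[j]
        outer_counts[l] = ot
        inner_counts[l] = total_inner
        conv[l] = 1 if ok else 0
    return betas, outer_counts, inner_counts, conv
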