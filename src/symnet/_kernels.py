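"""Numba-compiled inner loops: Gibbs sampling and L1 logistic paths.

Kept separate so the public modules stay readable; everything here is an
implementation detail of :mod:`symnet.synthetic_data` and
:mod:`symnet.ising`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_sample(tau, omega, n_cases, burn_in, thinning, seed):
    """Single-site Gibbs sampler for a {0,1} pairwise binary MRF.

    Node conditionals are ``P(x_i = 1 | rest) = logistic(tau_i + sum_j
    omega_ij x_j)``.  One chain, fixed cyclic node order, ``burn_in`` full
    sweeps then one retained sample every ``thinning`` sweeps.
    """
    np.random.seed(seed)
    p = tau.shape[0]
    x = np.zeros(p, dtype=np.int8)
    out = np.empty((n_cases, p), dtype=np.int8)
    for _ in range(burn_in):
        for i in range(p):
            eta = tau[i]
            for j in range(p):
                eta += omega[i, j] * x[j]
            x[i] = 1 if np.random.random() < 1.0 / (1.0 + np.exp(-eta)) else 0
    for s in range(n_cases):
        for _ in range(thinning):
            for i in range(p):
                eta = tau[i]
                for j in range(p):
                    eta += omega[i, j] * x[j]
                x[i] = 1 if np.random.random() < 1.0 / (1.0 + np.exp(-eta)) else 0
        out[s] = x
    return out


@njit(cache=True)
def lasso_logistic_path(X, y, lambdas, usable, tol, max_iter):
    """Coordinate-descent L1 logistic regression along a descending lambda grid.

    Minimises ``-(1/n) loglik + lambda * ||beta||_1`` with an unpenalised
    intercept, warm-starting each lambda from the previous solution.
    Each lambda is solved by iteratively reweighted least squares: a
    quadratic expansion at the current fit, minimised by cyclic coordinate
    descent on the penalised weighted least-squares problem, repeated until
    the largest coefficient change of an outer step drops below ``tol``.
    Fitted probabilities are clipped to [1e-5, 1 - 1e-5] so quasi-separated
    fits stay numerically stable.

    ``usable[j]`` is False for columns whose coefficient is forced to 0
    (constant columns).  Returns (intercepts, coefs, logliks) with coefs of
    shape (n_lambda, p).
    """
    n, p = X.shape
    L = lambdas.shape[0]
    intercepts = np.empty(L)
    coefs = np.zeros((L, p))
    logliks = np.empty(L)

    ybar = y.mean()
    if ybar <= 0.0:
        b0 = -30.0
    elif ybar >= 1.0:
        b0 = 30.0
    else:
        b0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    eta = np.full(n, b0)

    w = np.empty(n)
    z = np.empty(n)
    r = np.empty(n)
    eps = 1e-5

    for li in range(L):
        lam = lambdas[li]
        for _outer in range(max_iter):
            # quadratic expansion at the current eta
            for i in range(n):
                pi = 1.0 / (1.0 + np.exp(-eta[i]))
                if pi < eps:
                    pi = eps
                elif pi > 1.0 - eps:
                    pi = 1.0 - eps
                wi = pi * (1.0 - pi)
                w[i] = wi
                z[i] = eta[i] + (y[i] - pi) / wi
                r[i] = z[i] - eta[i]
            wsum = w.sum()
            # per-coordinate curvature, fixed within this expansion
            h = np.zeros(p)
            for j in range(p):
                if usable[j]:
                    s = 0.0
                    for i in range(n):
                        s += w[i] * X[i, j] * X[i, j]
                    h[j] = s / n

            outer_delta = 0.0
            for _inner in range(1000):
                inner_delta = 0.0
                # unpenalised intercept
                num = 0.0
                for i in range(n):
                    num += w[i] * r[i]
                d0 = num / wsum
                if d0 != 0.0:
                    b0 += d0
                    for i in range(n):
                        r[i] -= d0
                    if abs(d0) > inner_delta:
                        inner_delta = abs(d0)
                for j in range(p):
                    if not usable[j] or h[j] <= 0.0:
                        continue
                    hj = h[j]
                    gj = 0.0
                    for i in range(n):
                        gj += w[i] * X[i, j] * r[i]
                    u = gj / n + hj * beta[j]
                    if u > lam:
                        newb = (u - lam) / hj
                    elif u < -lam:
                        newb = (u + lam) / hj
                    else:
                        newb = 0.0
                    d = newb - beta[j]
                    if d != 0.0:
                        beta[j] = newb
                        for i in range(n):
                            r[i] -= d * X[i, j]
                        if abs(d) > inner_delta:
                            inner_delta = abs(d)
                if inner_delta > outer_delta:
                    outer_delta = inner_delta
                if inner_delta < tol:
                    break
            # rebuild eta from the WLS solution
            for i in range(n):
                eta[i] = z[i] - r[i]
            if outer_delta < tol:
                break
        intercepts[li] = b0
        coefs[li] = beta
        ll = 0.0
        for i in range(n):
            # log(1 + e^eta) computed stably
            if eta[i] > 30.0:
                ll += y[i] * eta[i] - eta[i]
            else:
                ll += y[i] * eta[i] - np.log(1.0 + np.exp(eta[i]))
        logliks[li] = ll
    return intercepts, coefs, logliks
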