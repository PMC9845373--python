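"""Independent oracles used by the test suite.

Each oracle re-derives a quantity by a different route than the package:
the natural spline via a generic truncated-power basis with the natural
constraints imposed by explicit linear algebra, and the Poisson MLE via a
Newton-Raphson maximizer of the written-out log-likelihood. They share no
code with the implementation they check.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def truncated_power_natural_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis built from the generic cubic truncated
    power family with the linearity ("natural") constraints solved
    explicitly.

    A cubic spline on knots xi_1 < ... < xi_m is
    f(x) = a + b x + c x^2 + d x^3 + sum_k theta_k (x - xi_k)_+^3.
    Linearity below xi_1 forces c = d = 0; linearity above xi_m then forces
    sum_k theta_k = 0 and sum_k theta_k xi_k = 0. For each j <= m-2 we set
    theta_j = 1 and solve the 2x2 system for (theta_{m-1}, theta_m), scaling
    the resulting function by 1/(xi_m - xi_j) to match the customary
    normalisation. Columns: [x, N_1, ..., N_{m-2}].
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(sorted(knots), dtype=float)
    m = knots.size
    tp = np.clip(x[:, None] - knots[None, :], 0.0, None) ** 3  # (n, m)
    cols = [x]
    A = np.array([[1.0, 1.0], [knots[m - 2], knots[m - 1]]])
    for j in range(m - 2):
        rhs = np.array([-1.0, -knots[j]])
        th_tail = np.linalg.solve(A, rhs)
        f = tp[:, j] + th_tail[0] * tp[:, m - 2] + th_tail[1] * tp[:, m - 1]
        cols.append(f / (knots[m - 1] - knots[j]))
    return np.column_stack(cols)


def poisson_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


def newton_poisson_mle(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-12, maxiter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Newton-Raphson maximizer of the Poisson log-likelihood with step
    halving. Returns (beta_hat, inverse observed information)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8)) if np.allclose(X[:, 0], 1.0) else 0.0
    ll = poisson_loglik(beta, X, y)
    for _ in range(maxiter):
        mu = np.exp(X @ beta)
        score = X.T @ (y - mu)
        hess = X.T @ (X * mu[:, None])
        step = np.linalg.solve(hess, score)
        scale = 1.0
        for _ in range(60):
            new = beta + scale * step
            ll_new = poisson_loglik(new, X, y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        if not np.isfinite(ll_new):
            raise RuntimeError("Newton oracle diverged")
        converged = np.max(np.abs(scale * step)) < tol
        beta, ll = new, ll_new
        if converged:
            break
    mu = np.exp(X @ beta)
    cov = np.linalg.inv(X.T @ (X * mu[:, None]))
    return beta, cov


def crossbasis_double_loop(
    tmax: np.ndarray, var_basis_fn, lag_basis: np.ndarray, max_lag: int
) -> np.ndarray:
    """Brute-force tensor sum: entry (t, (i,j)) = sum_l b_i(x_{t-l}) c_j(l),
    computed index by index; rows t < max_lag are NaN."""
    tmax = np.asarray(tmax, dtype=float)
    n = tmax.size
    dv = var_basis_fn(tmax[:1]).shape[1]
    dl = lag_basis.shape[1]
    out = np.full((n, dv * dl), np.nan)
    for t in range(max_lag, n):
        for i in range(dv):
            for j in range(dl):
                s = 0.0
                for l in range(max_lag + 1):
                    s += var_basis_fn(np.array([tmax[t - l]]))[0, i] * lag_basis[l, j]
                out[t, i * dl + j] = s
    return out
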