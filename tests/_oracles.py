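"""Independent solvers and direct-formula oracles used only by the tests.

These deliberately avoid the code paths they check:

* ``solve_ncr_qp`` — the network-constrained criterion rewritten as a smooth
  bound-constrained convex program via the positive/negative split
  ``beta = u - v`` and solved with L-BFGS-B (no coordinate descent, no data
  augmentation).
* ``solve_glasso_ista`` — proximal gradient with backtracking on the
  penalized Gaussian log-likelihood (no sklearn).
* ``ncr_objective`` / ``glasso_objective`` — the criteria written out
  directly for objective-value comparisons.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def ncr_objective(X, y, L, lam1, lam2, beta) -> float:
    beta = np.asarray(beta, dtype=float)
    resid = y - X @ beta
    pen = lam1 * np.abs(beta).sum()
    if lam2 > 0:
        pen += lam2 * beta @ L @ beta
    return float(resid @ resid + pen)


def solve_ncr_qp(X, y, L, lam1, lam2, tol=1e-14) -> np.ndarray:
    """Minimize ||y - Xb||^2 + lam1 ||b||_1 + lam2 b'Lb via b = u - v, u,v >= 0."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    q = X.shape[1]
    Lm = np.zeros((q, q)) if (L is None or lam2 == 0) else np.asarray(L, dtype=float)

    def fun(z):
        u, v = z[:q], z[q:]
        b = u - v
        r = X @ b - y
        f = r @ r + lam1 * (u.sum() + v.sum()) + lam2 * (b @ Lm @ b)
        g = 2 * X.T @ r + 2 * lam2 * (Lm @ b)
        grad = np.concatenate([g + lam1, -g + lam1])
        return f, grad

    z0 = np.zeros(2 * q)
    res = minimize(
        fun,
        z0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * 2 * q,
        options={"maxiter": 20000, "ftol": tol, "gtol": 1e-12},
    )
    u, v = res.x[:q], res.x[q:]
    return u - v


def glasso_objective(S, lam, theta) -> float:
    """Negative penalized log-likelihood: tr(S T) - log|T| + lam * |T|_offdiag."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    off = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    return float(np.trace(S @ theta) - logdet + lam * off)


def _soft(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def solve_glasso_ista(S, lam, tol=1e-10, max_iter=50000) -> np.ndarray:
    """Proximal gradient on the penalized likelihood with PD-preserving
    backtracking line search; penalty on off-diagonal entries only."""
    S = np.asarray(S, dtype=float)
    k = S.shape[0]
    theta = np.linalg.inv(S + 0.1 * np.eye(k))
    step = 1.0
    f_old = glasso_objective(S, lam, theta)
    off_mask = ~np.eye(k, dtype=bool)
    for _ in range(max_iter):
        grad = S - np.linalg.inv(theta)  # gradient of smooth part
        while True:
            cand = theta - step * grad
            cand[off_mask] = _soft(cand[off_mask], step * lam)
            cand = (cand + cand.T) / 2
            f_new = glasso_objective(S, lam, cand)
            if np.isfinite(f_new):
                # sufficient-decrease test against the quadratic model
                diff = cand - theta
                model = (
                    glasso_objective(S, 0.0, theta)
                    - lam * 0  # smooth part only
                    + (grad * diff).sum()
                    + (diff * diff).sum() / (2 * step)
                )
                smooth_new = glasso_objective(S, 0.0, cand)
                if smooth_new <= model + 1e-12:
                    break
            step *= 0.5
            if step < 1e-12:
                break
        theta = cand
        if abs(f_old - f_new) < tol * max(1.0, abs(f_old)):
            break
        f_old = f_new
        step = min(step * 2.0, 1.0)
    return theta
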