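"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's solver paths: a proximal-gradient
(FISTA) solver for the convex penalized objective, a dense-matrix restricted
GLS log-likelihood, and a dense-algebra BLUP evaluation.
"""

from __future__ import annotations

import numpy as np


def enet_objective(X, y, beta, lam, alpha, pf):
    n = y.shape[0]
    r = y - X @ beta
    pen = lam * pf * (alpha * np.abs(beta) + 0.5 * (1 - alpha) * beta**2)
    return float(r @ r / (2 * n) + pen.sum())


def fista_enet(X, y, lam, alpha, pf, max_iter=50_000, tol=1e-12):
    """Proximal-gradient (FISTA) minimizer of the elastic-net objective.

    Smooth part: quadratic loss + ridge component; prox: soft threshold with
    per-column penalty factors.  Runs to a tight objective tolerance.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    pf = np.asarray(pf, dtype=np.float64)
    n, p = X.shape
    L = np.linalg.norm(X, 2) ** 2 / n + lam * (1 - alpha) * (pf.max() if p else 0.0)
    step = 1.0 / max(L, 1e-12)
    beta = np.zeros(p)
    z = beta.copy()
    t = 1.0
    obj_prev = np.inf
    for it in range(max_iter):
        grad = -X.T @ (y - X @ z) / n + lam * (1 - alpha) * pf * z
        w = z - step * grad
        thresh = step * lam * alpha * pf
        beta_new = np.sign(w) * np.maximum(np.abs(w) - thresh, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = beta_new + ((t - 1) / t_new) * (beta_new - beta)
        beta, t = beta_new, t_new
        if it % 50 == 0:
            obj = enet_objective(X, y, beta, lam, alpha, pf)
            if obj_prev - obj < tol and obj_prev < np.inf:
                break
            obj_prev = obj
    return beta


def dense_restricted_loglik(eta, K, y, W):
    """Restricted GLS log-likelihood evaluated with dense matrices (no eigenbasis)."""
    n, m = W.shape
    Sigma = eta * K + (1 - eta) * np.eye(n)
    Si = np.linalg.inv(Sigma)
    A = W.T @ Si @ W
    b = np.linalg.solve(A, W.T @ Si @ y)
    r = y - W @ b
    s2 = float(r @ Si @ r) / (n - m)
    sign1, ld1 = np.linalg.slogdet(Sigma)
    sign2, ld2 = np.linalg.slogdet(A)
    return -0.5 * ((n - m) * np.log(2 * np.pi * s2) + ld1 + ld2 + (n - m))


def dense_blup(X1_std_pen, y1, lin_train, lin_new, X2_std_pen, eta, K):
    """BLUP for disjoint new samples via explicit dense linear algebra."""
    n, p = X1_std_pen.shape
    Sigma11 = eta * K + (1 - eta) * np.eye(n)
    K21 = X2_std_pen @ X1_std_pen.T / p
    adj = (eta * K21) @ np.linalg.solve(Sigma11, y1[:, None] - lin_train)
    return lin_new + adj
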