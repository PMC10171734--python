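"""Independent numeric oracles used by the test suite.

Every nonsmooth convex objective checked here is rewritten as a smooth
quadratic/linear program with epigraph variables (|q_j| <= u_j, TV terms
|(Dq)_j| <= z_j, group norm ||q|| <= s via s^2 - q'q >= 0) and solved with
scipy's SLSQP.  These oracles share no code with the package's proximal
operators or solvers.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import NonlinearConstraint, minimize


def _tv_matrix(n: int) -> np.ndarray:
    D = np.zeros((max(n - 1, 0), n))
    for j in range(n - 1):
        D[j, j] = 1.0
        D[j, j + 1] = -1.0
    return D


def prox_oracle(v, lam1=0.0, lam2=0.0, lam3=0.0):
    """argmin 1/2||q-v||^2 + lam1||q||_1 + lam2||q||_2 + lam3 TV(q).

    Smoothed-Newton with epsilon-continuation: each |x| is replaced by
    sqrt(x^2 + eps^2); the smoothed problem is solved exactly by damped
    Newton (analytic gradient and Hessian, always positive definite), and
    eps is driven from 1e-1 down to 1e-14.  The objective is 1-strongly
    convex, so |F_eps - F| <= C*eps bounds the argmin error by
    ~2*sqrt(C*eps).  Entirely independent of the package's closed-form
    decomposition.
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    D = _tv_matrix(n)

    def value(q, eps):
        hq = np.sqrt(q**2 + eps**2)
        val = 0.5 * np.sum((q - v) ** 2) + lam1 * np.sum(hq)
        val += lam2 * np.sqrt(q @ q + eps**2)
        if n > 1:
            val += lam3 * np.sum(np.sqrt((D @ q) ** 2 + eps**2))
        return val

    def grad_hess(q, eps):
        g = q - v
        Hs = np.eye(n)
        hq = np.sqrt(q**2 + eps**2)
        g += lam1 * q / hq
        Hs += lam1 * np.diag(eps**2 / hq**3)
        s = np.sqrt(q @ q + eps**2)
        g += lam2 * q / s
        Hs += lam2 * (np.eye(n) / s - np.outer(q, q) / s**3)
        if n > 1:
            d = D @ q
            hd = np.sqrt(d**2 + eps**2)
            g += lam3 * D.T @ (d / hd)
            Hs += lam3 * D.T @ np.diag(eps**2 / hd**3) @ D
        return g, Hs

    q = v.copy()
    for eps in 10.0 ** np.arange(-1, -15, -2):
        for _ in range(60):
            g, Hs = grad_hess(q, eps)
            step = np.linalg.solve(Hs, g)
            # damped Newton: backtrack on the smoothed value
            f0 = value(q, eps)
            tstep = 1.0
            while value(q - tstep * step, eps) > f0 - 1e-4 * tstep * (g @ step) and tstep > 1e-12:
                tstep *= 0.5
            q = q - tstep * step
            if np.linalg.norm(g) < 1e-11 or np.linalg.norm(step) * tstep < 1e-14:
                break
    return q


def full_objective_oracle(data, ts, w, tol=1e-14):
    """Minimize the complete training objective by SLSQP in Q = WR space.

    Returns (W_opt, objective).  Small problems only.
    """
    p, t = data.p, data.t
    D = _tv_matrix(t)
    m = D.shape[0]
    use_s = w.lam2 > 0
    nq = p * t

    def unpack(x):
        Q = x[:nq].reshape(p, t)
        u = x[nq : 2 * nq].reshape(p, t)
        z = x[2 * nq : 2 * nq + p * m].reshape(p, m) if m else np.zeros((p, 0))
        s = x[2 * nq + p * m :] if use_s else np.zeros(p)
        return Q, u, z, s

    def smooth_loss(Q):
        W = Q @ ts.R_inv
        if data.task_type == "regression":
            total, grad = 0.0, np.empty_like(W)
            for i, (Xi, yi) in enumerate(zip(data.X, data.y)):
                r = Xi @ W[:, i] - yi
                total += 0.5 * float(r @ r)
                grad[:, i] = Xi.T @ r
        else:
            total, grad = 0.0, np.empty_like(W)
            for i, (Xi, yi) in enumerate(zip(data.X, data.y)):
                ni = Xi.shape[0]
                mm = yi * (Xi @ W[:, i])
                total += float(np.sum(np.logaddexp(0.0, -mm))) / ni
                sg = np.where(mm >= 0, np.exp(-mm) / (1 + np.exp(-mm)),
                              1.0 / (1 + np.exp(mm)))
                grad[:, i] = -(Xi.T @ (sg * yi)) / ni
        return total, grad @ ts.R_inv.T

    def fun(x):
        Q, u, z, s = unpack(x)
        val = smooth_loss(Q)[0]
        return val + w.lam1 * np.sum(u) + w.lam3 * np.sum(z) + w.lam2 * np.sum(s)

    def jac(x):
        Q, u, z, s = unpack(x)
        g = np.zeros_like(x)
        g[:nq] = smooth_loss(Q)[1].ravel()
        g[nq : 2 * nq] = w.lam1
        if m:
            g[2 * nq : 2 * nq + p * m] = w.lam3
        if use_s:
            g[2 * nq + p * m :] = w.lam2
        return g

    cons = []
    for sign in (+1.0, -1.0):
        cons.append({"type": "ineq",
                     "fun": (lambda x, sg=sign: x[nq : 2 * nq] - sg * x[:nq])})
        if m:
            def tv_con(x, sg=sign):
                Q, u, z, s = unpack(x)
                return (z - sg * (Q @ D.T)).ravel()
            cons.append({"type": "ineq", "fun": tv_con})
    if use_s:
        def s_con(x):
            Q, u, z, s = unpack(x)
            return s**2 - np.sum(Q**2, axis=1)
        cons.append({"type": "ineq", "fun": s_con})

    bounds = ([(None, None)] * nq + [(0, None)] * nq + [(0, None)] * (p * m)
              + ([(0, None)] * p if use_s else []))
    x0 = np.zeros(len(bounds))
    x0[nq : 2 * nq] = 0.1
    if m:
        x0[2 * nq : 2 * nq + p * m] = 0.1
    if use_s:
        x0[2 * nq + p * m :] = 0.1
    res = minimize(fun, x0, jac=jac, method="SLSQP", bounds=bounds,
                   constraints=cons, options={"maxiter": 2000, "ftol": tol})
    Q = res.x[:nq].reshape(p, t)
    W = Q @ ts.R_inv
    return W, fun(res.x)


def least_squares_per_task(data):
    """Column-wise ordinary least squares (pseudoinverse) — the lambda=0 oracle."""
    W = np.empty((data.p, data.t))
    for i, (Xi, yi) in enumerate(zip(data.X, data.y)):
        W[:, i] = np.linalg.lstsq(Xi, yi, rcond=None)[0]
    return W


def ista_sparse_group_lasso(data, lam1, lam2, n_iter=30000):
    """Independently coded ISTA for 1/2 sum||X_i w_i - y_i||^2 + lam1||W||_1
    + lam2 sum_rows ||W_row||_2 (no temporal coupling, no acceleration).

    Deliberately shares nothing with the package solvers: plain gradient
    step at fixed 1/L plus an inline soft-threshold / row-shrink prox.
    """
    p, t = data.p, data.t
    L = max(np.linalg.norm(Xi, 2) ** 2 for Xi in data.X)
    W = np.zeros((p, t))
    step = 1.0 / L
    for _ in range(n_iter):
        G = np.empty_like(W)
        for i, (Xi, yi) in enumerate(zip(data.X, data.y)):
            G[:, i] = Xi.T @ (Xi @ W[:, i] - yi)
        V = W - step * G
        V = np.sign(V) * np.maximum(np.abs(V) - lam1 * step, 0.0)
        norms = np.linalg.norm(V, axis=1, keepdims=True)
        scale = np.where(norms > 0, np.maximum(1 - lam2 * step / np.where(norms > 0, norms, 1), 0), 0)
        W = V * scale
    return W
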