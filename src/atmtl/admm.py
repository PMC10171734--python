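"""Inexact ADMM solver via the splitting A = WR, B = WRH.

The constrained form introduces auxiliaries A (temporal tasks) and B
(temporal differences) so that all nonsmooth penalties act on A and B,
where they have closed-form proxes.  The W-block of the augmented
Lagrangian couples the columns of W through M = RRᵀ + NNᵀ (N = RH); the
update linearizes the coupling Jacobi-style — off-diagonal column terms
are taken at the previous iterate — leaving t independent linear systems

    V_i w_i = q_i,    V_i = X_iᵀX_i + ρ(1 + M_ii)·I,

whose Cholesky factors are computed once (V_i is constant for fixed ρ).
For classification the W-block is minimized by L-BFGS with the analytic
logistic-plus-quadratic gradient.  Stopping is on the primal residual
‖WR−A‖_F + ‖WRH−B‖_F and dual residual ‖ρΔA + ρΔB·Hᵀ‖_F.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .agm import FitResult
from .objectives import (
    MultiTaskDataset,
    PenaltyWeights,
    logistic_loss_and_grad,
    objective_value,
)
from .prox import soft_threshold, sparse_group_prox
from .temporal import TemporalStructure

__all__ = ["ADMMConfig", "ADMMState", "fit_admm", "update_w_regression",
           "update_w_classification", "update_auxiliary", "update_duals", "residuals"]


@dataclass(frozen=True)
class ADMMConfig:
    rho: float = 1.0
    max_iter: int = 10000
    tol_primal: float = 1e-4
    tol_dual: float = 1e-4
    inner_tol: float = 1e-6  # classification W-block
    inner_max_iter: int = 50

    def __post_init__(self) -> None:
        if not (self.rho > 0):
            raise ValueError("rho must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ADMMState:
    """All primal/dual blocks plus cached per-task factorizations."""

    W: np.ndarray
    A: np.ndarray          # auxiliary for WR, p×t
    B: np.ndarray          # auxiliary for WRH, p×(t-1)
    C: np.ndarray          # dual for the A-constraint
    D: np.ndarray          # dual for the B-constraint
    rho: float
    M: np.ndarray          # coupling RRᵀ + NNᵀ, t×t
    cholesky_factors: list[Any] = field(default_factory=list)
    Xty: np.ndarray | None = None  # p×t, precomputed XᵢᵀyᵢSeq

    @classmethod
    def initialize(cls, data: MultiTaskDataset, ts: TemporalStructure, rho: float) -> "ADMMState":
        p, t = data.p, data.t
        E = ts.R @ ts.R.T
        F = ts.N @ ts.N.T
        M = E + F
        state = cls(
            W=np.zeros((p, t)),
            A=np.zeros((p, t)),
            B=np.zeros((p, ts.N.shape[1])),
            C=np.zeros((p, t)),
            D=np.zeros((p, ts.N.shape[1])),
            rho=float(rho),
            M=M,
        )
        if data.task_type == "regression":
            Xty = np.empty((p, t))
            for i, (Xi, yi) in enumerate(zip(data.X, data.y)):
                Vi = Xi.T @ Xi + rho * (1.0 + M[i, i]) * np.eye(p)
                try:
                    state.cholesky_factors.append(cho_factor(Vi))
                except np.linalg.LinAlgError as exc:  # pragma: no cover
                    raise np.linalg.LinAlgError(f"V_{i + 1} is not positive definite") from exc
                Xty[:, i] = Xi.T @ yi
            state.Xty = Xty
        return state


def update_w_regression(state: ADMMState, data: MultiTaskDataset, ts: TemporalStructure) -> np.ndarray:
    """Jacobi-linearized W-update: solve V_i w_i = q_i per task via Cholesky."""
    G = state.A @ ts.R.T
    K = state.B @ ts.N.T
    Lm = state.C @ ts.R.T
    J = state.D @ ts.N.T
    rho = state.rho
    # off-diagonal coupling at the previous iterate
    M_off = state.M - np.diag(np.diag(state.M))
    coupling = state.W @ M_off
    W_new = np.empty_like(state.W)
    for i in range(data.t):
        # the ρ·I damping inside V_i is a proximal term; its center ρ·w_i^k
        # must appear on the right-hand side or the fixed point would not be
        # a stationary point of the augmented Lagrangian
        q = (state.Xty[:, i] - Lm[:, i] + rho * G[:, i]
             - J[:, i] + rho * K[:, i] - rho * coupling[:, i]
             + rho * state.W[:, i])
        W_new[:, i] = cho_solve(state.cholesky_factors[i], q)
    return W_new


def _w_block_value_grad(
    Wf: np.ndarray, shape: tuple[int, int], state: ADMMState,
    data: MultiTaskDataset, ts: TemporalStructure,
) -> tuple[float, np.ndarray]:
    """Value/gradient of the W-block of the augmented Lagrangian (logistic loss)."""
    W = Wf.reshape(shape)
    loss, gW = logistic_loss_and_grad(W, data)
    RA = W @ ts.R - state.A
    NB = W @ ts.N - state.B
    rho = state.rho
    val = (loss + float(np.sum(state.C * RA)) + 0.5 * rho * float(np.sum(RA * RA))
           + float(np.sum(state.D * NB)) + 0.5 * rho * float(np.sum(NB * NB)))
    grad = (gW + state.C @ ts.R.T + state.D @ ts.N.T
            + rho * RA @ ts.R.T + rho * NB @ ts.N.T)
    return val, grad.ravel()


def update_w_classification(
    state: ADMMState, data: MultiTaskDataset, ts: TemporalStructure,
    inner_tol: float = 1e-6, inner_max_iter: int = 50,
) -> np.ndarray:
    """Minimize the logistic W-block by L-BFGS (warm-started at the current W)."""
    shape = state.W.shape
    res = minimize(
        _w_block_value_grad, state.W.ravel(), args=(shape, state, data, ts),
        jac=True, method="L-BFGS-B",
        options={"maxiter": inner_max_iter, "gtol": inner_tol, "ftol": 1e-14},
    )
    if not np.all(np.isfinite(res.x)):
        raise FloatingPointError("inner L-BFGS produced non-finite iterate")
    return res.x.reshape(shape)


def update_auxiliary(
    state: ADMMState, ts: TemporalStructure, w: PenaltyWeights
) -> tuple[np.ndarray, np.ndarray]:
    """Prox updates: A by row-wise sparse-group prox, B by soft-thresholding."""
    rho = state.rho
    VA = state.W @ ts.R + state.C / rho
    A_new = np.empty_like(VA)
    for r in range(VA.shape[0]):
        A_new[r] = sparse_group_prox(VA[r], w.lam1 / rho, w.lam2 / rho)
    VB = state.W @ ts.N + state.D / rho
    B_new = soft_threshold(VB, w.lam3 / rho)
    return A_new, B_new


def update_duals(state: ADMMState, ts: TemporalStructure) -> tuple[np.ndarray, np.ndarray]:
    """Standard ascent: C += ρ(WR − A), D += ρ(WRH − B)."""
    C_new = state.C + state.rho * (state.W @ ts.R - state.A)
    D_new = state.D + state.rho * (state.W @ ts.N - state.B)
    return C_new, D_new


def residuals(
    state: ADMMState, ts: TemporalStructure,
    A_prev: np.ndarray, B_prev: np.ndarray,
) -> tuple[float, float]:
    """Primal ‖WR−A‖_F + ‖WRH−B‖_F and dual ‖ρΔA + ρΔB·Hᵀ‖_F."""
    primal = float(np.linalg.norm(state.W @ ts.R - state.A))
    primal += float(np.linalg.norm(state.W @ ts.N - state.B))
    dual = float(np.linalg.norm(
        state.rho * (state.A - A_prev) + state.rho * (state.B - B_prev) @ ts.H.T))
    return primal, dual


def fit_admm(
    data: MultiTaskDataset,
    ts: TemporalStructure,
    w: PenaltyWeights,
    cfg: ADMMConfig | None = None,
) -> FitResult:
    """Run the full ADMM loop until both residuals fall below tolerance."""
    cfg = cfg or ADMMConfig()
    if ts.t != data.t:
        raise ValueError(f"temporal structure built for t={ts.t}, dataset has t={data.t}")
    state = ADMMState.initialize(data, ts, cfg.rho)
    trace = [objective_value(state.W, data, ts, w)]
    primal_trace: list[float] = []
    dual_trace: list[float] = []
    converged = False
    n_iter = 0
    for k in range(1, cfg.max_iter + 1):
        n_iter = k
        if data.task_type == "regression":
            state.W = update_w_regression(state, data, ts)
        else:
            state.W = update_w_classification(state, data, ts, cfg.inner_tol, cfg.inner_max_iter)
        A_prev, B_prev = state.A, state.B
        state.A, state.B = update_auxiliary(state, ts, w)
        state.C, state.D = update_duals(state, ts)
        primal, dual = residuals(state, ts, A_prev, B_prev)
        obj = objective_value(state.W, data, ts, w)
        if not np.isfinite(obj) or not np.isfinite(primal):
            raise FloatingPointError("ADMM diverged: non-finite iterate")
        trace.append(obj)
        primal_trace.append(primal)
        dual_trace.append(dual)
        if primal < cfg.tol_primal and dual < cfg.tol_dual:
            converged = True
            break
    return FitResult(
        W=state.W,
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
        solver="admm",
        diagnostics={
            "rho": cfg.rho,
            "primal_residuals": primal_trace,
            "dual_residuals": dual_trace,
            "final_primal": primal_trace[-1] if primal_trace else 0.0,
            "final_dual": dual_trace[-1] if dual_trace else 0.0,
        },
    )
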