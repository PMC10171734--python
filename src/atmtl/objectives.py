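"""Losses, penalties, the full training objective, and the Lipschitz bound.

The model couples t per-time-point tasks (design X_i ∈ R^{n_i×p}, target
y_i) through a shared p×t coefficient matrix W and minimizes

    L(W) + λ1‖WR‖₁ + λ2‖WR‖_{1,2} + λ3‖(WRH)ᵀ‖₁

with R = R(α) the adaptive global temporal structure and H the consecutive
difference operator.  L is ½·Σ_i‖X_i w_i − y_i‖² for regression and the
per-task-averaged logistic loss for ±1 classification.

Scaling conventions (they matter when comparing λ values across software):
the squared loss carries a global ½; the logistic loss and gradient are
both normalized by 1/n_i per task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .temporal import TemporalStructure

__all__ = [
    "MultiTaskDataset",
    "PenaltyWeights",
    "squared_loss_and_grad",
    "logistic_loss_and_grad",
    "loss_and_grad",
    "penalty_value",
    "objective_value",
    "lipschitz_bound",
]

TaskType = Literal["regression", "classification"]


@dataclass
class MultiTaskDataset:
    """t ordered tasks sharing p features; task order is temporal order."""

    X: list[np.ndarray]
    y: list[np.ndarray]
    task_type: TaskType = "regression"
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or not self.X:
            raise ValueError("need the same, nonzero number of design matrices and targets")
        self.X = [np.asarray(X, dtype=float) for X in self.X]
        self.y = [np.asarray(y, dtype=float).ravel() for y in self.y]
        p = self.X[0].shape[1]
        for i, (Xi, yi) in enumerate(zip(self.X, self.y)):
            if Xi.ndim != 2 or Xi.shape[1] != p:
                raise ValueError(f"task {i + 1}: design has shape {Xi.shape}, expected p={p} columns")
            if Xi.shape[0] != yi.shape[0] or Xi.shape[0] < 1:
                raise ValueError(f"task {i + 1}: {Xi.shape[0]} rows vs {yi.shape[0]} targets")
        if self.task_type == "classification":
            for i, yi in enumerate(self.y):
                if not np.all(np.isin(yi, (-1.0, 1.0))):
                    raise ValueError(
                        f"task {i + 1}: classification labels must be in {{-1, +1}} "
                        "(remap e.g. {0,1} -> {-1,+1} before fitting)"
                    )
        elif self.task_type != "regression":
            raise ValueError(f"unknown task_type {self.task_type!r}")

    @property
    def t(self) -> int:
        return len(self.X)

    @property
    def p(self) -> int:
        return self.X[0].shape[1]

    @property
    def n(self) -> tuple[int, ...]:
        return tuple(Xi.shape[0] for Xi in self.X)


@dataclass(frozen=True)
class PenaltyWeights:
    """Hyperparameters of the objective: λ1 (L1), λ2 (group), λ3 (fusion), α."""

    lam1: float = 0.0
    lam2: float = 0.0
    lam3: float = 0.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lam1", "lam2", "lam3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not (0.0 <= self.alpha <= 0.5):
            raise ValueError(f"alpha must lie in [0, 0.5], got {self.alpha!r}")


def _check_shapes(W: np.ndarray, data: MultiTaskDataset) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.shape != (data.p, data.t):
        raise ValueError(f"W has shape {W.shape}, expected ({data.p}, {data.t})")
    return W


def squared_loss_and_grad(W: np.ndarray, data: MultiTaskDataset) -> tuple[float, np.ndarray]:
    """½·Σ_i ‖X_i w_i − y_i‖² and its gradient X_iᵀ(X_i w_i − y_i) per column."""
    if data.task_type != "regression":
        raise ValueError("squared loss requires a regression dataset")
    W = _check_shapes(W, data)
    loss = 0.0
    grad = np.empty_like(W)
    for i, (Xi, yi) in enumerate(zip(data.X, data.y)):
        r = Xi @ W[:, i] - yi
        loss += 0.5 * float(r @ r)
        grad[:, i] = Xi.T @ r
    return loss, grad


def logistic_loss_and_grad(W: np.ndarray, data: MultiTaskDataset) -> tuple[float, np.ndarray]:
    """Σ_i (1/n_i)·Σ_j log(1 + exp(−y_ij·x_ijᵀw_i)), stably, with gradient."""
    if data.task_type != "classification":
        raise ValueError("logistic loss requires a classification dataset")
    W = _check_shapes(W, data)
    loss = 0.0
    grad = np.empty_like(W)
    for i, (Xi, yi) in enumerate(zip(data.X, data.y)):
        ni = Xi.shape[0]
        m = yi * (Xi @ W[:, i])  # margins
        # log(1+exp(-m)) = log1p(exp(-m)) for m>=0, = -m + log1p(exp(m)) for m<0
        loss += float(np.sum(np.logaddexp(0.0, -m))) / ni
        # d/dm log(1+exp(-m)) = -sigma(-m)
        s = _sigmoid(-m)
        grad[:, i] = -(Xi.T @ (s * yi)) / ni
    return loss, grad


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def loss_and_grad(W: np.ndarray, data: MultiTaskDataset) -> tuple[float, np.ndarray]:
    """Dispatch on the dataset's task type."""
    if data.task_type == "regression":
        return squared_loss_and_grad(W, data)
    return logistic_loss_and_grad(W, data)


def penalty_value(W: np.ndarray, ts: TemporalStructure, w: PenaltyWeights) -> float:
    """λ1‖WR‖₁ + λ2·Σ_rows‖(WR)_row‖₂ + λ3‖WRH‖₁ (elementwise L1 of the fusion)."""
    W = np.asarray(W, dtype=float)
    Q = W @ ts.R
    val = w.lam1 * float(np.sum(np.abs(Q)))
    val += w.lam2 * float(np.sum(np.linalg.norm(Q, axis=1)))
    if ts.t >= 2:
        val += w.lam3 * float(np.sum(np.abs(Q @ ts.H)))
    return val


def objective_value(
    W: np.ndarray, data: MultiTaskDataset, ts: TemporalStructure, w: PenaltyWeights
) -> float:
    """Loss plus penalty — the quantity both solvers monitor."""
    return loss_and_grad(W, data)[0] + penalty_value(W, ts, w)


def lipschitz_bound(data: MultiTaskDataset) -> float:
    """Smallest uniform Lipschitz constant bound for the loss gradient.

    Regression: σ_X² with σ_X = max_i σ_max(X_i) — the gradient is
    block-diagonal in the columns of W, so the worst task's squared top
    singular value bounds the whole map.  Classification: the logistic
    curvature is at most ¼, giving max_i σ_max(X_i)²/(4 n_i) under the
    1/n_i normalization.
    """
    if not data.X:
        raise ValueError("empty dataset")
    if data.task_type == "regression":
        return max(float(np.linalg.norm(Xi, 2)) ** 2 for Xi in data.X)
    return max(float(np.linalg.norm(Xi, 2)) ** 2 / (4.0 * Xi.shape[0]) for Xi in data.X)
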