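"""Adaptive global temporal structure (AGTS).

The coupling at the heart of the model: each time point's "temporal task"
is a convex combination of the current raw task and the temporal task one
step earlier,

    w̄_1 = w_1,    w̄_i = α·w̄_{i-1} + (1-α)·w_i,   α ∈ [0, 0.5],

which in matrix form reads W·R(α) with R(α) = A_1(α)···A_{t-1}(α) upper
triangular and invertible.  α = 0 decouples the tasks (R = I); the cap at
0.5 keeps the current time point at least as influential as all history
combined.  The difference operator H turns temporal tasks into consecutive
temporal differences, W·R·H, on which the fused-Lasso smoothness penalty
acts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

__all__ = [
    "TemporalStructure",
    "build_agts",
    "agts_column_weights",
    "build_difference_matrix",
    "invert_agts",
]


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not np.isfinite(alpha) or not (0.0 <= alpha <= 0.5):
        raise ValueError(f"alpha must lie in [0, 0.5], got {alpha!r}")
    return alpha


def build_agts(alpha: float, t: int) -> np.ndarray:
    """Build the t×t adaptive global temporal structure matrix R(α).

    R(α) is the product A_1(α)···A_{t-1}(α), where A_i is the identity
    except A_i[i-1, i] = α and A_i[i, i] = 1-α (0-based).  Equivalently its
    columns satisfy the recursion r_1 = e_1, r_i = α r_{i-1} + (1-α) e_i.
    For t = 1 the 1×1 identity is returned.
    """
    alpha = _check_alpha(alpha)
    t = int(t)
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    R = np.zeros((t, t))
    R[0, 0] = 1.0
    for i in range(1, t):
        R[:, i] = alpha * R[:, i - 1]
        R[i, i] = 1.0 - alpha
    return R


def agts_column_weights(alpha: float, i: int, t: int) -> np.ndarray:
    """Closed-form column i (1-based) of R(α): a length-t weight vector.

    Weights are α^{i-1} on the first time point and α^{i-k}(1-α) on time
    point k for 2 ≤ k ≤ i, zero beyond row i.  They sum to one and are
    non-decreasing over the support: the farther back a time point lies,
    the smaller its influence on the current temporal task.
    """
    alpha = _check_alpha(alpha)
    t, i = int(t), int(i)
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    if not (1 <= i <= t):
        raise IndexError(f"task index i must satisfy 1 <= i <= t={t}, got {i}")
    r = np.zeros(t)
    r[0] = alpha ** (i - 1)
    for k in range(2, i + 1):
        r[k - 1] = alpha ** (i - k) * (1.0 - alpha)
    return r


def build_difference_matrix(t: int) -> np.ndarray:
    """Build the t×(t-1) difference operator H.

    Column j carries +1 in row j and -1 in row j+1, so right-multiplying a
    p×t matrix by H forms consecutive column differences.
    """
    t = int(t)
    if t < 2:
        raise ValueError(f"difference matrix needs t >= 2 time points, got {t}")
    H = np.zeros((t, t - 1))
    idx = np.arange(t - 1)
    H[idx, idx] = 1.0
    H[idx + 1, idx] = -1.0
    return H


def invert_agts(R: np.ndarray) -> np.ndarray:
    """Invert R by triangular back-substitution.

    R is upper triangular with diagonal (1, 1-α, ..., 1-α), hence
    invertible for α < 1; a zero diagonal entry is rejected.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"R must be square, got shape {R.shape}")
    d = np.diag(R)
    if np.any(np.abs(d) < 1e-14):
        raise np.linalg.LinAlgError("AGTS matrix is numerically singular (zero diagonal)")
    return solve_triangular(R, np.eye(R.shape[0]), lower=False)


@dataclass(frozen=True)
class TemporalStructure:
    """α, R(α), its inverse, and the difference operators for t tasks.

    ``N = R @ H`` maps coefficient space directly to temporal differences;
    it is the coupling matrix both solvers use.  For t = 1 the difference
    operators are empty (t×0) and the fusion penalty vanishes.
    """

    alpha: float
    t: int
    R: np.ndarray = field(repr=False)
    R_inv: np.ndarray = field(repr=False)
    H: np.ndarray = field(repr=False)
    N: np.ndarray = field(repr=False)

    @classmethod
    def create(cls, alpha: float, t: int) -> "TemporalStructure":
        R = build_agts(alpha, t)
        R_inv = invert_agts(R)
        H = build_difference_matrix(t) if t >= 2 else np.zeros((t, 0))
        return cls(alpha=float(alpha), t=int(t), R=R, R_inv=R_inv, H=H, N=R @ H)
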