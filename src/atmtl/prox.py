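"""Proximal operators for the composite temporal penalty.

The reparameterized objective puts three penalties on each row q of the
temporal-task matrix Q = W·R:

    ½‖q − v‖² + λ1‖q‖₁ + λ2‖q‖₂ + λ3·Σ|q_j − q_{j+1}|            (*)

This prox decomposes exactly: first the fused-Lasso prox (1-D total
variation at λ3 followed by soft-thresholding at λ1), then group (L2)
shrinkage at λ2.  The ordering matters — the decomposition holds in this
direction only.  Rows of Q decouple, so the matrix prox is a row loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProxWeights",
    "soft_threshold",
    "group_shrink",
    "sparse_group_prox",
    "tv1d_prox",
    "fused_lasso_prox",
    "composite_row_prox",
    "matrix_row_prox",
]


@dataclass(frozen=True)
class ProxWeights:
    """Non-negative weights of the three penalties inside a prox subproblem."""

    lam1: float = 0.0  # L1 (elementwise sparsity)
    lam2: float = 0.0  # L2 / group shrinkage
    lam3: float = 0.0  # fusion (total variation on consecutive entries)

    def __post_init__(self) -> None:
        for name in ("lam1", "lam2", "lam3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def scaled(self, factor: float) -> "ProxWeights":
        return ProxWeights(self.lam1 * factor, self.lam2 * factor, self.lam3 * factor)


def _check_lam(lam: float, name: str = "lam") -> float:
    lam = float(lam)
    if not np.isfinite(lam) or lam < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {lam!r}")
    return lam


def soft_threshold(v: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise soft-thresholding: prox of lam·‖·‖₁."""
    lam = _check_lam(lam)
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


def group_shrink(v: np.ndarray, lam: float) -> np.ndarray:
    """Block soft-thresholding: prox of lam·‖·‖₂; zero maps to zero."""
    lam = _check_lam(lam)
    v = np.asarray(v, dtype=float)
    nrm = float(np.linalg.norm(v))
    if nrm <= lam or nrm == 0.0:
        return np.zeros_like(v)
    return (1.0 - lam / nrm) * v


def sparse_group_prox(v: np.ndarray, lam1: float, lam2: float) -> np.ndarray:
    """Prox of lam1·‖·‖₁ + lam2·‖·‖₂ — L2 shrinkage after soft-thresholding."""
    return group_shrink(soft_threshold(v, lam1), lam2)


def tv1d_prox(v: np.ndarray, lam: float) -> np.ndarray:
    """Exact prox of lam·Σ|x_j − x_{j+1}| (1-D total variation).

    Direct single-pass taut-string style algorithm; non-iterative and
    exact up to floating point.  O(n) for typical inputs.
    """
    lam = _check_lam(lam)
    y = np.asarray(v, dtype=float)
    n = y.size
    if n <= 1 or lam == 0.0:
        return y.copy()
    x = np.empty(n)
    # running segment [k0, k] with candidate levels vmin/vmax and slack
    k = k0 = kminus = kplus = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == n - 1:
            # end of signal: flush the pending segment
            if umin < 0.0:
                x[k0 : kminus + 1] = vmin
                k = k0 = kminus = kminus + 1
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
                if k == n - 1:
                    x[k] = vmin + umin
                    return x
                continue
            if umax > 0.0:
                x[k0 : kplus + 1] = vmax
                k = k0 = kplus = kplus + 1
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
                if k == n - 1:
                    x[k] = vmax + umax
                    return x
                continue
            x[k0:n] = vmin + umin / (k - k0 + 1)
            return x
        if y[k + 1] + umin < vmin - lam:
            # level vmin can no longer be extended: negative jump
            x[k0 : kminus + 1] = vmin
            k = k0 = kminus = kplus = kminus + 1
            vmin = y[k]
            vmax = y[k] + 2.0 * lam
            umin = lam
            umax = -lam
        elif y[k + 1] + umax > vmax + lam:
            # positive jump
            x[k0 : kplus + 1] = vmax
            k = k0 = kminus = kplus = kplus + 1
            vmin = y[k] - 2.0 * lam
            vmax = y[k]
            umin = lam
            umax = -lam
        else:
            # extend the segment, updating the slacks
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                kminus = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kplus = k


def fused_lasso_prox(v: np.ndarray, lam1: float, lam3: float) -> np.ndarray:
    """Prox of lam1·‖·‖₁ + lam3·TV: total variation first, then soft-threshold.

    The order is essential; soft-thresholding commutes through the TV prox
    in this direction only (the fused-lasso signal approximator identity).
    """
    return soft_threshold(tv1d_prox(v, lam3), lam1)


def composite_row_prox(v: np.ndarray, w: ProxWeights) -> np.ndarray:
    """Full three-penalty prox (*): group shrinkage of the fused-Lasso prox."""
    return group_shrink(fused_lasso_prox(v, w.lam1, w.lam3), w.lam2)


def matrix_row_prox(V: np.ndarray, w: ProxWeights) -> np.ndarray:
    """Apply the composite prox to every row of a p×t matrix (rows decouple)."""
    V = np.asarray(V, dtype=float)
    out = np.empty_like(V)
    for i in range(V.shape[0]):
        out[i] = composite_row_prox(V[i], w)
    return out
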