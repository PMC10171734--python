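"""Synthetic progression datasets with known ground truth.

Emulates the regime the model targets: a shared feature space across t
ordered time points, per-time-point sample counts that shrink over time
(longitudinal attrition), a small set of feature rows active at every
time point, and coefficient columns that drift smoothly — a seeded random
walk — from one time point to the next.  Regression targets add Gaussian
noise; classification labels are drawn from the logistic model at the
true scores, matching the loss the solvers optimize.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .objectives import MultiTaskDataset

__all__ = ["SyntheticSpec", "make_true_coefficients", "simulate_dataset", "DEFAULT_ATTRITION"]

# default per-time-point sample counts: a declining cohort, exercising
# the unequal-n_i code paths the way real longitudinal panels do
DEFAULT_ATTRITION = (120, 110, 100, 90, 60, 50)


@dataclass(frozen=True)
class SyntheticSpec:
    p: int = 30
    t: int = 6
    n: tuple[int, ...] = DEFAULT_ATTRITION
    s_shared: int = 6       # rows nonzero in every task
    s_task: int = 0         # extra rows each active in one task only
    smooth_step: float = 0.1  # column-to-column drift scale
    noise_sd: float = 0.5
    task_type: Literal["regression", "classification"] = "regression"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1 or self.t < 1:
            raise ValueError("p and t must be >= 1")
        if len(self.n) != self.t:
            raise ValueError(f"need {self.t} sample counts, got {len(self.n)}")
        if any(ni < 1 for ni in self.n):
            raise ValueError("all sample counts must be >= 1")
        if self.s_shared + self.s_task > self.p:
            raise ValueError("s_shared + s_task must not exceed p")
        if self.s_shared < 0 or self.s_task < 0:
            raise ValueError("support sizes must be >= 0")
        if self.smooth_step < 0 or self.noise_sd < 0:
            raise ValueError("smooth_step and noise_sd must be >= 0")


def make_true_coefficients(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth W*: sparse rows, temporally smooth columns.

    Shared-support rows start standard normal at the first time point and
    follow a random walk with step scale ``smooth_step``; task-specific
    rows are active in a single column.  Returns (W*, boolean support
    mask) — both fully determined by the seed.
    """
    rng = np.random.default_rng(spec.seed)
    W = np.zeros((spec.p, spec.t))
    rows = rng.permutation(spec.p)
    shared = rows[: spec.s_shared]
    task_rows = rows[spec.s_shared : spec.s_shared + spec.s_task]
    if spec.s_shared:
        W[shared, 0] = rng.standard_normal(spec.s_shared)
        for k in range(1, spec.t):
            W[shared, k] = W[shared, k - 1] + spec.smooth_step * rng.standard_normal(spec.s_shared)
    for j, r in enumerate(task_rows):
        W[r, j % spec.t] = rng.standard_normal()
    mask = W != 0.0
    # shared rows count as supported at every time point even if a walk hits 0
    if spec.s_shared:
        mask[shared, :] = True
    return W, mask


def simulate_dataset(spec: SyntheticSpec) -> tuple[MultiTaskDataset, np.ndarray, np.ndarray]:
    """Draw (dataset, W*, support mask) from the spec, reproducibly.

    Designs are i.i.d. standard normal.  Regression: y = X w* + noise_sd·ε.
    Classification: P(y=+1) = sigmoid(X w*), labels in {−1, +1}.
    """
    W, mask = make_true_coefficients(spec)
    rng = np.random.default_rng(spec.seed + 1_000_003)
    Xs, ys = [], []
    for i, ni in enumerate(spec.n):
        Xi = rng.standard_normal((ni, spec.p))
        score = Xi @ W[:, i]
        if spec.task_type == "regression":
            yi = score + spec.noise_sd * rng.standard_normal(ni)
        else:
            prob = 1.0 / (1.0 + np.exp(-score))
            yi = np.where(rng.random(ni) < prob, 1.0, -1.0)
        Xs.append(Xi)
        ys.append(yi)
    data = MultiTaskDataset(X=Xs, y=ys, task_type=spec.task_type)
    return data, W, mask
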