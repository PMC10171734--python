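"""User-facing estimator surface: fit, predict, metrics, cross-validation.

Metrics follow the multi-task conventions of the progression-modelling
literature: regression is scored by nMSE — per-task squared error divided
by the population variance of the true test targets, pooled over all
tasks' samples — so that predicting each task's mean scores exactly 1;
classification is scored by pooled accuracy on ±1 labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

import numpy as np
from sklearn.model_selection import KFold

from .admm import ADMMConfig, fit_admm
from .agm import AGMConfig, FitResult, fit_agm
from .objectives import MultiTaskDataset, PenaltyWeights
from .temporal import TemporalStructure

__all__ = [
    "CVGrid",
    "fit",
    "predict",
    "nmse",
    "accuracy",
    "cross_validate",
]

_PAPER_LAMBDAS = [10.0 ** k for k in range(-3, 5)]
_PAPER_ALPHAS = [0.01, 0.02, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5]
_COARSE_LAMBDAS = [0.1, 1.0, 10.0]
_COARSE_ALPHAS = [0.1, 0.3, 0.5]


@dataclass(frozen=True)
class CVGrid:
    """Hyperparameter grid for k-fold cross-validation.

    The full grid spans eight decades per penalty weight (10⁻³…10⁴); the
    coarse preset keeps three mid-range values per weight and three α
    values, trading resolution for a ~200× smaller search.
    """

    lam1_grid: tuple[float, ...] = tuple(_PAPER_LAMBDAS)
    lam2_grid: tuple[float, ...] = tuple(_PAPER_LAMBDAS)
    lam3_grid: tuple[float, ...] = tuple(_PAPER_LAMBDAS)
    alpha_grid: tuple[float, ...] = tuple(_PAPER_ALPHAS)
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("cross-validation needs k >= 2 folds")
        for name in ("lam1_grid", "lam2_grid", "lam3_grid", "alpha_grid"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")

    @classmethod
    def coarse(cls, k: int = 5, seed: int = 0) -> "CVGrid":
        return cls(
            lam1_grid=tuple(_COARSE_LAMBDAS),
            lam2_grid=tuple(_COARSE_LAMBDAS),
            lam3_grid=tuple(_COARSE_LAMBDAS),
            alpha_grid=tuple(_COARSE_ALPHAS),
            k=k,
            seed=seed,
        )

    def points(self) -> list[PenaltyWeights]:
        return [
            PenaltyWeights(l1, l2, l3, a)
            for l1, l2, l3, a in itertools.product(
                self.lam1_grid, self.lam2_grid, self.lam3_grid, self.alpha_grid
            )
        ]


def fit(
    data: MultiTaskDataset,
    weights: PenaltyWeights,
    solver: Literal["agm", "admm"] = "agm",
    solver_cfg: AGMConfig | ADMMConfig | None = None,
) -> FitResult:
    """Fit the temporal multi-task model with the chosen solver."""
    ts = TemporalStructure.create(weights.alpha, data.t)
    if solver == "agm":
        result = fit_agm(data, ts, weights, solver_cfg)
    elif solver == "admm":
        result = fit_admm(data, ts, weights, solver_cfg)
    else:
        raise ValueError(f"unknown solver {solver!r}; expected 'agm' or 'admm'")
    result.diagnostics["weights"] = {
        "lam1": weights.lam1, "lam2": weights.lam2, "lam3": weights.lam3, "alpha": weights.alpha,
    }
    return result


def predict(
    W: np.ndarray,
    X_new: Sequence[np.ndarray],
    task_type: Literal["regression", "classification"] = "regression",
    return_scores: bool = False,
):
    """Per-task predictions X_i·w_i; classification takes signs (ties → +1)."""
    W = np.asarray(W, dtype=float)
    if len(X_new) != W.shape[1]:
        raise ValueError(f"{len(X_new)} design matrices for {W.shape[1]} tasks")
    scores = []
    for i, Xi in enumerate(X_new):
        Xi = np.asarray(Xi, dtype=float)
        if Xi.shape[1] != W.shape[0]:
            raise ValueError(f"task {i + 1}: {Xi.shape[1]} features, expected {W.shape[0]}")
        scores.append(Xi @ W[:, i])
    if task_type == "regression":
        return scores
    labels = [np.where(s >= 0, 1.0, -1.0) for s in scores]
    return (labels, scores) if return_scores else labels


def nmse(Y_true: Sequence[np.ndarray], Y_pred: Sequence[np.ndarray]) -> float:
    """Pooled normalized mean squared error.

    nMSE = [Σ_i ‖y_i − ŷ_i‖² / σ²(y_i)] / Σ_i n_i with σ² the population
    variance (divide by n_i) of the true targets, so the per-task mean
    predictor scores exactly 1.
    """
    if len(Y_true) != len(Y_pred):
        raise ValueError("task count mismatch between truth and predictions")
    num = 0.0
    n_total = 0
    for i, (yt, yp) in enumerate(zip(Y_true, Y_pred)):
        yt = np.asarray(yt, dtype=float).ravel()
        yp = np.asarray(yp, dtype=float).ravel()
        if yt.shape != yp.shape:
            raise ValueError(f"task {i + 1}: shape mismatch {yt.shape} vs {yp.shape}")
        var = float(np.var(yt))
        if var <= 0:
            raise ValueError(f"task {i + 1}: true targets have zero variance, nMSE undefined")
        num += float(np.sum((yt - yp) ** 2)) / var
        n_total += yt.size
    return num / n_total


def accuracy(y_true: Sequence[np.ndarray], y_pred: Sequence[np.ndarray]) -> float:
    """Pooled fraction of correctly predicted ±1 labels across all tasks."""
    if len(y_true) != len(y_pred):
        raise ValueError("task count mismatch between truth and predictions")
    correct = 0
    total = 0
    for i, (yt, yp) in enumerate(zip(y_true, y_pred)):
        yt = np.asarray(yt).ravel()
        yp = np.asarray(yp).ravel()
        if yt.shape != yp.shape:
            raise ValueError(f"task {i + 1}: shape mismatch {yt.shape} vs {yp.shape}")
        if not np.all(np.isin(yt, (-1, 1))):
            raise ValueError(f"task {i + 1}: labels must be in {{-1, +1}}")
        correct += int(np.sum(yt == yp))
        total += yt.size
    return correct / total


def _fold_indices(data: MultiTaskDataset, k: int, seed: int) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Per-task shuffled k-fold split; fold f pools task-wise index pairs."""
    per_task = []
    for i, ni in enumerate(data.n):
        if ni < k:
            raise ValueError(f"task {i + 1} has {ni} samples, too few for {k}-fold CV")
        kf = KFold(n_splits=k, shuffle=True, random_state=seed + i)
        per_task.append(list(kf.split(np.arange(ni))))
    return [[per_task[i][f] for i in range(data.t)] for f in range(k)]


def _subset(data: MultiTaskDataset, idx_lists: Sequence[np.ndarray]) -> MultiTaskDataset:
    return MultiTaskDataset(
        X=[data.X[i][idx] for i, idx in enumerate(idx_lists)],
        y=[data.y[i][idx] for i, idx in enumerate(idx_lists)],
        task_type=data.task_type,
        feature_names=data.feature_names,
    )


def cross_validate(
    data: MultiTaskDataset,
    grid: CVGrid,
    solver: Literal["agm", "admm"] = "agm",
    solver_cfg: AGMConfig | ADMMConfig | None = None,
) -> tuple[PenaltyWeights, list[dict[str, Any]]]:
    """k-fold grid search: minimize mean validation nMSE (regression) or
    maximize pooled accuracy (classification).

    Folds are drawn per task with the grid's seed, so tasks with unequal
    sample counts are split independently; every grid point sees the same
    folds.  Returns the selected weights plus the full score table.
    """
    folds = _fold_indices(data, grid.k, grid.seed)
    table: list[dict[str, Any]] = []
    best: tuple[float, PenaltyWeights] | None = None
    maximize = data.task_type == "classification"
    for pw in grid.points():
        scores = []
        for f, fold in enumerate(folds):
            train = _subset(data, [np.asarray(tr) for tr, _ in fold])
            val = _subset(data, [np.asarray(va) for _, va in fold])
            res = fit(train, pw, solver=solver, solver_cfg=solver_cfg)
            if maximize:
                score = accuracy(val.y, predict(res.W, val.X, "classification"))
            else:
                score = nmse(val.y, predict(res.W, val.X, "regression"))
            scores.append(score)
            table.append({
                "lam1": pw.lam1, "lam2": pw.lam2, "lam3": pw.lam3, "alpha": pw.alpha,
                "fold": f, "metric": "acc" if maximize else "nmse", "score": score,
            })
        mean_score = float(np.mean(scores))
        key = -mean_score if maximize else mean_score
        if best is None or key < best[0]:
            best = (key, pw)
    return best[1], table
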