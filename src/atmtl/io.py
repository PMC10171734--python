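"""Dataset and result I/O: one CSV per time point plus a JSON manifest.

The on-disk layout mirrors how longitudinal cohorts are usually shipped —
one visit per file, each with a header row, a target column, and shared
feature columns.  The manifest fixes the temporal order of the files and
names the target column.  Results round-trip as a headered CSV for the
coefficient matrix plus a JSON run record carrying the full configuration
and convergence trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .agm import FitResult
from .objectives import MultiTaskDataset

__all__ = ["DatasetManifest", "read_dataset", "write_dataset", "write_result", "read_coefficients"]


@dataclass
class DatasetManifest:
    task_files: list[str]
    target_column: str = "target"
    feature_columns: list[str] | Literal["all-others"] = "all-others"
    task_type: Literal["regression", "classification"] = "regression"
    delimiter: str = ","

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def read_dataset(
    manifest: DatasetManifest | str | Path,
    base_dir: str | Path | None = None,
    standardize: bool = False,
) -> MultiTaskDataset:
    """Load per-task tables in manifest order into a MultiTaskDataset.

    Feature columns are aligned by name across files (order-insensitive);
    a mismatched column set, a missing target, or a non-numeric cell is
    rejected naming the offending file.  ``standardize`` z-scores each
    feature using that task's own statistics.
    """
    if not isinstance(manifest, DatasetManifest):
        manifest_path = Path(manifest)
        base_dir = base_dir if base_dir is not None else manifest_path.parent
        manifest = DatasetManifest.load(manifest_path)
    base = Path(base_dir) if base_dir is not None else Path(".")

    frames = []
    for fname in manifest.task_files:
        path = base / fname
        if not path.exists():
            raise FileNotFoundError(f"task file not found: {path}")
        df = pd.read_csv(path, delimiter=manifest.delimiter, float_precision="round_trip")
        if manifest.target_column not in df.columns:
            raise ValueError(f"{path}: missing target column {manifest.target_column!r}")
        frames.append((path, df))

    if manifest.feature_columns == "all-others":
        feat = [c for c in frames[0][1].columns if c != manifest.target_column]
    else:
        feat = list(manifest.feature_columns)
    feat_set = set(feat)
    Xs, ys = [], []
    for path, df in frames:
        cols = set(df.columns) - {manifest.target_column}
        if feat_set - cols:
            missing = sorted(feat_set - cols)
            raise ValueError(f"{path}: missing feature columns {missing}")
        block = df[feat]
        if not all(np.issubdtype(dt, np.number) for dt in block.dtypes):
            bad = [c for c, dt in block.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ValueError(f"{path}: non-numeric feature columns {bad}")
        X = block.to_numpy(dtype=float)
        y = df[manifest.target_column].to_numpy(dtype=float)
        if manifest.task_type == "classification" and not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError(
                f"{path}: classification labels must be in {{-1, +1}}; "
                "found other values (remap e.g. 0/1 -> -1/+1)"
            )
        if standardize:
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd[sd == 0] = 1.0
            X = (X - mu) / sd
        Xs.append(X)
        ys.append(y)
    return MultiTaskDataset(X=Xs, y=ys, task_type=manifest.task_type, feature_names=feat)


def write_dataset(
    data: MultiTaskDataset,
    out_dir: str | Path,
    target_column: str = "target",
    prefix: str = "task",
) -> DatasetManifest:
    """Write one CSV per task plus manifest.json; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feat = data.feature_names or [f"f{j + 1}" for j in range(data.p)]
    files = []
    for i, (Xi, yi) in enumerate(zip(data.X, data.y)):
        df = pd.DataFrame(Xi, columns=feat)
        df[target_column] = yi
        fname = f"{prefix}_{i + 1:02d}.csv"
        df.to_csv(out / fname, index=False)
        files.append(fname)
    manifest = DatasetManifest(
        task_files=files, target_column=target_column,
        feature_columns=feat, task_type=data.task_type,
    )
    manifest.save(out / "manifest.json")
    return manifest


def write_result(
    result: FitResult,
    out_dir: str | Path,
    feature_names: Sequence[str] | None = None,
) -> dict[str, Path]:
    """Write W (CSV, features × tasks), a JSON run record, and a text log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p, t = result.W.shape
    feat = list(feature_names) if feature_names else [f"f{j + 1}" for j in range(p)]
    wdf = pd.DataFrame(result.W, index=pd.Index(feat, name="feature"),
                       columns=[f"task_{i + 1}" for i in range(t)])
    w_path = out / "coefficients.csv"
    wdf.to_csv(w_path)

    record = {
        "solver": result.solver,
        "n_iter": result.n_iter,
        "converged": bool(result.converged),
        "objective_trace": [float(v) for v in result.objective_trace],
        "diagnostics": _jsonable(result.diagnostics),
        "shape": {"p": p, "t": t},
    }
    rec_path = out / "run_record.json"
    with open(rec_path, "w") as fh:
        json.dump(record, fh, indent=2)

    log_path = out / "run.log"
    with open(log_path, "w") as fh:
        fh.write(f"solver={result.solver} converged={result.converged} "
                 f"n_iter={result.n_iter} final_objective={result.objective:.10g}\n")
    return {"coefficients": w_path, "record": rec_path, "log": log_path}


def read_coefficients(path: str | Path) -> np.ndarray:
    """Read back a coefficient CSV written by write_result."""
    return pd.read_csv(path, index_col=0).to_numpy(dtype=float)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
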