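import numpy as np
import pytest

from atmtl import MultiTaskDataset, SyntheticSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_regression():
    """Tiny noisy regression instance with known sparse ground truth."""
    data, W_true, mask = simulate_dataset(
        SyntheticSpec(p=6, t=3, n=(30, 25, 20), s_shared=2, smooth_step=0.1,
                      noise_sd=0.3, seed=7)
    )
    return data, W_true, mask


@pytest.fixture
def small_classification():
    data, W_true, mask = simulate_dataset(
        SyntheticSpec(p=5, t=3, n=(40, 35, 30), s_shared=2, smooth_step=0.1,
                      noise_sd=0.0, task_type="classification", seed=11)
    )
    return data, W_true, mask


def random_dataset(rng, p, t, n_range=(10, 40), task_type="regression", w_scale=1.0):
    """Dense random multi-task instance (no sparsity structure)."""
    W = w_scale * rng.standard_normal((p, t))
    Xs, ys = [], []
    for i in range(t):
        ni = int(rng.integers(*n_range))
        Xi = rng.standard_normal((ni, p))
        score = Xi @ W[:, i]
        if task_type == "regression":
            yi = score + 0.2 * rng.standard_normal(ni)
        else:
            prob = 1 / (1 + np.exp(-score))
            yi = np.where(rng.random(ni) < prob, 1.0, -1.0)
        Xs.append(Xi)
        ys.append(yi)
    return MultiTaskDataset(X=Xs, y=ys, task_type=task_type), W
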