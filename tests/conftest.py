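import numpy as np
import pytest

from ipidyn.predictor import Split, WindowedDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def linear_map_dataset(n=200, k=10, seed=0, slope=0.5, intercept=1.0):
    """Windowed dataset whose target is a noiseless linear function of the
    last input value: target = slope * inputs[:, -1] + intercept."""
    gen = np.random.default_rng(seed)
    inputs = gen.uniform(5.0, 20.0, size=(n, k))
    targets = slope * inputs[:, -1] + intercept
    split = np.empty(n, dtype="<U5")
    n_tr, n_va = int(n * 0.6), int(n * 0.15)
    split[:n_tr] = Split.TRAIN.value
    split[n_tr : n_tr + n_va] = Split.VAL.value
    split[n_tr + n_va :] = Split.TEST.value
    tv = np.concatenate([inputs[:n_tr].ravel(), targets[:n_tr]])
    return WindowedDataset(inputs, targets, split,
                           (float(tv.mean()), float(tv.std())), normalize=True)


@pytest.fixture
def linear_dataset():
    return linear_map_dataset()
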