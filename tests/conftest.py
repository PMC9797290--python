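import numpy as np
import pytest

from nodulenet import phantom, preprocess


@pytest.fixture(scope="session")
def small_volume():
    """One deterministic phantom with three nodules and two distractors."""
    vol, ann = phantom.generate_volume(seed=1, n_nodules=3, n_distractors=2)
    return vol, ann


@pytest.fixture(scope="session")
def preprocessed_volume(small_volume):
    vol, ann = small_volume
    return preprocess.preprocess_volume(vol), ann


def numeric_gradient(fn, tensor, eps=1e-5):
    """Central finite-difference gradient of scalar fn() w.r.t. tensor.data."""
    num = np.zeros_like(tensor.data)
    it = np.nditer(tensor.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = tensor.data[i]
        tensor.data[i] = orig + eps
        fp = float(fn().data.sum())
        tensor.data[i] = orig - eps
        fm = float(fn().data.sum())
        tensor.data[i] = orig
        num[i] = (fp - fm) / (2 * eps)
    return num
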