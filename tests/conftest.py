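import numpy as np
import pytest

from browaug.simulate import BarcodeSpec, stack_traces, synthesize_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """80 traces, 8 classes x 10, 4 experiments, default morphology."""
    traces = synthesize_dataset([10] * 8, 4, seed=1234)
    X, labels, exps = stack_traces(traces)
    return traces, X, labels, exps


@pytest.fixture
def clean_spec():
    """Noiseless, unfolded, forward-read barcode spec."""
    def make(bits, **kw):
        return BarcodeSpec(bits=bits, noise_std=0.0, fold_prob=0.0,
                           reverse_prob=0.0, **kw)
    return make


@pytest.fixture(scope="session")
def split_fixture():
    """Per-label experiment shares 80/8/7/5 over 4 experiments, 8 labels.

    Feasible subsets for bounds (0.04, 0.15) are the same for every label:
    {1}, {2}, {3}, {1,2}, {1,3}, {2,3}.
    """
    counts = {0: 80, 1: 8, 2: 7, 3: 5}
    labels, exps = [], []
    for lab in range(8):
        for e, c in counts.items():
            labels.extend([lab] * c)
            exps.extend([e] * c)
    return np.array(labels), np.array(exps)
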