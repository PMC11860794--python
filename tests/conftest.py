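import numpy as np
import pytest

import fdmcma as f


@pytest.fixture(scope="session")
def beat_pool():
    """Four well-separated synthetic beat classes, 50 train + 200 test per
    class, processed into full-variant data matrices once per session."""
    specs = f.beat_class_library()[:4]
    ds = f.generate_dataset(specs, n_train=50, n_test=200, seed=1)
    train, test = {}, {}
    for sig in ds.train:
        train.setdefault(sig.label, []).append(f.process_signal(sig))
    for sig in ds.test:
        test.setdefault(sig.label, []).append(f.process_signal(sig))
    return train, test


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
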