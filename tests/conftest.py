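import dataclasses

import numpy as np
import pytest

from kneevbr import synthetic as syn


@pytest.fixture(scope="session")
def atlas32():
    return syn.generate_atlas(syn.PhantomSpec(grid_shape=(32, 32, 32)))


@pytest.fixture(scope="session")
def atlas16():
    return syn.generate_atlas(syn.PhantomSpec(grid_shape=(16, 16, 16)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_records(n, seed=0, grade_split=None):
    """Simulated records; optionally force the first half of a grade variable
    to 0 and the second half to 1 for exact group splits."""
    records = syn.simulate_records(n, rng=np.random.default_rng(seed))
    if grade_split:
        records = [
            dataclasses.replace(r, **{grade_split: 0 if i < n // 2 else 1})
            for i, r in enumerate(records)
        ]
    return records
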