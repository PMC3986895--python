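import numpy as np
import pytest
from hypothesis import settings

import barkit as bk

# deterministic hypothesis runs (CI-friendly: no example database, no flakiness)
settings.register_profile("barkit", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("barkit")


@pytest.fixture(scope="session")
def profiles():
    return bk.builtin_profiles()


@pytest.fixture(scope="session")
def default_dataset():
    """One parametric sample under the study design (seeded)."""
    return bk.sample_feature_table(seed=12345)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
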