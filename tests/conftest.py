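import numpy as np
import pandas as pd
import pytest

import sedrisk as sr
from sedrisk.samples import METALS


@pytest.fixture(scope="session")
def profile():
    return sr.default_liuye_profile()


@pytest.fixture(scope="session")
def table21(profile):
    """A default 21-site synthetic table (fixed seed)."""
    return sr.generate_samples(profile, seed=123)


def make_sample_df(n=2, seed=0, with_al=False):
    """Small valid sample frame with arbitrary positive concentrations."""
    rng = np.random.default_rng(seed)
    data = {"site_id": [f"S{i + 1}" for i in range(n)]}
    for metal in METALS:
        data[metal] = rng.uniform(0.5, 10.0, size=n)
    if with_al:
        data["Al"] = rng.uniform(50_000, 90_000, size=n)
    return pd.DataFrame(data)


@pytest.fixture
def sample_df():
    return make_sample_df(n=4, seed=1)
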