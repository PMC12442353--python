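import numpy as np
import pandas as pd
import pytest

from mwsip.synthetic_data import GradientDesign, simulate_community


@pytest.fixture(scope="session")
def design():
    return GradientDesign()


@pytest.fixture(scope="session")
def community():
    """Default-condition community: 100 taxa, 10% incorporators per substrate."""
    return simulate_community(100, 0.1, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_counts():
    return pd.DataFrame(
        {
            "s1": [10, 0, 5, 1],
            "s2": [20, 1, 5, 0],
            "s3": [30, 0, 5, 0],
        },
        index=pd.Index(["t1", "t2", "t3", "t4"], name="taxon_id"),
    )
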