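import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    from mirnet.simulate import SimulationConfig

    return SimulationConfig(n_genes=300, n_mirnas=80, n_true_interactions=8, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    from mirnet.simulate import generate_study

    return generate_study(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_counts():
    """Tiny deterministic count matrix with two groups of three samples."""
    from mirnet.rnaseq import CountMatrix

    rng = np.random.default_rng(5)
    vals = pd.DataFrame(
        rng.integers(5, 200, size=(20, 6)),
        index=[f"g{i}" for i in range(20)],
        columns=[f"CTL_P{i}" for i in range(1, 4)] + [f"MSA_P{i}" for i in range(1, 4)],
    )
    meta = pd.DataFrame(
        {"group": ["control"] * 3 + ["MSA"] * 3, "pool": [f"P{i}" for i in range(1, 4)] * 2},
        index=vals.columns,
    )
    return CountMatrix(vals, meta)
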