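import warnings

import numpy as np
import pandas as pd
import pytest

from ticknet.containers import CountTable
from ticknet.syndata import SimConfig, generate_bundle, generate_counts


@pytest.fixture(autouse=True)
def _quiet_clamp_warnings():
    # omega clamping is expected on small permuted tables and is itself tested
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*basis variance.*")
        yield


@pytest.fixture(scope="session")
def small_counts() -> CountTable:
    """Deterministic 6-taxa x 8-sample table with two groups."""
    rng = np.random.default_rng(123)
    df = pd.DataFrame(
        rng.integers(0, 200, size=(6, 8)),
        index=[f"t{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(8)],
    )
    meta = pd.DataFrame(
        {"group": ["a"] * 4 + ["b"] * 4}, index=pd.Index(df.columns, name="sample")
    )
    return CountTable(df, meta)


@pytest.fixture(scope="session")
def default_bundle():
    """Full synthetic study bundle at the default (study-design) sizes."""
    return generate_bundle(SimConfig(seed=11))


@pytest.fixture(scope="session")
def hub_counts() -> CountTable:
    """Single-group planted-hub table used by network recovery tests."""
    cfg = SimConfig(n_taxa=25, groups=("mock",), n_samples_per_group=100, seed=5)
    return generate_counts(cfg)
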