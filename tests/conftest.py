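import numpy as np
import pandas as pd
import pytest

from funcbind.config import SimConfig
from funcbind.synthdata import simulate_study


def small_config(seed: int = 0, **kw) -> SimConfig:
    """A study small enough for per-test simulation but with the default
    statistical structure (3 batches, triplicates, planted factors)."""
    base = dict(
        n_genes=500, n_tfs=10, n_knockdowns=6, mean_out_degree=40,
        mean_unbound_targets=20, n_control_probes=150,
    )
    base.update(kw)
    return SimConfig(seed=seed, **base)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return small_config(seed=7)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    """(net, layout, mat, probes, truth) for the session's shared study."""
    return simulate_study(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
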