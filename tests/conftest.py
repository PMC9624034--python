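import numpy as np
import pytest

from methdriver.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A reduced synthetic cohort for fast unit tests."""
    return SimConfig(
        seed=7, n_tumor=10, n_normal=10, n_genes=30, n_probes=150,
        frac_driver=0.2, n_bsp_pairs=6,
    )
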