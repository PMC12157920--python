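import numpy as np
import pytest

from lofproxy import synthetic


@pytest.fixture(scope="session")
def demo_config():
    return synthetic.default_config(seed=11, n_genes=1500)


@pytest.fixture(scope="session")
def demo_panel(demo_config):
    return synthetic.simulate_panel(demo_config)


@pytest.fixture(scope="session")
def demo_ko(demo_config, demo_panel):
    _, truth = demo_panel
    return synthetic.simulate_ko(demo_config, truth)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def small_config(**overrides):
    """Fast configuration for targeted tests."""
    defaults = dict(
        n_strains=20,
        n_genes=120,
        focal_fold_range=3.0,
        module_specs=(synthetic.ModuleSpec("modA", 10, 0.5, -1),),
        tf_specs=(synthetic.TFSpec("tfA", 0.7, -0.7),),
        noise_sd=0.4,
        ko_replicates=3,
        ko_effect=1.0,
        seed=5,
    )
    defaults.update(overrides)
    return synthetic.SimulationConfig(**defaults)


@pytest.fixture
def tiny_config():
    return small_config()
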