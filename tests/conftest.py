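import numpy as np
import pytest

from shellproxy import SyntheticConfig, generate_microstructure_image, run_synthetic_experiment


@pytest.fixture
def small_config() -> SyntheticConfig:
    """Scaled-down generator config for fast unit tests (same structure as default)."""
    return SyntheticConfig(
        canvas_size=(192, 192),
        n_bmu=80,
        pore_density=0.8,
        tail_fraction=0.02,
        bmu_tail_base=0.3,
        bmu_tail_scale_slope=0.05,
        pore_base_size=0.05,
        noise_sd=0.02,
        seed=7,
    )


@pytest.fixture
def small_image(small_config):
    return generate_microstructure_image(small_config)


@pytest.fixture(scope="session")
def e2e_result():
    """Full default-config experiment: 3 specimens x 6 temperatures, fixed seed.

    Session-scoped because it carries the whole generate→segment→measure→
    calibrate chain (several minutes); every end-to-end assertion reads from
    this single run.
    """
    return run_synthetic_experiment(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
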