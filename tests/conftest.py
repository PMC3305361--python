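import numpy as np
import pytest

from vinotyper.sim import SimulationConfig, simulate_dataset


def noiseless_config(**overrides):
    """Config with every stochastic nuisance switched off."""
    base = dict(
        n_probes=6,
        n_samples=12,
        seed=0,
        het_sample_fraction=0.5,
        otv_probe_rate=0.0,
        cluster_sd=(0.0, 0.0),
        cg_bias_coeffs=(),
        fraglen_bias_coeffs=(),
        array_scale_sd=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def clean_dataset():
    """Default-noise dataset without OTVs (accuracy conditions)."""
    cfg = SimulationConfig(n_probes=60, n_samples=96, seed=7, otv_probe_rate=0.0)
    probe_table, truth, intensities = simulate_dataset(cfg)
    return cfg, probe_table, truth, intensities


@pytest.fixture(scope="session")
def otv_dataset():
    """Default mixed-event dataset with OTVs."""
    cfg = SimulationConfig(n_probes=60, n_samples=96, seed=11)
    probe_table, truth, intensities = simulate_dataset(cfg)
    return cfg, probe_table, truth, intensities


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
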