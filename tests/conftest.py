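import pytest

from dsp_attenuation.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny 2-region dataset with planted effects, shared across read-only tests."""
    config = SimulationConfig(
        n_genes=300,
        regions=("CA", "DG"),
        n_replicates=3,
        n_flight_degs_per_region=30,
        flight_effect_size=2.0,
        attenuation_alpha=1.0,
        seed=11,
    )
    return simulate_dataset(config)
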