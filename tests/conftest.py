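import pytest

from bacterivory import SimulationConfig, simulate_all


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down experiment that keeps every structural feature of the
    default study conditions (4 incubations, 4-6 samples, planted markers,
    housekeeping and photosynthesis sets, present/relative/absent species)."""
    params = dict(
        n_transcripts=4000, n_kos=400, n_marker_kos=30, n_hk_kos=60,
        n_photo_kos=15, n_species=10, n_cds_per_species=60,
        min_present_transcripts=120,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def config():
    return small_config()


@pytest.fixture(scope="session")
def experiment(config):
    return simulate_all(config, seed=1)
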