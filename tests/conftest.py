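import pytest

from ssbtax import RunConfig, build_population, sample_bmi_heights


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def population(default_config):
    return build_population(default_config)


@pytest.fixture(scope="session")
def small_sample(population):
    """A modest BMI microsample for fast unit tests (2,000 per stratum)."""
    return sample_bmi_heights(population, n_per_stratum=2_000, seed=7)


@pytest.fixture(scope="session")
def full_sample(population, default_config):
    """The default-size microsample (~1e5 individuals per sex), shared across tests."""
    return sample_bmi_heights(population, default_config.n_per_stratum, seed=11)


@pytest.fixture()
def fast_config(default_config) -> RunConfig:
    """Default scenario with a small microsample, for pipeline-level tests."""
    return default_config.model_copy(update={"n_per_stratum": 500})
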