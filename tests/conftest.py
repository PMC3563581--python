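import numpy as np
import pytest

from radmap import PipelineConfig, SimConfig
from radmap.pipeline import run_family_pipeline


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    """A small but fully exercised family: 3 chromosomes, 48 offspring."""
    return PipelineConfig(
        sim=SimConfig(
            n_chromosomes=3,
            markers_per_chromosome=14,
            n_offspring=48,
            mean_coverage=40.0,
            coverage_dispersion=40.0,
            psv_fraction=0.3,
            seed=11,
        ),
        seed=11,
    ).validate()


@pytest.fixture(scope="session")
def small_result(small_config):
    """One end-to-end pipeline run shared by the read-level tests."""
    return run_family_pipeline(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20124)
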