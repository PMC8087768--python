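import logging

import numpy as np
import pytest
from hypothesis import settings

from heelspring import CohortSpec, PipelineConfig, generate_subject

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# COP-outside-foot warnings are expected on forefoot-strike sprint steps
logging.getLogger("heelspring.inverse_dynamics").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def noiseless_spec() -> CohortSpec:
    """Cohort spec with marker/force noise disabled, for oracle comparisons."""
    return CohortSpec(seed=5, marker_noise_sd=0.0, force_noise_sd=0.0)


@pytest.fixture(scope="session")
def default_spec() -> CohortSpec:
    return CohortSpec(seed=5)


@pytest.fixture(scope="session")
def no_filter_config() -> PipelineConfig:
    """Pipeline config with smoothing disabled (noise-free oracle runs)."""
    return PipelineConfig(filtering_enabled=False)


@pytest.fixture(scope="session")
def subject(noiseless_spec):
    return generate_subject(noiseless_spec, 3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
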