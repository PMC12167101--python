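import numpy as np
import pytest

from nsa_vision.synthetic_scene import (
    CohortRanges,
    SceneParams,
    generate_scene,
    generate_template_bank,
    sample_scene_params,
)


@pytest.fixture(scope="session")
def template_bank():
    """Default 5-template reference bank, shared across tests."""
    return generate_template_bank(seed=3)


@pytest.fixture(scope="session")
def clean_scene():
    """One noiseless scene with canonical geometry."""
    return generate_scene(SceneParams(noise_sigma=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_scene():
    """One scene at the default noise level."""
    return generate_scene(SceneParams(seed=11))


@pytest.fixture(scope="session")
def small_cohort_params():
    """Ten independent hip parameter draws at default conditions."""
    return sample_scene_params(10, CohortRanges(), seed=29)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
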