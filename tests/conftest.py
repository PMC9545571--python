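import pytest

from lidarpol import (
    DEFAULT_CONSTANTS,
    FieldSimConfig,
    ModelParams,
    generate_field_observations,
)


@pytest.fixture
def constants():
    return DEFAULT_CONSTANTS


def make_field(truth: ModelParams, n_obs: int, noise_sd: float = 0.0,
               seed: int = 0, **overrides):
    """Shorthand for a synthetic underway series with known truth."""
    config = FieldSimConfig(
        n_obs=n_obs, truth=truth, delta_noise_sd=noise_sd, seed=seed,
        **overrides,
    )
    return generate_field_observations(config)


@pytest.fixture
def single_truth():
    return ModelParams("single", m22_p=0.7, phi_p=0.1)
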