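import numpy as np
import pytest

from priorityfx.synthetic_data import (
    generate_experiment,
    paper_like_spec,
)


@pytest.fixture(scope="session")
def default_spec():
    return paper_like_spec()


@pytest.fixture(scope="session")
def noise_free_frame(default_spec):
    return generate_experiment(default_spec.without_noise(), seed=0)


@pytest.fixture(scope="session")
def noisy_frame(default_spec):
    return generate_experiment(default_spec, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
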