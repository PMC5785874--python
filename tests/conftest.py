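import numpy as np
import pytest

from fenofed import ModelParameters, TrialDesign, generate_trial


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def small_trial(params):
    """6-subject three-way crossover with the default study conditions."""
    return generate_trial(TrialDesign(n_subjects=6), params, seed=42)


@pytest.fixture(scope="session")
def noiseless_params(params):
    """All variability switched off: typical-subject predictions only."""
    return params.zero_random_effects()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
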