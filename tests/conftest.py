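import numpy as np
import pytest

from roscopk.population import FINAL_MODEL
from roscopk.synthetic import TrialDesign, generate_trial


@pytest.fixture(scope="session")
def final_model():
    """The published population model (typical values, IIV, errors)."""
    return FINAL_MODEL


@pytest.fixture(scope="session")
def study_trial(final_model):
    """One synthetic trial at the study design (23 subjects, 3 arms)."""
    return generate_trial(final_model, TrialDesign(), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
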