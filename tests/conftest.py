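import numpy as np
import pytest

from strabiscreen.pipeline import StudyConfig, run_study
from strabiscreen.synth import EyeAppearance

STUDY_SEED = 20240


@pytest.fixture(scope="session")
def study():
    """The full synthetic end-to-end study: trained models, calibration and
    screening results.  Trained once per session; several integration tests
    and the end-to-end acceptance test share it."""
    return run_study(StudyConfig(seed=STUDY_SEED))


@pytest.fixture()
def quiet_appearance():
    """Noise-free default appearance for exact-geometry tests."""
    return EyeAppearance(noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
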