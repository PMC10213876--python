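import numpy as np
import pytest

from qtiholter import generate_recording, reference_cohort
from qtiholter.simulate import SubjectProfile

#: profile overrides that remove every stochastic nuisance
CLEAN = dict(qt_noise_sd=0.0, noise_sd=0.0, wander_amp=0.0, ectopy_rate=0.0)


def make_profile(**overrides) -> SubjectProfile:
    base = dict(
        subject_id="test-subject",
        group="control",
        sex="male",
        alpha_true=0.168,
        beta_true=231.0,  # QTi_true = 399 ms
        rr_mean=828.0,
    )
    base.update(overrides)
    return SubjectProfile(**base)


@pytest.fixture(scope="session")
def ref_spec():
    return reference_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_recording():
    """10-minute noise-free recording with its ground truth."""
    profile = make_profile(**CLEAN)
    rec, truth = generate_recording(
        profile, duration_s=600.0, rng=np.random.default_rng(7))
    return profile, rec, truth
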