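import numpy as np
import pytest

from foveaq.cohort import generate_cohort
from foveaq.quotients import compute_patient_quotients


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (74 eyes of 38 patients), fixed seed."""
    eyes, latent = generate_cohort(seed=1234)
    return eyes, latent


@pytest.fixture(scope="session")
def quotient_table(cohort):
    eyes, _ = cohort
    return compute_patient_quotients(eyes)


@pytest.fixture()
def rng():
    return np.random.default_rng(98765)
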