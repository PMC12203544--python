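import numpy as np
import pytest

from plexdyn.cohort import CohortSpec, sample_cohort
from plexdyn.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default-noise phantom (noise SD = 10% of the CSF-ChP T1w contrast)."""
    return make_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noisefree_phantom():
    """Noise-free phantom with a small bias field (keeps intensities
    non-degenerate for the mixture fits)."""
    return make_phantom(PhantomSpec(seed=7, noise_sd=0.0, bias_amplitude=0.02))


@pytest.fixture(scope="session")
def cohort422():
    """The seeded default synthetic cohort (n=422, study visit structure)."""
    return sample_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def big_baseline_cohort():
    """Large baseline-only cohort for large-sample recovery checks."""
    return sample_cohort(CohortSpec(seed=3, n_subjects=20000, p_fu1=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
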