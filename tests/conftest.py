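import numpy as np
import pytest

from nctpipe import CohortSpec, make_parcellation, simulate_cohort, simulate_subject

#: compact seven-network parcellation used throughout the unit tests
SMALL_NETWORKS = {"VIS": 4, "SMN": 4, "DAN": 4, "SAL": 4, "LIM": 4, "FPN": 4, "DMN": 4}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scheme():
    return make_parcellation(28, SMALL_NETWORKS)


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_subjects_per_group=3, n_timepoints=120, seed=11)


@pytest.fixture(scope="session")
def small_subject(small_scheme, small_spec):
    return simulate_subject(
        small_scheme, small_spec, "NH", np.random.default_rng(7), subject_id="sub-NH01"
    )


@pytest.fixture(scope="session")
def small_cohort(small_scheme, small_spec):
    subjects, metadata = simulate_cohort(small_scheme, small_spec)
    return subjects, metadata


def random_symmetric(n, rng, low=-1.0, high=1.0):
    """Random symmetric matrix with zero diagonal and entries in [low, high]."""
    a = rng.uniform(low, high, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def random_hurwitz(n, rng, eig_low=-2.0, eig_high=-0.5):
    """Random symmetric strictly stable matrix with eigenvalues in [low, high]."""
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    eigs = rng.uniform(eig_low, eig_high, size=n)
    return (q * eigs) @ q.T
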