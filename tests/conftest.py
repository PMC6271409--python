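import numpy as np
import pytest

from lungqct.synthetic import CohortSpec, PhantomSpec, generate_cohort, generate_phantom

# a fast, fully in-body phantom used across test modules
TINY_KW = dict(
    shape=(10, 20, 20),
    spacing=(2.0, 1.5, 1.5),
    lung_centers=((0.0, 0.0, -6.0), (0.0, 0.0, 6.0)),
    lung_semiaxes=((7.0, 7.0, 4.0), (7.0, 7.0, 4.0)),
    body_semiaxes=(11.0, 12.0),
)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def clean_phantom():
    """Default-geometry phantom, no fibrosis, no noise."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def fibrotic_phantom():
    """Default-geometry phantom with a 30% subpleural fibrotic shell."""
    return generate_phantom(PhantomSpec(seed=12, fibrosis_fraction=0.3))


@pytest.fixture()
def tiny_phantom():
    return generate_phantom(PhantomSpec(seed=13, **TINY_KW))


@pytest.fixture(scope="session")
def cohort42():
    """A 42-patient simulated cohort at realistic marginal scales."""
    return generate_cohort(CohortSpec(seed=7, n=42))


@pytest.fixture(scope="session")
def cohort500():
    return generate_cohort(CohortSpec(seed=21, n=500))
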