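import numpy as np
import pytest

from ki67seg.synthetic import AcquisitionProfile, simulate_dataset


@pytest.fixture(scope="session")
def small_profile() -> AcquisitionProfile:
    return AcquisitionProfile(matrix_size=64)


@pytest.fixture(scope="session")
def small_dataset(small_profile):
    """20 phantom cases at 64x64, fixed seed; shared read-only across tests."""
    return simulate_dataset(12, 8, small_profile, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_mask(rng: np.random.Generator, size: int, p: float = 0.3) -> np.ndarray:
    return (rng.random((size, size)) < p).astype(np.uint8)
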