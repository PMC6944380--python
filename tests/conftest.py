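import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from bomilearn import (
    InterfaceMap,
    LearnerParams,
    ProtocolConfig,
    SubjectSpec,
    generate_subject,
)


def random_orthonormal_map(
    rng: np.random.Generator, S: int = 8, K: int = 2, norm: float = 1.0
) -> InterfaceMap:
    """An interface map with orthonormal rows scaled to a given spectral
    norm — the canonical synthetic stand-in for a PCA-derived map."""
    Q, _ = np.linalg.qr(rng.standard_normal((S, S)))
    return InterfaceMap(H=norm * Q[:, :K].T, origin=np.zeros(K))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def unit_map(rng) -> InterfaceMap:
    return random_orthonormal_map(rng, norm=1.0)


@pytest.fixture(scope="session")
def fixture_subject():
    """A small, fully deterministic synthetic subject shared by tests."""
    spec = SubjectSpec(
        params=LearnerParams(eta=0.029, epsilon=0.1937, sigma=0.7794, seed=7),
        seed=7,
    )
    return generate_subject(spec, ProtocolConfig(seed=7))
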