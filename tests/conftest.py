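import numpy as np
import pytest

from lineuproc import EvidenceModel, TrialPool


@pytest.fixture(scope="session")
def model15() -> EvidenceModel:
    """Reference equal-variance model, d' = 1.5."""
    return EvidenceModel(1.5)


@pytest.fixture(scope="session")
def pool6(model15) -> TrialPool:
    """Shared six-person pool, 10k TP + 10k TA trials."""
    return TrialPool.sample(model15, 6, 10_000, 10_000, 20)


@pytest.fixture(scope="session")
def pool1(model15) -> TrialPool:
    """Shared showup pool, 10k TP + 10k TA trials."""
    return TrialPool.sample(model15, 1, 10_000, 10_000, 21)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
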