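import numpy as np
import pytest

import sbarisk as sk


@pytest.fixture(scope="session")
def onset_F() -> sk.OnsetDistribution:
    """Surrogate labour-onset distribution (Khambalia cohort statistics)."""
    return sk.onset_distribution("khambalia")


@pytest.fixture(scope="session")
def latent_Gn() -> sk.LatentPhaseDistribution:
    return sk.latent_distribution("nulliparous")


@pytest.fixture(scope="session")
def latent_Gm() -> sk.LatentPhaseDistribution:
    return sk.latent_distribution("multiparous")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240501)
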