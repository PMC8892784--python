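import numpy as np
import pytest
from hypothesis import settings

from circaheart import StudyConfig, generate_study

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def zt_times():
    """18 observation times: ZT1..ZT21 every 4 h, three replicates each."""
    return np.tile([1.0, 5.0, 9.0, 13.0, 17.0, 21.0], 3)


@pytest.fixture(scope="session")
def small_study():
    """A small but fully structured synthetic study (60 genes, 54 samples)."""
    cfg = StudyConfig(seed=7, n_genes=60)
    return generate_study(cfg)
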