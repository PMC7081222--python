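import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracle helper

from fbatscan import SimConfig, simulate_families


@pytest.fixture(scope="session")
def small_dataset():
    """A modest ascertained cohort with extra null markers, reused across
    read-only tests."""
    return simulate_families(SimConfig(n_families=80, n_null_variants=4, seed=2024))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
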