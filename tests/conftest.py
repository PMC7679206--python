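import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mhengage.simulate import generate, paperlike_config

# optimisation chatter from alternative-link fits is expected, not a defect
warnings.filterwarnings("ignore", category=RuntimeWarning,
                        module="statsmodels")


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-user paperlike cohort shared across tests (events, profiles, truth)."""
    events, profiles, truth = generate(paperlike_config(n_users=120, seed=11))
    return events, profiles, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
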