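import warnings

import numpy as np
import pytest

from pseudonullclines.models import get_model
from pseudonullclines.models.cellcycle import MODIFIED_REGIME

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def fhn():
    return get_model("fhn_toy")


@pytest.fixture(scope="session")
def linear_toy():
    return get_model("linear_toy")


@pytest.fixture(scope="session")
def cellcycle():
    return get_model("cellcycle")


@pytest.fixture(scope="session")
def cellcycle_modified():
    """Strong-feedback regime with basal APC activity: SN pair + excitability."""
    return get_model("cellcycle", k_synth=1.52, **MODIFIED_REGIME)


@pytest.fixture(scope="session")
def mapk_reduced():
    from pseudonullclines.models.mapk22 import mapk22_reduced_system
    return mapk22_reduced_system()


@pytest.fixture(scope="session")
def mapk_full():
    from pseudonullclines.models.mapk22 import mapk22_full_system
    return mapk22_full_system()


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
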