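import numpy as np
import pytest

from nkscreen.layout import ChipLayout
from nkscreen.synthetic import OpticsModel, preset_config, simulate_assay


@pytest.fixture(scope="session")
def small_layout() -> ChipLayout:
    """One imaging field (9 x 9 wells) at default geometry."""
    return ChipLayout(subunit_rows=1, subunit_cols=1)


@pytest.fixture(scope="session")
def resting_sim(small_layout):
    """One simulated field under the resting preset (fixed seed)."""
    config, dist = preset_config("resting")
    return simulate_assay(small_layout, config, dist, None, np.random.default_rng(42))


@pytest.fixture(scope="session")
def noiseless_optics() -> OpticsModel:
    return OpticsModel(noise_sd=0.0, debris_rate_late=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
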