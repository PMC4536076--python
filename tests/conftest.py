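import numpy as np
import pytest

from quiescreen.simulate import ScreenSimConfig, generate_screen_plates


STRONG_ACTIVES = {
    # viability 2% of control at 50 uM in both conditions, 80% at 5 uM
    f"PW-{i:04d}": {
        "proliferating": (0.02, 0.8),
        "quiescent": (0.02, 0.8),
    }
    for i in (3, 17, 42, 81, 140)
}


@pytest.fixture(scope="session")
def small_screen_cfg() -> ScreenSimConfig:
    """Two plates per condition (160 compounds), five strong true actives."""
    return ScreenSimConfig(n_compounds=160, actives=dict(STRONG_ACTIVES), seed=20150813)


@pytest.fixture(scope="session")
def small_screen(small_screen_cfg):
    return generate_screen_plates(small_screen_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
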