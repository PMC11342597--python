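import numpy as np
import pytest

from stratmode import PlatformConfig, simulate_platform, sinusoidal_sealevel


@pytest.fixture(scope="session")
def scenario_a_record():
    """One platform under the composite-sinusoid forcing, reused by all tests.

    2 Myr, 1 kyr steps, 10 x 150 grid, 70 m/Myr subsidence — the long-period
    (1 Myr, 20 m) plus short-period (0.112 Myr, 2 m) eustatic forcing that
    produces a platform with two prolonged lowstand gaps.
    """
    cfg = PlatformConfig(sea_level=sinusoidal_sealevel(), seed=42)
    return simulate_platform(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
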