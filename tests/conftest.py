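import numpy as np
import pytest

from binloud.individualization import calibrated_config
from binloud.synthetic import (GeneratorConfig, ReferenceNH, generate_profile,
                               simulate_listener)


@pytest.fixture(scope="session")
def cfg():
    """Calibrated configuration at a reduced segment count (fast tests)."""
    return calibrated_config(n_segments=200)


@pytest.fixture(scope="session")
def reference_nh(cfg):
    return ReferenceNH.generate(cfg)


@pytest.fixture(scope="session")
def nh_profile(cfg):
    return generate_profile(GeneratorConfig(group="NH", seed=3), cfg)


@pytest.fixture(scope="session")
def hi_profile(cfg):
    return generate_profile(GeneratorConfig(group="HI", seed=7), cfg)


@pytest.fixture(scope="session")
def nh_session(cfg, nh_profile, reference_nh):
    """Noise-free simulated measurement session of the NH listener."""
    return simulate_listener(nh_profile, n_trials=33, noise_cu=0.0, seed=3,
                             reference=reference_nh)
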