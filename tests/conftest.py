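import numpy as np
import pytest

from ecokit import simulate
from ecokit.dyads import DyadPairing


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_session():
    """One deterministic ladder session (no amplitude noise, no blinks)."""
    config = simulate.SessionSimConfig(noise_sd=0.0, blink_rate=0.0, seed=7)
    trace, events = simulate.simulate_pupil_session(config)
    return config, trace, events


@pytest.fixture(scope="session")
def null_cfos_study():
    """Three-group c-Fos study with no planted effects and no coupling."""
    config = simulate.CfosSimConfig(
        n_regions=20, n_per_group=(6, 7, 7), effect_log_fold=0.0,
        dyad_coupling_r=0.0, seed=11,
    )
    return simulate.simulate_cfos_study(config)


@pytest.fixture(scope="session")
def effect_cfos_study():
    """Study with DEM-activated regions a subset of OBS-activated regions
    and one coupled region."""
    config = simulate.CfosSimConfig(
        n_regions=20,
        n_per_group=(6, 7, 7),
        activated_regions_dem=frozenset(range(5)),
        activated_regions_obs=frozenset(range(10)),
        effect_log_fold=1.0,
        dyad_coupling_r=0.9,
        coupled_regions=frozenset([2]),
        seed=23,
    )
    return simulate.simulate_cfos_study(config)


@pytest.fixture
def pairing(effect_cfos_study):
    return DyadPairing(effect_cfos_study.pairing)
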