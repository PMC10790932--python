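import numpy as np
import pytest

from turnintent.features import extract_epochs
from turnintent.preprocess import PreprocessConfig, preprocess
from turnintent.simdata import (
    DecisionModel,
    NoiseModel,
    ScenarioConfig,
    simulate_behavior,
    simulate_recording,
)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced channel/intersection counts keep the suite fast; the design
    ratios (2 Hz, 4-s windows, gap range) match the full protocol."""
    return ScenarioConfig(n_intersections=20, n_blocks=4, n_channels=24, rng_seed=7)


@pytest.fixture(scope="session")
def decision_model():
    return DecisionModel()


@pytest.fixture(scope="session")
def small_log(small_cfg, decision_model):
    return simulate_behavior(small_cfg, decision_model)


@pytest.fixture(scope="session")
def small_recording(small_cfg, small_log):
    rng = np.random.default_rng(small_cfg.rng_seed)
    return simulate_recording(
        small_cfg, small_log,
        active_channels=np.array([1, 4, 9, 13, 17, 21]),
        amplitude=1.0e-3, rng=rng,
    )


@pytest.fixture(scope="session")
def prep_cfg():
    return PreprocessConfig()


@pytest.fixture(scope="session")
def small_conc(small_recording, prep_cfg):
    return preprocess(small_recording, prep_cfg)


@pytest.fixture(scope="session")
def small_epochs(small_conc, small_log):
    return extract_epochs(small_conc, small_log)


@pytest.fixture(scope="session")
def default_cfg():
    """Full protocol size for the design-arithmetic checks (fewer channels
    than the full montage; instance counts do not depend on channel count)."""
    return ScenarioConfig(n_intersections=100, n_blocks=10, n_channels=24, rng_seed=11)


@pytest.fixture(scope="session")
def default_log(default_cfg, decision_model):
    return simulate_behavior(default_cfg, decision_model)


@pytest.fixture(scope="session")
def default_epochs(default_cfg, default_log):
    rng = np.random.default_rng(default_cfg.rng_seed)
    rec = simulate_recording(default_cfg, default_log,
                             active_channels=np.arange(8), rng=rng)
    conc = preprocess(rec, PreprocessConfig())
    return extract_epochs(conc, default_log)
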