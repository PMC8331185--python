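import numpy as np
import pytest

from pupalyze.muscles import make_muscle_map
from pupalyze.simulate import SimulationConfig, simulate_cohort, simulate_recording


@pytest.fixture(scope="session")
def muscle_map():
    return make_muscle_map()


@pytest.fixture(scope="session")
def roi_map():
    return make_muscle_map(with_rois=True)


@pytest.fixture(scope="session")
def default_recording():
    """One simulated animal under default study conditions."""
    return simulate_recording(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """Three animals under default conditions, with the pooled event table."""
    recs, events = simulate_cohort(SimulationConfig(seed=11), 3)
    return recs, events


@pytest.fixture(scope="session")
def support_cohort():
    """Support-planting cohort: 10 animals x 20 bouts, each planted syllable
    in 90% of bouts (the ensemble-recovery benchmark conditions)."""
    cfg = SimulationConfig(
        seed=5, syllable_support=0.9, support_n_bouts=20,
        within_ensemble_jitter=1, idiosyncratic_rate=0.1,
    )
    recs, events = simulate_cohort(cfg, 10)
    return cfg, recs, events


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
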