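import numpy as np
import pytest

import cyclorhythm as cr


@pytest.fixture
def simple_annotation():
    """Two irregular cycles: boundaries 0, 0.5, 1.0, 1.75, 2.5."""
    return cr.CycleZoneAnnotation(np.array([0.0, 0.5, 1.0, 1.75, 2.5]))


@pytest.fixture
def regular_annotation():
    """Five regular cycles of 2 s (zones 0.8 s + 1.2 s)."""
    durations = np.tile([0.8, 1.2], 5)
    return cr.CycleZoneAnnotation(np.concatenate(([0.0], np.cumsum(durations))))


@pytest.fixture(scope="session")
def small_regular_sim():
    """Regular-rhythm simulation: 8 cycles, 1 channel, integer samples per zone."""
    cfg = cr.SimulationConfig(
        n_channels=1, n_cycles=8, jitter=0.0, zone_durations=(0.4, 0.6)
    )
    return cr.simulate(cfg, seed=7) + (cfg,)


@pytest.fixture(scope="session")
def default_sim():
    """Default study conditions: 3 channels, 50 cycles, irregular rhythm."""
    cfg = cr.SimulationConfig()
    return cr.simulate(cfg, seed=123) + (cfg,)
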