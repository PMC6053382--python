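import numpy as np
import pytest

from meanet import SimConfig, SpikeTrain, WellRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def poisson_train(rng):
    """Stationary 2-Hz Poisson train over 300 s."""
    t = np.sort(rng.uniform(0, 300.0, rng.poisson(600)))
    return SpikeTrain(t, electrode_id="E00", duration=300.0)


@pytest.fixture
def quiet_sim_config():
    """Single-process simulator config: tonic firing only, all electrodes active."""
    return SimConfig(n_electrodes=8, duration=120.0,
                     frac_active={1: 1.0, 2: 1.0, 3: 1.0},
                     tonic_rate={1: 1.0, 2: 1.0, 3: 1.0},
                     unit_burst_rate={1: 0.0, 2: 0.0, 3: 0.0},
                     pop_event_rate={1: 0.0, 2: 0.0, 3: 0.0})


def make_well(trains_times, duration=300.0, **kwargs):
    trains = [SpikeTrain(np.asarray(t, dtype=float), electrode_id=f"E{i:02d}",
                         duration=duration)
              for i, t in enumerate(trains_times)]
    return WellRecording(trains, duration=duration, **kwargs)


@pytest.fixture
def well_factory():
    return make_well
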