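import numpy as np
import pytest

import srsleep as sr


@pytest.fixture(scope="session")
def defaults():
    return sr.default_params()


@pytest.fixture(scope="session")
def sp(defaults):
    return defaults["s_process"]


@pytest.fixture(scope="session")
def rp(defaults):
    return defaults["r_process"]


@pytest.fixture(scope="session")
def cfg(defaults):
    return defaults["features"]


@pytest.fixture(scope="session")
def lmap(defaults):
    return defaults["latency_map"]


@pytest.fixture(scope="session")
def baseline_sched():
    return sr.build_entrained(3)


@pytest.fixture(scope="session")
def baseline_traj(baseline_sched, sp, rp):
    return sr.simulate_prescribed(baseline_sched, sp, rp, dt=0.1)


@pytest.fixture(scope="session")
def baseline_features(baseline_traj, baseline_sched, cfg):
    # analysis day: 2 h before the day-2 wake-up until the next wake-up
    return sr.classify_window(baseline_traj, baseline_sched, 46.0, 26.0, cfg)
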