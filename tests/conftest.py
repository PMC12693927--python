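import numpy as np
import pandas as pd
import pytest

import microclim as m


@pytest.fixture(scope="session")
def default_config():
    thresholds, calendar = m.load_default_config()
    return thresholds, calendar


@pytest.fixture(scope="session")
def thresholds(default_config):
    return default_config[0]


@pytest.fixture(scope="session")
def calendar(default_config):
    return default_config[1]


@pytest.fixture(scope="session")
def demo_sim():
    """Short full-pipeline simulation shared across tests (12 days keeps
    the suite fast while covering one stage boundary-free window)."""
    cfg = m.SimulationConfig(seed=11, cycle_days=12)
    return cfg, m.simulate_greenhouse(cfg)


@pytest.fixture(scope="session")
def full_sim():
    """Full-length (190-day) simulation for calibration checks."""
    cfg = m.SimulationConfig(seed=1)
    return cfg, m.simulate_greenhouse(cfg)


@pytest.fixture(scope="session")
def classified_s1(demo_sim, default_config):
    thresholds, calendar = default_config
    _, out = demo_sim
    frame = m.add_vpd(out.complete["S1-EQ"])
    return m.classify_records(frame, thresholds, calendar)


def stage_slices(frame, calendar):
    ts = pd.to_datetime(frame["timestamp"])
    dat = (ts.dt.normalize()
           - pd.Timestamp(calendar.transplant_date)).dt.days
    return {s.name: frame[(dat >= s.start_dat) & (dat <= s.end_dat)]
            for s in calendar.stages}
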