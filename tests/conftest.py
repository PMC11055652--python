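import numpy as np
import pytest

from mbody.core import LfpChannel, SpikeTrain, EpochSet
from mbody.synthetic import (
    SessionConfig,
    StateSchedule,
    UnitSpec,
    generate_session,
)


def awake_schedule(duration: float) -> StateSchedule:
    return StateSchedule(((0.0, duration, "AWK"),), duration)


@pytest.fixture(scope="session")
def awake_session():
    """One 600 s awake session with a mix of tuned units, shared by tests.

    Unit 0: theta-locked (phi = pi/2, kappa = 4); unit 1: linear speed
    (slope 0.2 Hz per cm/s); unit 2: homogeneous Poisson control;
    unit 3: bursting, theta-locked; unit 4: CW AHV-tuned.
    """
    cfg = SessionConfig(
        duration=600.0,
        schedule=awake_schedule(600.0),
        units=(
            UnitSpec(0, base_rate=5.0, phase_lock=(np.pi / 2, 4.0)),
            UnitSpec(1, base_rate=4.0, speed_model=("linear", 0.2, 1.0)),
            UnitSpec(2, base_rate=5.0),
            UnitSpec(3, base_rate=8.0, phase_lock=(0.0, 3.0), burst_mode="bursting"),
            UnitSpec(4, base_rate=4.0, ahv_model=(1.2, 0.0)),
        ),
    )
    return generate_session(cfg, 42)


@pytest.fixture(scope="session")
def sleep_session():
    """A session with wake and sleep blocks, ripples and SWR-coupled units."""
    cfg = SessionConfig(
        duration=900.0,
        awake_frac=1.0 / 3.0,
        mb_response_gain=3.0,
        units=(
            UnitSpec(0, base_rate=5.0, swr_gain=3.0),
            UnitSpec(1, base_rate=5.0),
            UnitSpec(2, base_rate=5.0, swr_gain=0.0),
        ),
    )
    return generate_session(cfg, 7)


def poisson_train(rate: float, duration: float, rng, unit_id=0, region="MB") -> SpikeTrain:
    n = rng.poisson(rate * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    t = t[np.concatenate(([True], np.diff(t) > 1e-6))]
    return SpikeTrain(unit_id, t, duration, region)
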