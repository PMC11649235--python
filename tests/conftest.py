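import numpy as np
import pytest

import ethoflight as ef
from ethoflight.kinematics import SpeedSeries, Trajectory


@pytest.fixture(scope="session")
def pa_cd2_schedule():
    return ef.build_schedule(ef.session_spec("CD2", "PA", seed=1))


@pytest.fixture(scope="session")
def pa_cd2_session(pa_cd2_schedule):
    """One simulated PA animal on CD2 with shipped defaults."""
    params = ef.default_params("PA", seed=1)
    return ef.simulate_session(pa_cd2_schedule, params, animal_seed=0)


@pytest.fixture
def speed_factory():
    """Build a SpeedSeries from a plain list of cm/s values at 30 fps."""

    def _make(values, fps=30.0):
        v = np.asarray(values, dtype=float)
        return SpeedSeries(t=np.arange(len(v)) / fps, v=v, fps=fps)

    return _make


@pytest.fixture
def trajectory_factory():
    """Build a Trajectory from x/y pixel arrays (30 fps, 1/15 cm/px)."""

    def _make(x, y, fps=30.0, calibration=1.0 / 15.0, **channels):
        x = np.asarray(x, dtype=float)
        return Trajectory(fps=fps, t=np.arange(len(x)) / fps, x=x,
                          y=np.asarray(y, dtype=float),
                          calibration=calibration,
                          channels={k: np.asarray(v) for k, v in
                                    channels.items()})

    return _make
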