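from datetime import datetime

import numpy as np
import pytest

from soilvar.process import VARProcess
from soilvar.series import HourlySeries
from soilvar.synthetic import DepthConfig

START = datetime(2017, 12, 19, 0, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(20170101)


def make_hourly(values, variable="moisture", depth=10, start=START, label=""):
    return HourlySeries(
        variable=variable, depth=depth, start=start,
        values=np.asarray(values, dtype=float), label=label,
    )


def flat_depth_config(depth, process, temp_baseline=10.0, moist_baseline=25.0):
    """Depth config with flat trend (and diurnal harmonics, which the
    seasonal difference annihilates exactly)."""
    far = 1e9
    return DepthConfig(
        depth=depth, temp_baseline=temp_baseline, moist_baseline=moist_baseline,
        temp_amplitude=1.0, moist_amplitude=0.2, phase_shift=15.0,
        temp_trend=((0.0, 0.0), (far, 0.0)),
        moist_trend=((0.0, 0.0), (far, 0.0)),
        var_process=process,
    )


@pytest.fixture(scope="session")
def var1_process():
    """Small, clearly stable VAR(1) used across modules."""
    return VARProcess(
        np.array([[[0.5, 0.2], [0.1, 0.4]]]),
        sigma=np.array([[1.0, 0.3], [0.3, 1.0]]),
        labels=("y1", "y2"),
    )
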