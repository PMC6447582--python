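import logging

import numpy as np
import pytest

from myophase import (ProtocolSpec, SignalModelSpec, generate_accel_trace,
                      generate_muscle_signal)

logging.getLogger("myophase").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def protocol():
    return ProtocolSpec()


@pytest.fixture(scope="session")
def pre_trace(protocol):
    """One 5-squat accelerometer stage with ground truth (fixed seed)."""
    return generate_accel_trace(protocol, seed=7, stage="pre")


@pytest.fixture(scope="session")
def hold_trace():
    """One 90 s wall-squat accelerometer stage with ground truth."""
    proto = ProtocolSpec(wall_squat_duration_s=90.0)
    return generate_accel_trace(proto, seed=11, stage="hold")


@pytest.fixture(scope="session")
def mmg_rest_model():
    """MMG model with no fatigue ramps (stationary statistics)."""
    return SignalModelSpec.mmg_default(fatigue_rms_slope=0.0,
                                       fatigue_mpf_slope=0.0)


@pytest.fixture(scope="session")
def mmg_rest_signal(pre_trace, mmg_rest_model):
    _, _, _, truth = pre_trace
    return generate_muscle_signal(mmg_rest_model, truth, "MMG", seed=13)
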