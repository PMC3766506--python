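import numpy as np
import pytest

from pulsedepth import (
    MotorConfig,
    ProtocolConfig,
    SubjectProfile,
    depth_for_pressure,
)
from pulsedepth.acquisition import _Instrument


@pytest.fixture
def symmetric_profile() -> SubjectProfile:
    """Noiseless wrist with the envelope peak at the range midpoint."""
    return SubjectProfile(
        subject_id="SYM",
        heart_rate=72.0,
        p_first=25.0,
        p_peak=135.0,
        p_last=245.0,
        a_max=10.0,
        a_thresh=2.0,
        contact_depth=1.5,
        stiffness=50.0,
        gamma=1.2,
        noise_sd=0.0,
    )


@pytest.fixture
def motor() -> MotorConfig:
    return MotorConfig()


@pytest.fixture
def proto() -> ProtocolConfig:
    return ProtocolConfig()


@pytest.fixture
def step_recording_at(motor, proto):
    """Factory: a 10-s dwell recording at a given baseline pressure."""

    def _make(profile: SubjectProfile, pressure: float, seed: int = 0):
        ins = _Instrument(profile, motor, proto, seed=seed)
        ins.depth = depth_for_pressure(profile, pressure)
        return ins.record_step(1, pressure)

    return _make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
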