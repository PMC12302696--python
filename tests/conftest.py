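import numpy as np
import pytest

from souvenir import SessionSchedule
from souvenir.config import PipelineParams


@pytest.fixture
def default_schedule() -> SessionSchedule:
    """Full study protocol: 8 h window, 3 x 30 min sessions, 30 s cues."""
    return SessionSchedule()


@pytest.fixture
def hour_schedule() -> SessionSchedule:
    """Scaled-down protocol for fast simulation: 1 h window, 60 cues/day."""
    return SessionSchedule(
        window_start=0.0,
        window_duration=3600.0,
        session_starts=(300.0, 1500.0, 2700.0),
        session_duration=600.0,
        inter_cue_interval=30.0,
    )


@pytest.fixture
def tiny_schedule() -> SessionSchedule:
    """Minimal schedule for unit tests: 20 min window, 12 cues/day."""
    return SessionSchedule(
        window_start=0.0,
        window_duration=1200.0,
        session_starts=(100.0, 500.0, 900.0),
        session_duration=120.0,
        inter_cue_interval=30.0,
    )


@pytest.fixture
def params() -> PipelineParams:
    return PipelineParams()


def make_grid(duration_s: float, rate: float = 12.5) -> np.ndarray:
    return np.arange(int(round(duration_s * rate))) / rate
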