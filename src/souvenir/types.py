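"""Domain types for dual-wrist accelerometry monitoring days.

All timestamps are seconds since the start of the monitoring day (float,
millisecond precision is preserved by the CSV writers).  Epochs are 1 s,
half-open and 0-based: epoch ``k`` covers ``[k, k+1)`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

Side = Literal["MI", "LI"]
ActivityStage = Literal["tap", "assist", "independent"]

#: Nominal accelerometer sampling rate (samples per second).
NOMINAL_RATE_HZ = 12.5


class InvariantError(ValueError):
    """Raised when a domain-type invariant is violated at construction."""


@dataclass
class AccelStream:
    """A single wrist's tri-axial accelerometer log.

    Parameters
    ----------
    side : {"MI", "LI"}
        More-involved or less-involved wrist.
    t : ndarray of float
        Sample timestamps, seconds since day start, strictly increasing.
    x, y, z : ndarray of float
        Acceleration along each axis, in g.
    """

    side: Side
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.side not in ("MI", "LI"):
            raise InvariantError(f"side must be 'MI' or 'LI', got {self.side!r}")
        n = len(self.t)
        for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
            if len(arr) != n:
                raise InvariantError(f"{name} has {len(arr)} samples, t has {n}")
            if n and not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise InvariantError(f"non-finite {name} value at row {bad}")
        if n and not np.all(np.isfinite(self.t)):
            raise InvariantError("non-finite timestamp")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                bad = int(np.flatnonzero(dt <= 0)[0])
                raise InvariantError(
                    f"timestamps not strictly increasing at row {bad + 1} "
                    f"(t={self.t[bad + 1]:.3f} follows t={self.t[bad]:.3f})"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xyz(self) -> np.ndarray:
        """Samples as an (n, 3) array."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class CueEventLog:
    """Ordered vibrotactile cue events for one monitoring day."""

    t: np.ndarray
    session_index: np.ndarray  # 1-based session number
    cue_index_in_day: np.ndarray  # 1-based temporal order within the day
    out_of_session: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.session_index = np.asarray(self.session_index, dtype=int)
        self.cue_index_in_day = np.asarray(self.cue_index_in_day, dtype=int)
        if self.out_of_session is None:
            self.out_of_session = np.zeros(len(self.t), dtype=bool)
        else:
            self.out_of_session = np.asarray(self.out_of_session, dtype=bool)
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise InvariantError("cue timestamps not strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class SessionSchedule:
    """Daily monitoring window and cued-session layout.

    Defaults reproduce the study protocol: an 8 h monitoring window holding
    three 30 min cued sessions with one cue every 30 s (180 cues/day).
    """

    window_start: float = 0.0
    window_duration: float = 8 * 3600.0
    session_starts: Sequence[float] = (3600.0, 12600.0, 21600.0)
    session_duration: float = 30 * 60.0
    inter_cue_interval: float = 30.0

    def __post_init__(self) -> None:
        starts = sorted(float(s) for s in self.session_starts)
        self.session_starts = tuple(starts)
        if self.window_duration <= 0:
            raise InvariantError("window_duration must be positive")
        if self.session_duration <= 0 or self.inter_cue_interval <= 0:
            raise InvariantError("session_duration and inter_cue_interval must be positive")
        end = self.window_start + self.window_duration
        prev_end = -np.inf
        for s in starts:
            if s < self.window_start or s + self.session_duration > end:
                raise InvariantError(f"session at {s} s not contained in monitoring window")
            if s < prev_end:
                raise InvariantError("sessions overlap")
            prev_end = s + self.session_duration

    @property
    def window_end(self) -> float:
        return self.window_start + self.window_duration

    @property
    def sessions(self) -> list[tuple[float, float]]:
        """Session intervals as (start, end) pairs."""
        return [(s, s + self.session_duration) for s in self.session_starts]

    def cues_per_session(self) -> int:
        return int(np.floor(self.session_duration / self.inter_cue_interval))

    def cue_count(self) -> int:
        """Expected number of cues per day: sessions x floor(duration/interval)."""
        return len(self.session_starts) * self.cues_per_session()

    def session_of(self, t: float) -> Optional[int]:
        """1-based index of the session containing time ``t``, or None."""
        for i, (s0, s1) in enumerate(self.sessions, start=1):
            if s0 <= t < s1:
                return i
        return None

    def cue_times(self) -> np.ndarray:
        """Nominal cue delivery times for the full protocol."""
        k = np.arange(self.cues_per_session())
        return np.concatenate(
            [s + k * self.inter_cue_interval for s in self.session_starts]
        )


@dataclass
class MonitoringDay:
    """One participant-day: both wrist streams plus the (optional) cue log."""

    participant_id: str
    day_index: int
    schedule: SessionSchedule
    mi_stream: AccelStream
    li_stream: AccelStream
    cue_log: Optional[CueEventLog] = None
    activity_stage: Optional[ActivityStage] = None

    def __post_init__(self) -> None:
        if self.mi_stream.side != "MI" or self.li_stream.side != "LI":
            raise InvariantError("mi_stream/li_stream sides are mislabelled")
        if self.cue_log is not None and len(self.cue_log):
            for t in self.cue_log.t:
                if self.schedule.session_of(float(t)) is None:
                    raise InvariantError(
                        f"cue at t={t:.3f} s lies outside every scheduled session"
                    )


@dataclass
class EpochActivitySeries:
    """Per-wrist 1 Hz epoch series of filtered-magnitude sums and active flags.

    ``missing`` marks epochs with insufficient data; those epochs are held
    inactive but are distinguishable from true below-threshold zeros.
    """

    side: Side
    epoch_start_times: np.ndarray  # integer seconds since day start
    magnitude_sum: np.ndarray
    active: np.ndarray
    missing: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.epoch_start_times = np.asarray(self.epoch_start_times, dtype=int)
        self.magnitude_sum = np.asarray(self.magnitude_sum, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        n = len(self.epoch_start_times)
        if not (len(self.magnitude_sum) == len(self.active) == len(self.missing) == n):
            raise InvariantError("epoch series arrays have mismatched lengths")
        valid = ~self.missing
        if np.any(self.magnitude_sum[valid] < 0):
            raise InvariantError("magnitude_sum must be non-negative")
        expect = self.magnitude_sum[valid] >= self.threshold
        if not np.array_equal(self.active[valid], expect):
            raise InvariantError("active flags inconsistent with threshold")
        if np.any(self.active[self.missing]):
            raise InvariantError("missing epochs cannot be active")

    def __len__(self) -> int:
        return len(self.epoch_start_times)


@dataclass
class CohortTestResult:
    """Outcome of a cohort-level t test against a threshold or paired baseline."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    ci_level: float
    ci_bounds: tuple[float, float]
    threshold: Optional[float]
    direction: Literal["greater", "less", "two_sided"]
    estimate: float = float("nan")  # mean (one-sample) or mean difference (paired)

    def __post_init__(self) -> None:
        lo, hi = self.ci_bounds
        if lo > hi:
            raise InvariantError("ci_lower must not exceed ci_upper")

    def to_dict(self) -> dict:
        return {
            "t": self.t_statistic,
            "df": self.degrees_of_freedom,
            "p": self.p_value,
            "ci_level": self.ci_level,
            "ci": list(self.ci_bounds),
            "threshold": self.threshold,
            "direction": self.direction,
            "estimate": self.estimate,
        }
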