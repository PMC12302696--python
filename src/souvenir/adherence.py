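"""Primary feasibility outcomes: wear-time compliance and cue response rates.

Window conventions (deterministic; the cue/epoch phase is not otherwise
pinned down): the post-cue window is the 5 epochs starting at the first
epoch boundary at/after the cue (``ceil(t_cue)``); the pre-cue window is the
5 epochs ending at the last boundary at/before the cue (``floor(t_cue)``).
A cue "response" is >= ``min_active`` active 1 s epochs in the window;
contiguity is not required.  Cues that fall inside a non-wear gap, or whose
window leaves the monitoring day, are excluded from both numerator and
denominator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .types import AccelStream, CueEventLog, EpochActivitySeries, SessionSchedule, Side

log = logging.getLogger(__name__)

CueOutcome = Literal["responded", "not", "absent"]


@dataclass
class ComplianceResult:
    """Wear-time compliance for one side over one monitoring window."""

    side: str  # MI | LI | system
    total_window_s: float
    non_wear_s: float

    @property
    def compliance_pct(self) -> float:
        if self.total_window_s <= 0:
            raise ValueError("window duration must be positive")
        pct = 100.0 * (self.total_window_s - self.non_wear_s) / self.total_window_s
        return float(np.clip(pct, 0.0, 100.0))


@dataclass
class CueResponseResult:
    """Per-day cue outcomes and the derived pre/post rates."""

    participant_id: str
    day_index: int
    n_cues_delivered: int
    post_cue_response_rate: float
    pre_cue_activity_rate: float
    per_cue_outcomes: list[CueOutcome]  # one slot per scheduled cue index

    def __post_init__(self) -> None:
        if self.n_cues_delivered:
            responded = self.per_cue_outcomes.count("responded")
            if abs(responded / self.n_cues_delivered - self.post_cue_response_rate) > 1e-9:
                raise ValueError("post_cue_response_rate inconsistent with outcomes")


def detect_gaps(
    timestamps: np.ndarray | AccelStream,
    window: Optional[tuple[float, float]] = None,
    min_gap_s: float = 60.0,
) -> list[tuple[float, float]]:
    """Maximal data-free intervals of duration >= ``min_gap_s`` (inclusive).

    Gap duration is the difference between successive sample timestamps, so a
    hole of exactly 60 s counts and 59.9 s does not.  When ``window`` is
    given, leading/trailing holes against the window edges count too, and a
    window with < 2 samples is one whole gap.
    """
    if isinstance(timestamps, AccelStream):
        timestamps = timestamps.t
    t = np.asarray(timestamps, dtype=float)
    if window is not None:
        w0, w1 = window
        t = t[(t >= w0) & (t <= w1)]
        if len(t) < 2:
            return [(w0, w1)] if (w1 - w0) >= min_gap_s else []
        edges = np.concatenate(([w0], t, [w1]))
    else:
        if len(t) < 2:
            return []
        edges = t
    dt = np.diff(edges)
    gaps = [
        (float(edges[i]), float(edges[i + 1]))
        for i in np.flatnonzero(dt >= min_gap_s)
    ]
    return gaps


def wear_time_compliance(
    stream: AccelStream | np.ndarray,
    window: tuple[float, float],
    min_gap_s: float = 60.0,
    side: Optional[str] = None,
) -> ComplianceResult:
    """Percentage of the intended window free of data gaps >= ``min_gap_s``."""
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window duration must be positive")
    if side is None:
        side = stream.side if isinstance(stream, AccelStream) else "MI"
    gaps = detect_gaps(stream, window=window, min_gap_s=min_gap_s)
    non_wear = sum(b - a for a, b in gaps)
    return ComplianceResult(side=side, total_window_s=w1 - w0, non_wear_s=non_wear)


def system_compliance(
    mi: AccelStream,
    li: AccelStream,
    window: tuple[float, float],
    min_gap_s: float = 60.0,
) -> ComplianceResult:
    """System-level variant: both devices must be connected simultaneously.

    Non-wear is the union of the two sides' gap intervals.
    """
    w0, w1 = window
    events: list[tuple[float, int]] = []
    for s in (mi, li):
        for a, b in detect_gaps(s, window=window, min_gap_s=min_gap_s):
            events.append((a, 1))
            events.append((b, -1))
    events.sort()
    non_wear = 0.0
    depth = 0
    open_at = 0.0
    for pos, delta in events:
        if depth == 0 and delta == 1:
            open_at = pos
        depth += delta
        if depth == 0:
            non_wear += pos - open_at
    return ComplianceResult(side="system", total_window_s=w1 - w0, non_wear_s=non_wear)


def _cue_in_gap(t_cue: float, gaps: Sequence[tuple[float, float]]) -> bool:
    return any(a < t_cue < b for a, b in gaps)


def _window_epochs(
    series: EpochActivitySeries, first_epoch: int, n_epochs: int
) -> Optional[np.ndarray]:
    """Active flags for epochs [first, first+n); None if outside the series."""
    start = int(series.epoch_start_times[0])
    i0 = first_epoch - start
    i1 = i0 + n_epochs
    if i0 < 0 or i1 > len(series):
        return None
    return series.active[i0:i1]


def _select_active(
    mi: EpochActivitySeries, li: Optional[EpochActivitySeries], response_arm: str
) -> list[EpochActivitySeries]:
    if response_arm == "MI" or li is None:
        return [mi]
    if response_arm == "LI":
        return [li]
    return [mi, li]


def _cue_responded(
    series_list: list[EpochActivitySeries],
    first_epoch: int,
    window_epochs: int,
    min_active_epochs: int,
    response_arm: str,
) -> Optional[bool]:
    votes = []
    for s in series_list:
        flags = _window_epochs(s, first_epoch, window_epochs)
        if flags is None:
            return None
        votes.append(int(flags.sum()) >= min_active_epochs)
    if response_arm == "both":
        return all(votes)
    return any(votes)  # single-arm or either-arm


def cue_windows(
    cue_log: CueEventLog, window_s: float = 5.0
) -> list[tuple[int, int]]:
    """(first_post_epoch, first_pre_epoch) boundaries per cue."""
    w = int(round(window_s))
    return [(math.ceil(t), math.floor(t) - w) for t in cue_log.t]


def cue_response_result(
    mi: EpochActivitySeries,
    li: Optional[EpochActivitySeries],
    cue_log: CueEventLog,
    schedule: SessionSchedule,
    gaps: Sequence[tuple[float, float]] = (),
    window_s: float = 5.0,
    min_active_s: float = 1.0,
    response_arm: str = "MI",
    participant_id: str = "",
    day_index: int = 0,
) -> CueResponseResult:
    """Post-cue response rate and pre-cue activity rate for one day.

    ``gaps`` (non-wear intervals) exclude the cues they contain from both
    rates symmetrically.
    """
    if len(cue_log) == 0:
        raise ValueError("cue response rate is undefined for an empty cue log")
    w = int(round(window_s))
    need = int(round(min_active_s))
    series = _select_active(mi, li, response_arm)
    n_slots = schedule.cue_count()
    outcomes: list[CueOutcome] = ["absent"] * n_slots
    pre_hits = 0
    post_hits = 0
    n_post = 0
    n_pre = 0
    for t_cue, idx in zip(cue_log.t, cue_log.cue_index_in_day):
        slot = int(idx) - 1
        if _cue_in_gap(float(t_cue), gaps):
            continue
        post = _cue_responded(series, math.ceil(t_cue), w, need, response_arm)
        pre = _cue_responded(series, math.floor(t_cue) - w, w, need, response_arm)
        if post is None:
            log.debug("cue at %.1f s: post window leaves the monitoring day; excluded", t_cue)
        else:
            n_post += 1
            if post:
                post_hits += 1
                if 0 <= slot < n_slots:
                    outcomes[slot] = "responded"
            elif 0 <= slot < n_slots:
                outcomes[slot] = "not"
        if pre is not None:
            n_pre += 1
            pre_hits += int(pre)
    if n_post == 0:
        raise ValueError("no evaluable cues (all excluded)")
    return CueResponseResult(
        participant_id=participant_id,
        day_index=day_index,
        n_cues_delivered=n_post,
        post_cue_response_rate=post_hits / n_post,
        pre_cue_activity_rate=pre_hits / n_pre if n_pre else float("nan"),
        per_cue_outcomes=outcomes,
    )


def cue_response_rate(
    active_series: EpochActivitySeries,
    cue_log: CueEventLog,
    schedule: SessionSchedule,
    window_s: float = 5.0,
    min_active_s: float = 1.0,
) -> float:
    """Post-cue response rate from a single wrist's active flags."""
    res = cue_response_result(
        active_series, None, cue_log, schedule,
        window_s=window_s, min_active_s=min_active_s, response_arm="MI",
    )
    return res.post_cue_response_rate


def pre_cue_activity_rate(
    active_series: EpochActivitySeries,
    cue_log: CueEventLog,
    schedule: SessionSchedule,
    window_s: float = 5.0,
    min_active_s: float = 1.0,
) -> float:
    """Fraction of cues with activity in the 5 s window preceding the cue."""
    res = cue_response_result(
        active_series, None, cue_log, schedule,
        window_s=window_s, min_active_s=min_active_s, response_arm="MI",
    )
    return res.pre_cue_activity_rate


def response_curve_by_cue_index(
    results: Sequence[CueResponseResult], n_slots: int = 180
) -> np.ndarray:
    """Slot-wise mean response rate over all days where that cue was delivered.

    Slots never delivered come back NaN.
    """
    if not results:
        raise ValueError("need at least one cue response result")
    hits = np.zeros(n_slots)
    counts = np.zeros(n_slots)
    for r in results:
        for k, outcome in enumerate(r.per_cue_outcomes[:n_slots]):
            if outcome == "absent":
                continue
            counts[k] += 1
            hits[k] += outcome == "responded"
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)


def schedule_cue_count(schedule: SessionSchedule) -> int:
    """Expected cues per day: sessions x floor(session_duration / interval)."""
    return schedule.cue_count()


def aggregate_participant_rates(
    results: Sequence[CueResponseResult],
) -> dict[str, dict[str, float]]:
    """Average daily pre/post rates across usable days for each participant."""
    by_pid: dict[str, list[CueResponseResult]] = {}
    for r in results:
        by_pid.setdefault(r.participant_id, []).append(r)
    out = {}
    for pid, rs in by_pid.items():
        out[pid] = {
            "post_cue_response_rate": float(np.mean([r.post_cue_response_rate for r in rs])),
            "pre_cue_activity_rate": float(np.nanmean([r.pre_cue_activity_rate for r in rs])),
            "n_days": len(rs),
        }
    return out
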