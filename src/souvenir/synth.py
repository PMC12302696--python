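"""Synthetic monitoring-day and cohort generator.

Produces tri-axial wrist streams with the statistical structure the
downstream analysis assumes: gravity + sensor noise, cue-locked movement
bursts (Bernoulli per cue with optional engagement decay), background
spontaneous activity tiled on 5 s windows, wear gaps, and connection
dropouts.  Everything is driven by a single integer seed.

Burst model: a half-sine amplitude envelope carrying a 1 Hz fundamental —
comfortably inside the 0.25-2.5 Hz passband, so bursts survive filtering by
construction.  The spectrum of real paretic-arm movement is not modelled;
this is a testing convention, not biomechanics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as sio
from .config import QUEST_ITEM_LABELS, SurveyMaps
from .types import AccelStream, CueEventLog, MonitoringDay, SessionSchedule

log = logging.getLogger(__name__)

#: Width of the background-activity tiling; matches the pre/post cue windows.
TILE_S = 5.0


@dataclass
class GeneratorParams:
    """Knobs for one simulated participant-day.

    Defaults for ``p_post``/``p_pre`` follow the cohort means the analysis is
    designed to recover (0.66 post-cue response probability, 0.35 background
    activity per 5 s window).
    """

    seed: int
    p_post: float = 0.66
    p_pre: float = 0.35
    decay_per_cue: float = 1.0
    burst_amplitude: float = 0.2  # g
    burst_duration: float = 1.5  # s
    noise_sd: float = 0.003  # g per axis
    gravity_vector: tuple[float, float, float] = (0.0, 0.0, 1.0)
    gap_spec: Sequence[tuple[float, float]] = ()  # (start_s, duration_s) non-wear
    dropout_spec: Sequence[tuple[float, float]] = ()  # short connection losses
    mi_li_activity_ratio: float = 1.0  # LI background prob = p_pre * ratio

    def __post_init__(self) -> None:
        for name in ("p_post", "p_pre", "decay_per_cue"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.burst_duration < 1.0:
            raise ValueError("burst_duration must be >= 1 s")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _burst(t_rel: np.ndarray, duration: float, amplitude: float) -> np.ndarray:
    """Half-sine envelope x 1 Hz carrier, nonzero on [0, duration)."""
    inside = (t_rel >= 0) & (t_rel < duration)
    env = np.where(inside, np.sin(np.pi * t_rel / duration), 0.0)
    return amplitude * env * np.sin(2 * np.pi * 1.0 * t_rel)


def _add_burst(sig: np.ndarray, t: np.ndarray, t0: float,
               duration: float, amplitude: float) -> None:
    """Add a burst in place, touching only the samples it covers."""
    i0 = int(np.searchsorted(t, t0, side="left"))
    i1 = int(np.searchsorted(t, t0 + duration, side="left"))
    if i1 > i0:
        sig[i0:i1] += _burst(t[i0:i1] - t0, duration, amplitude)


def _make_cue_log(schedule: SessionSchedule) -> CueEventLog:
    t = schedule.cue_times()
    sessions = np.repeat(np.arange(1, len(schedule.session_starts) + 1),
                         schedule.cues_per_session())
    return CueEventLog(t=t, session_index=sessions,
                       cue_index_in_day=np.arange(1, len(t) + 1))


def generate_day(
    params: GeneratorParams,
    schedule: Optional[SessionSchedule] = None,
    participant_id: str = "SYN01",
    day_index: int = 1,
    cued: bool = True,
) -> MonitoringDay:
    """Simulate one participant-day at 12.5 Hz on both wrists.

    Cue responses: with probability ``p_post * decay_per_cue**(i-1)`` for the
    i-th cue, a burst lands on the MI stream at a uniform latency in
    [0.5, 4) s.  Background bursts are tiled on 5 s windows at rate ``p_pre``
    (MI) and ``p_pre * mi_li_activity_ratio`` (LI), with tiles overlapping any
    post-cue window excluded so the post- and pre-cue rates stay separately
    identifiable.  Gap/dropout intervals excise samples from both streams;
    bursts swallowed by an excision are simply lost (logged).
    """
    schedule = schedule or SessionSchedule()
    rng = np.random.default_rng(params.seed)
    rate = 12.5
    n = int(round(schedule.window_duration * rate))
    t = schedule.window_start + np.arange(n) / rate

    cue_log = _make_cue_log(schedule) if cued else None
    cue_times = cue_log.t if cue_log is not None else np.array([])

    mi_sig = np.zeros(n)  # movement signal, added to one axis
    li_sig = np.zeros(n)

    # cue-locked responses on the MI wrist
    n_responded = 0
    for i, tc in enumerate(cue_times):
        p = params.p_post * params.decay_per_cue ** i
        if rng.random() < p:
            latency = rng.uniform(0.5, 4.0)
            _add_burst(mi_sig, t, tc + latency,
                       params.burst_duration, params.burst_amplitude)
            n_responded += 1

    # background activity tiled on 5 s windows, skipping post-cue windows
    n_tiles = int(schedule.window_duration // TILE_S)
    tile_starts = schedule.window_start + TILE_S * np.arange(n_tiles)
    blocked = np.zeros(n_tiles, dtype=bool)
    for tc in cue_times:
        lo, hi = tc, tc + TILE_S
        overlap = (tile_starts < hi) & (tile_starts + TILE_S > lo)
        blocked |= overlap
    p_pre_li = min(1.0, params.p_pre * params.mi_li_activity_ratio)
    for sig, p_bg in ((mi_sig, params.p_pre), (li_sig, p_pre_li)):
        draws = rng.random(n_tiles)
        offsets = rng.uniform(0.0, max(TILE_S - params.burst_duration, 0.0), size=n_tiles)
        for k in np.flatnonzero((draws < p_bg) & ~blocked):
            t0 = tile_starts[k] + offsets[k]
            _add_burst(sig, t, t0, params.burst_duration, params.burst_amplitude)

    gx, gy, gz = params.gravity_vector
    streams = {}
    for side, sig in (("MI", mi_sig), ("LI", li_sig)):
        xyz = rng.normal(0.0, params.noise_sd, size=(n, 3))
        xyz[:, 0] += gx + sig  # movement on the x axis
        xyz[:, 1] += gy
        xyz[:, 2] += gz
        keep = np.ones(n, dtype=bool)
        for start, dur in list(params.gap_spec) + list(params.dropout_spec):
            cut = (t >= start) & (t < start + dur)
            keep &= ~cut
        if not keep.all():
            lost = [(s, d) for s, d in params.gap_spec if np.any((t >= s) & (t < s + d))]
            log.debug("%s: excised %d samples across %d intervals",
                      side, int((~keep).sum()), len(lost))
        xyz = np.round(xyz, 6)  # storage precision (see io.write_accel_log)
        streams[side] = AccelStream(side=side, t=np.round(t[keep], 3),
                                    x=xyz[keep, 0], y=xyz[keep, 1], z=xyz[keep, 2])

    return MonitoringDay(
        participant_id=participant_id,
        day_index=day_index,
        schedule=schedule,
        mi_stream=streams["MI"],
        li_stream=streams["LI"],
        cue_log=cue_log,
    )


@dataclass
class CohortParams:
    """Population distributions for :func:`generate_cohort`."""

    n_participants: int
    n_days: int = 2
    base: GeneratorParams = field(default_factory=lambda: GeneratorParams(seed=0))
    p_post_mean: float = 0.66
    p_post_sd: float = 0.0
    p_pre_mean: float = 0.35
    p_pre_sd: float = 0.0
    # survey item-response means (items drawn around these, clipped to range)
    sus_item_mean: float = 4.2
    quest_item_mean: float = 4.5
    imi_item_mean: float = 5.5

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("cohort needs at least one participant")


@dataclass
class SyntheticParticipant:
    participant_id: str
    p_post: float
    p_pre: float
    days: list[MonitoringDay]
    sus_items: np.ndarray  # 10 ints in 1-5
    quest_items: np.ndarray  # 12 ints in 1-5
    quest_picks: tuple[str, str, str]
    imi_items: np.ndarray  # 37 ints in 1-7


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def _survey_items(rng: np.random.Generator, n: int, mean: float, lo: int, hi: int) -> np.ndarray:
    vals = np.rint(rng.normal(mean, 0.8, size=n)).astype(int)
    return np.clip(vals, lo, hi)


def generate_cohort(
    cohort: CohortParams,
    schedule: Optional[SessionSchedule] = None,
    seed: Optional[int] = None,
) -> list[SyntheticParticipant]:
    """Draw a reproducible cohort of participants with days and survey sheets.

    Per-participant ``p_post``/``p_pre`` come from truncated normals; the
    participant's day seeds are spawned from the cohort seed, so two calls
    with the same seed produce identical cohorts.
    """
    schedule = schedule or SessionSchedule()
    seed = cohort.base.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    out: list[SyntheticParticipant] = []
    for p_idx, child in enumerate(root.spawn(cohort.n_participants), start=1):
        rng = np.random.default_rng(child)
        pid = f"SYN{p_idx:02d}"
        p_post = _trunc_normal(rng, cohort.p_post_mean, cohort.p_post_sd, 0.0, 1.0)
        p_pre = _trunc_normal(rng, cohort.p_pre_mean, cohort.p_pre_sd, 0.0, 1.0)
        days = []
        for d in range(1, cohort.n_days + 1):
            day_seed = int(rng.integers(0, 2**31 - 1))
            params = replace(cohort.base, seed=day_seed, p_post=p_post, p_pre=p_pre)
            days.append(generate_day(params, schedule, participant_id=pid, day_index=d))
        picks_idx = rng.choice(12, size=3, replace=False)
        out.append(
            SyntheticParticipant(
                participant_id=pid,
                p_post=p_post,
                p_pre=p_pre,
                days=days,
                sus_items=_survey_items(rng, 10, cohort.sus_item_mean, 1, 5),
                quest_items=_survey_items(rng, 12, cohort.quest_item_mean, 1, 5),
                quest_picks=tuple(QUEST_ITEM_LABELS[i] for i in sorted(picks_idx)),
                imi_items=_survey_items(rng, 37, cohort.imi_item_mean, 1, 7),
            )
        )
    return out


def write_fixture_dir(
    participants: list[SyntheticParticipant],
    out_dir: str | Path,
    schedule: Optional[SessionSchedule] = None,
    manifest_extra: Optional[dict] = None,
) -> Path:
    """Write a full fixture directory: accel/cue logs, survey sheets, manifest."""
    schedule = schedule or SessionSchedule()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sus_rows, quest_rows, imi_rows = [], [], []
    for p in participants:
        for day in p.days:
            stem = f"{p.participant_id}_d{day.day_index:02d}"
            sio.write_accel_log(day.mi_stream, out_dir / f"{stem}_mi.csv")
            sio.write_accel_log(day.li_stream, out_dir / f"{stem}_li.csv")
            if day.cue_log is not None:
                sio.write_cue_log(day.cue_log, out_dir / f"{stem}_cues.csv")
        sus_rows.append([p.participant_id, *p.sus_items.tolist()])
        quest_rows.append([p.participant_id, *p.quest_items.tolist(), *p.quest_picks])
        imi_rows.append([p.participant_id, *p.imi_items.tolist()])

    def _write(path: Path, header: list[str], rows: list[list]) -> None:
        with open(path, "w") as fh:
            fh.write(",".join(header) + "\n")
            for r in rows:
                fh.write(",".join(str(v) for v in r) + "\n")

    _write(out_dir / "sus.csv",
           ["participant_id", *[f"sus_{i:02d}" for i in range(1, 11)]], sus_rows)
    _write(out_dir / "quest.csv",
           ["participant_id", *[f"quest_{i:02d}" for i in range(1, 13)],
            "pick_1", "pick_2", "pick_3"], quest_rows)
    _write(out_dir / "imi.csv",
           ["participant_id", *[f"imi_{i:02d}" for i in range(1, 38)]], imi_rows)

    manifest = {
        "n_participants": len(participants),
        "participants": [
            {"participant_id": p.participant_id, "p_post": p.p_post,
             "p_pre": p.p_pre, "n_days": len(p.days)}
            for p in participants
        ],
        "schedule": {
            "window_start": schedule.window_start,
            "window_duration": schedule.window_duration,
            "session_starts": list(schedule.session_starts),
            "session_duration": schedule.session_duration,
            "inter_cue_interval": schedule.inter_cue_interval,
        },
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir
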