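"""Pipeline configuration: schedule, signal parameters, and survey maps."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .types import NOMINAL_RATE_HZ, SessionSchedule


class ConfigError(ValueError):
    pass


#: Default activity-count threshold (g-seconds per 1 s epoch), calibrated so
#: that resting accelerometer noise at the generator default (noise_sd =
#: 0.003 g) produces < 1% false-active epochs.  The underlying study names a
#: thresholding approach without printing a value; this constant is a repo
#: convention (see :func:`souvenir.pipeline.calibrate_threshold`).
DEFAULT_ACTIVITY_THRESHOLD = 0.15

#: QUEST satisfaction-item labels (12-item instrument).
QUEST_ITEM_LABELS = (
    "dimensions",
    "weight",
    "adjustments",
    "safety",
    "durability",
    "ease_of_use",
    "comfort",
    "effectiveness",
    "service_delivery",
    "repairs_servicing",
    "professional_service",
    "follow_up_services",
)

#: Default 37-item intrinsic-motivation subscale map (1-based item numbers).
#: Block layout and reverse set are a repo convention and must be checked
#: against the administered instrument sheet before comparing published scores.
DEFAULT_IMI_SUBSCALES: dict[str, list[int]] = {
    "interest_enjoyment": list(range(1, 8)),
    "perceived_competence": list(range(8, 14)),
    "effort_importance": list(range(14, 19)),
    "pressure_tension": list(range(19, 24)),
    "perceived_choice": list(range(24, 31)),
    "value_usefulness": list(range(31, 38)),
}
DEFAULT_IMI_REVERSE_ITEMS = frozenset({4, 15, 17, 19, 20, 24, 26, 27, 29, 30})


@dataclass
class PipelineParams:
    """Signal-processing and response-window parameters."""

    rate_hz: float = NOMINAL_RATE_HZ
    band_hz: tuple[float, float] = (0.25, 2.5)
    filter_order: int = 4
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD
    min_gap_s: float = 60.0
    response_window_s: float = 5.0
    min_active_s: float = 1.0
    max_interp_gap_intervals: float = 2.0
    response_arm: str = "MI"  # MI | LI | either | both

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        nyquist = self.rate_hz / 2.0
        if not (0.0 < lo < hi < nyquist):
            raise ConfigError(
                f"filter band {self.band_hz} must lie inside (0, {nyquist}) Hz "
                f"at {self.rate_hz} Hz sampling"
            )
        if self.activity_threshold <= 0:
            raise ConfigError("activity_threshold must be positive")
        if self.response_arm not in ("MI", "LI", "either", "both"):
            raise ConfigError(f"unknown response_arm {self.response_arm!r}")


@dataclass
class SurveyMaps:
    imi_subscales: dict[str, list[int]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_IMI_SUBSCALES.items()}
    )
    imi_reverse_items: frozenset[int] = DEFAULT_IMI_REVERSE_ITEMS
    quest_item_labels: tuple[str, ...] = QUEST_ITEM_LABELS

    def __post_init__(self) -> None:
        seen: dict[int, str] = {}
        for sub, items in self.imi_subscales.items():
            for it in items:
                if it in seen:
                    raise ConfigError(f"IMI item {it} mapped to both {seen[it]} and {sub}")
                seen[it] = sub
        expected = set(range(1, 38))
        if set(seen) != expected:
            missing = sorted(expected - set(seen))
            extra = sorted(set(seen) - expected)
            raise ConfigError(f"IMI map must cover items 1-37 exactly (missing {missing}, extra {extra})")
        if not self.imi_reverse_items <= expected:
            raise ConfigError("IMI reverse items outside 1-37")
        if len(self.quest_item_labels) != 12:
            raise ConfigError("QUEST needs exactly 12 item labels")


@dataclass
class Config:
    schedule: SessionSchedule
    pipeline: PipelineParams
    surveys: SurveyMaps

    def to_dict(self) -> dict:
        d = {
            "schedule": {
                "window_start": self.schedule.window_start,
                "window_duration": self.schedule.window_duration,
                "session_starts": list(self.schedule.session_starts),
                "session_duration": self.schedule.session_duration,
                "inter_cue_interval": self.schedule.inter_cue_interval,
            },
            "pipeline": asdict(self.pipeline),
            "surveys": {
                "imi_subscales": {k: list(v) for k, v in self.surveys.imi_subscales.items()},
                "imi_reverse_items": sorted(self.surveys.imi_reverse_items),
                "quest_item_labels": list(self.surveys.quest_item_labels),
            },
        }
        d["pipeline"]["band_hz"] = list(self.pipeline.band_hz)
        return d


def default_config() -> Config:
    return Config(schedule=SessionSchedule(), pipeline=PipelineParams(), surveys=SurveyMaps())


def load_config(path: str | Path) -> Config:
    """Load a YAML config; absent optional keys fall back to defaults.

    ``schedule.session_starts`` is required — everything else has a default.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sched_raw = raw.get("schedule") or {}
    if "session_starts" not in sched_raw:
        raise ConfigError(f"{path}: schedule.session_starts is required")
    sched_fields = {
        k: sched_raw[k]
        for k in ("window_start", "window_duration", "session_starts",
                  "session_duration", "inter_cue_interval")
        if k in sched_raw
    }
    schedule = SessionSchedule(**sched_fields)

    pipe_raw = dict(raw.get("pipeline") or {})
    if "band_hz" in pipe_raw:
        pipe_raw["band_hz"] = tuple(float(v) for v in pipe_raw["band_hz"])
    pipeline = PipelineParams(**pipe_raw)

    surv_raw = raw.get("surveys") or {}
    kwargs = {}
    if "imi_subscales" in surv_raw:
        kwargs["imi_subscales"] = {k: list(v) for k, v in surv_raw["imi_subscales"].items()}
    if "imi_reverse_items" in surv_raw:
        kwargs["imi_reverse_items"] = frozenset(int(v) for v in surv_raw["imi_reverse_items"])
    if "quest_item_labels" in surv_raw:
        kwargs["quest_item_labels"] = tuple(surv_raw["quest_item_labels"])
    surveys = SurveyMaps(**kwargs)

    return Config(schedule=schedule, pipeline=pipeline, surveys=surveys)


def save_config(config: Config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def describe(config: Config) -> str:
    """Effective configuration as a YAML string (for logging/manifests)."""
    return yaml.safe_dump(config.to_dict(), sort_keys=True)
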