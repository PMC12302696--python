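"""Scoring for the three user-experience instruments.

SUS: 10 items on 1-5; odd (positively worded) items contribute score-1, even
(negatively worded) items 5-score; the total is scaled by 2.5 onto 0-100
(passable >= 68).  QUEST: mean of 12 items on 1-5 (midpoint 3), plus a tally
of each participant's three most-important items.  The 37-item intrinsic
motivation inventory: items on 1-7, reverse items mapped through 8-score,
averaged within six subscales (midpoint 4; pressure/tension is favourable
when low).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import SurveyMaps
from .io import read_survey_sheet
from .types import InvariantError

SUS_THRESHOLD = 68.0
QUEST_THRESHOLD = 3.0
IMI_THRESHOLD = 4.0


def _check_items(items: Sequence[int], n: int, lo: int, hi: int, name: str) -> np.ndarray:
    arr = np.asarray(items)
    if arr.shape != (n,):
        raise InvariantError(f"{name} needs exactly {n} items, got shape {arr.shape}")
    if np.any(pd.isna(arr)):
        raise InvariantError(f"{name}: missing item response (no imputation)")
    arr = arr.astype(int)
    if np.any((arr < lo) | (arr > hi)):
        raise InvariantError(f"{name}: item responses must be integers in [{lo}, {hi}]")
    return arr


@dataclass
class SurveyResponseSUS:
    participant_id: str
    items: np.ndarray  # 10 ints, 1-5

    def __post_init__(self) -> None:
        self.items = _check_items(self.items, 10, 1, 5, "SUS")


@dataclass
class SurveyResponseQUEST:
    participant_id: str
    items: np.ndarray  # 12 ints, 1-5
    importance_picks: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.items = _check_items(self.items, 12, 1, 5, "QUEST")
        self.importance_picks = frozenset(self.importance_picks)
        if self.importance_picks and len(self.importance_picks) != 3:
            raise InvariantError("importance_picks must hold exactly 3 distinct items")


@dataclass
class SurveyResponseIMI:
    participant_id: str
    items: np.ndarray  # 37 ints, 1-7

    def __post_init__(self) -> None:
        self.items = _check_items(self.items, 37, 1, 7, "IMI")


def score_sus(response: SurveyResponseSUS | Sequence[int]) -> float:
    """Standard SUS score in [0, 100]."""
    items = response.items if isinstance(response, SurveyResponseSUS) else \
        _check_items(response, 10, 1, 5, "SUS")
    odd = items[0::2]  # items 1,3,5,7,9 (positive)
    even = items[1::2]  # items 2,4,6,8,10 (negative)
    total = np.sum(odd - 1) + np.sum(5 - even)
    return float(total * 2.5)


def score_quest(
    response: SurveyResponseQUEST | Sequence[int], allow_missing: bool = False
) -> float:
    """Mean satisfaction across the 12 items, in [1, 5].

    With ``allow_missing`` the mean is taken over answered items only
    (NaN entries skipped); the default is to refuse incomplete sheets.
    """
    if isinstance(response, SurveyResponseQUEST):
        return float(np.mean(response.items))
    arr = np.asarray(response, dtype=float)
    if arr.shape != (12,):
        raise InvariantError(f"QUEST needs exactly 12 items, got shape {arr.shape}")
    if np.isnan(arr).any():
        if not allow_missing:
            raise InvariantError("QUEST: missing item response")
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            raise InvariantError("QUEST: no answered items")
    if np.any((arr < 1) | (arr > 5)):
        raise InvariantError("QUEST: item responses must be in [1, 5]")
    return float(np.mean(arr))


def quest_importance_tally(
    picks: Iterable[frozenset[str] | set[str]], labels: Sequence[str]
) -> dict[str, int]:
    """Count, per category, how often it was picked among each respondent's 3."""
    counts: Counter[str] = Counter({lab: 0 for lab in labels})
    for rec in picks:
        rec = frozenset(rec)
        if len(rec) != 3:
            raise InvariantError(f"importance picks must have exactly 3 members, got {sorted(rec)}")
        unknown = rec - set(labels)
        if unknown:
            raise InvariantError(f"unknown importance categories {sorted(unknown)}")
        counts.update(rec)
    return dict(counts)


def score_imi(
    response: SurveyResponseIMI | Sequence[int],
    maps: SurveyMaps | None = None,
) -> dict[str, float]:
    """Six subscale means in [1, 7]; reverse items transformed as 8 - score."""
    maps = maps or SurveyMaps()
    items = response.items if isinstance(response, SurveyResponseIMI) else \
        _check_items(response, 37, 1, 7, "IMI")
    adjusted = items.astype(float).copy()
    for it in maps.imi_reverse_items:
        adjusted[it - 1] = 8 - adjusted[it - 1]
    return {
        sub: float(np.mean([adjusted[i - 1] for i in item_nums]))
        for sub, item_nums in maps.imi_subscales.items()
    }


# ---------------------------------------------------------------------------
# sheet-level scoring


@dataclass
class ScoredSurveys:
    """Cohort survey scores keyed by participant id."""

    sus: dict[str, float] = field(default_factory=dict)
    quest: dict[str, float] = field(default_factory=dict)
    imi: dict[str, dict[str, float]] = field(default_factory=dict)
    quest_tally: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        pids = sorted(set(self.sus) | set(self.quest) | set(self.imi))
        rows = []
        for pid in pids:
            row: dict[str, object] = {"participant_id": pid}
            row["sus"] = self.sus.get(pid, np.nan)
            row["quest"] = self.quest.get(pid, np.nan)
            for sub, val in self.imi.get(pid, {}).items():
                row[f"imi_{sub}"] = val
            rows.append(row)
        return pd.DataFrame(rows)


def score_sheets(
    sus_path=None, quest_path=None, imi_path=None, maps: SurveyMaps | None = None
) -> ScoredSurveys:
    """Score survey sheet CSVs (one row per participant, one column per item)."""
    maps = maps or SurveyMaps()
    out = ScoredSurveys()
    if sus_path is not None:
        df = read_survey_sheet(sus_path, "sus", 10)
        for _, row in df.iterrows():
            items = row[[f"sus_{i:02d}" for i in range(1, 11)]].to_numpy()
            out.sus[row["participant_id"]] = score_sus(
                SurveyResponseSUS(row["participant_id"], items)
            )
    if quest_path is not None:
        df = read_survey_sheet(quest_path, "quest", 12,
                               extra=["pick_1", "pick_2", "pick_3"])
        picks_all = []
        for _, row in df.iterrows():
            items = row[[f"quest_{i:02d}" for i in range(1, 13)]].to_numpy()
            picks = frozenset(row[["pick_1", "pick_2", "pick_3"]])
            resp = SurveyResponseQUEST(row["participant_id"], items, picks)
            out.quest[row["participant_id"]] = score_quest(resp)
            picks_all.append(picks)
        out.quest_tally = quest_importance_tally(picks_all, maps.quest_item_labels)
    if imi_path is not None:
        df = read_survey_sheet(imi_path, "imi", 37)
        for _, row in df.iterrows():
            items = row[[f"imi_{i:02d}" for i in range(1, 38)]].to_numpy()
            out.imi[row["participant_id"]] = score_imi(
                SurveyResponseIMI(row["participant_id"], items), maps
            )
    return out
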