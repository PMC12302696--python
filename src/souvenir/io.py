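"""Readers and writers for the plain-text interchange formats.

Accelerometer logs and cue logs are header + comma-delimited columns;
timestamps are seconds since day start at millisecond precision.  Survey
sheets are one row per participant, one column per item.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    AccelStream,
    CueEventLog,
    EpochActivitySeries,
    InvariantError,
    SessionSchedule,
    Side,
)

ACCEL_COLUMNS = ["timestamp_s", "x_g", "y_g", "z_g"]
CUE_COLUMNS = ["timestamp_s"]


class LogParseError(ValueError):
    """A log file failed to parse; the message names the offending line."""


class EmptyStreamError(ValueError):
    """An accelerometer log contained no samples."""


def _read_numeric_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyStreamError(f"{path} is empty") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise LogParseError(f"{path}: missing required column(s) {missing}")
    out = {}
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise LogParseError(
                f"{path}: malformed value {df[col].iloc[bad[0]]!r} in column "
                f"{col!r} at line {bad[0] + 2}"
            )
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise LogParseError(f"{path}: empty value in column {col!r} at line {row + 2}")
        out[col] = vals.to_numpy(dtype=float)
    return pd.DataFrame(out)


def read_accel_log(path: str | Path, side: Side, sort: bool = False) -> AccelStream:
    """Read a wrist accelerometer CSV into an :class:`AccelStream`.

    Parameters
    ----------
    path
        CSV with columns ``timestamp_s, x_g, y_g, z_g``.
    side
        Which wrist the log belongs to (``"MI"`` or ``"LI"``).
    sort
        If True, out-of-order rows are sorted instead of rejected.
        Duplicate timestamps are always rejected.
    """
    df = _read_numeric_table(path, ACCEL_COLUMNS)
    if df.empty:
        raise EmptyStreamError(f"{path} contains no samples")
    t = df["timestamp_s"].to_numpy()
    order = np.arange(len(t))
    dt = np.diff(t)
    if np.any(dt == 0):
        row = int(np.flatnonzero(dt == 0)[0])
        raise LogParseError(f"{path}: duplicated timestamp at line {row + 3}")
    if np.any(dt < 0):
        if not sort:
            row = int(np.flatnonzero(dt < 0)[0])
            raise LogParseError(
                f"{path}: out-of-order timestamp at line {row + 3} (pass sort=True to sort)"
            )
        order = np.argsort(t, kind="stable")
        t = t[order]
        if np.any(np.diff(t) == 0):
            raise LogParseError(f"{path}: duplicated timestamp after sorting")
    return AccelStream(
        side=side,
        t=t,
        x=df["x_g"].to_numpy()[order],
        y=df["y_g"].to_numpy()[order],
        z=df["z_g"].to_numpy()[order],
    )


def write_accel_log(stream: AccelStream, path: str | Path) -> None:
    """Write an accelerometer stream as CSV (ms timestamps, 1e-6 g values)."""
    arr = np.column_stack([stream.t, stream.x, stream.y, stream.z])
    header = ",".join(ACCEL_COLUMNS)
    np.savetxt(
        path, arr, fmt=["%.3f", "%.6f", "%.6f", "%.6f"],
        delimiter=",", header=header, comments="",
    )


def read_cue_log(
    path: str | Path,
    schedule: SessionSchedule,
    reject_out_of_session: bool = False,
) -> CueEventLog:
    """Read a cue-event CSV and index cues against the session schedule.

    ``cue_index_in_day`` is assigned by temporal order (1-based).  Cues
    outside every scheduled session are flagged (``out_of_session``) or
    dropped when ``reject_out_of_session`` is set.  More cues than the
    schedule allows is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = _read_numeric_table(path, CUE_COLUMNS)
    except EmptyStreamError:
        return CueEventLog(t=np.array([]), session_index=np.array([], dtype=int),
                           cue_index_in_day=np.array([], dtype=int))
    t = df["timestamp_s"].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise LogParseError(f"{path}: cue timestamps not increasing at line {row + 3}")
    if len(t) > schedule.cue_count():
        raise LogParseError(
            f"{path}: {len(t)} cues exceed the scheduled maximum of {schedule.cue_count()}"
        )
    sessions = np.array([schedule.session_of(float(v)) or 0 for v in t], dtype=int)
    flagged = sessions == 0
    if reject_out_of_session and flagged.any():
        t, sessions, flagged = t[~flagged], sessions[~flagged], flagged[~flagged]
    return CueEventLog(
        t=t,
        session_index=sessions,
        cue_index_in_day=np.arange(1, len(t) + 1),
        out_of_session=flagged,
    )


def write_cue_log(log: CueEventLog, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CUE_COLUMNS)
        for v in log.t:
            w.writerow([f"{v:.3f}"])


def write_epoch_series(
    mi: EpochActivitySeries, li: EpochActivitySeries, path: str | Path
) -> None:
    """Write the paired per-second epoch series as CSV."""
    if len(mi) != len(li) or not np.array_equal(mi.epoch_start_times, li.epoch_start_times):
        raise InvariantError("MI and LI epoch series are not aligned")
    df = pd.DataFrame(
        {
            "epoch_start_s": mi.epoch_start_times,
            "mi_sum": mi.magnitude_sum,
            "li_sum": li.magnitude_sum,
            "mi_active": mi.active.astype(int),
            "li_active": li.active.astype(int),
            "mi_missing": mi.missing.astype(int),
            "li_missing": li.missing.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_epoch_series(
    path: str | Path, threshold: float
) -> tuple[EpochActivitySeries, EpochActivitySeries]:
    df = pd.read_csv(path)
    out = []
    for side in ("mi", "li"):
        out.append(
            EpochActivitySeries(
                side=side.upper(),  # type: ignore[arg-type]
                epoch_start_times=df["epoch_start_s"].to_numpy(dtype=int),
                magnitude_sum=df[f"{side}_sum"].to_numpy(dtype=float),
                active=df[f"{side}_active"].to_numpy(dtype=bool),
                missing=df[f"{side}_missing"].to_numpy(dtype=bool),
                threshold=threshold,
            )
        )
    return out[0], out[1]


def read_survey_sheet(
    path: str | Path, prefix: str, n_items: int, extra: Optional[list[str]] = None
) -> pd.DataFrame:
    """Read a one-row-per-participant survey sheet.

    Item columns are ``{prefix}_01 .. {prefix}_{n_items:02d}``; ``extra``
    names additional required columns (e.g. importance picks).
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    cols = [f"{prefix}_{i:02d}" for i in range(1, n_items + 1)]
    missing = [c for c in ["participant_id", *cols, *(extra or [])] if c not in df.columns]
    if missing:
        raise LogParseError(f"{path}: missing survey column(s) {missing}")
    return df
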