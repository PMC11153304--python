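"""Wear-day screening and participant-level daily averaging.

Day-level monitor summaries (one row per worn day, with stepping broken into
cadence epochs) are reduced to one average daily composition per participant:

* the first measured day is dropped (it coincides with the clinic visit);
* the final day is dropped when it holds <= 14 h of recorded information;
* remaining days must contain >= 14 h (840 min) of waking time;
* stepping epochs split into LPA (< 100 steps/min) and MVPA (>= 100 steps/min);
* behaviours are averaged arithmetically over valid days and sleep is the
  complement of average waking time in 24 h.

Participants with no valid day, or a behaviour averaging to zero, are
excluded with an explicit reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .composition import PARTS, TOTAL_MINUTES, ZeroPartError, close

__all__ = [
    "DayRecord",
    "ParticipantInvalidError",
    "filter_valid_days",
    "cadence_split",
    "average_daily_composition",
    "aggregate_participants",
]

#: Cadence cut separating light from moderate-to-vigorous stepping, steps/min.
MVPA_CADENCE = 100.0

#: Minimum waking minutes for a day to count as valid (14 h).
MIN_WAKING_MINUTES = 840.0

#: Recorded-information threshold (hours) below/at which the last day is dropped.
LAST_DAY_MAX_HOURS = 14.0


class ParticipantInvalidError(ValueError):
    """No analysable wear days remain for this participant."""


@dataclass(frozen=True)
class DayRecord:
    """One monitored day: posture totals plus stepping epochs with cadence."""

    day_index: int
    recorded_hours: float
    waking_minutes: float
    sitting_minutes: float
    standing_minutes: float
    stepping_epochs: tuple[tuple[float, float], ...] = ()  # (minutes, steps/min)
    is_last_day: bool = False

    def __post_init__(self):
        for dur, cad in self.stepping_epochs:
            if dur < 0:
                raise ValueError(f"negative epoch duration {dur} on day {self.day_index}")
            if cad < 0:
                raise ValueError(f"negative cadence {cad} on day {self.day_index}")
        stepping = sum(d for d, _ in self.stepping_epochs)
        classified = self.sitting_minutes + self.standing_minutes + stepping
        if classified > self.waking_minutes + 1.0:
            raise ValueError(
                f"day {self.day_index}: classified behaviour ({classified:.1f} min) "
                f"exceeds waking time ({self.waking_minutes:.1f} min) beyond tolerance"
            )


def filter_valid_days(days: Sequence[DayRecord]) -> list[DayRecord]:
    """Apply the wear-day validity rules, preserving day order.

    Raises :class:`ParticipantInvalidError` when nothing survives.
    """
    days = list(days)
    idx = [d.day_index for d in days]
    if len(set(idx)) != len(idx) or idx != sorted(idx):
        raise ValueError("day_index values must be unique and ordered")
    last_index = max((d.day_index for d in days if d.is_last_day), default=idx[-1] if idx else None)
    kept = []
    for d in days:
        if d.day_index == 1:
            continue
        if d.day_index == last_index and d.recorded_hours <= LAST_DAY_MAX_HOURS:
            continue
        if d.waking_minutes < MIN_WAKING_MINUTES:
            continue
        kept.append(d)
    if not kept:
        raise ParticipantInvalidError("no valid wear day (>=14 h waking) remains")
    return kept


def cadence_split(
    epochs: Iterable[tuple[float, float]], cutoff: float = MVPA_CADENCE
) -> tuple[float, float]:
    """Split stepping epochs into (LPA, MVPA) minutes at the cadence cutoff.

    Epochs at exactly the cutoff count as MVPA. Conserves total minutes.
    """
    lpa = mvpa = 0.0
    for dur, cad in epochs:
        if dur < 0:
            raise ValueError(f"negative epoch duration {dur}")
        if cad >= cutoff:
            mvpa += dur
        else:
            lpa += dur
    return lpa, mvpa


def average_daily_composition(
    valid_days: Sequence[DayRecord], residual: str = "scale"
) -> np.ndarray:
    """Average valid days into one closed 1440-min composition.

    Waking time may exceed the sum of classified behaviours (monitor
    non-classified remainder); with ``residual='scale'`` the shortfall is
    spread proportionally over the four waking behaviours so the 24 h
    identity holds, with ``residual='error'`` any shortfall > 1 min raises.
    """
    if not valid_days:
        raise ParticipantInvalidError("no valid days to average")
    if residual not in ("scale", "error"):
        raise ValueError("residual must be 'scale' or 'error'")
    sit = float(np.mean([d.sitting_minutes for d in valid_days]))
    stand = float(np.mean([d.standing_minutes for d in valid_days]))
    splits = [cadence_split(d.stepping_epochs) for d in valid_days]
    lpa = float(np.mean([s[0] for s in splits]))
    mvpa = float(np.mean([s[1] for s in splits]))
    waking = float(np.mean([d.waking_minutes for d in valid_days]))
    sleeping = TOTAL_MINUTES - waking

    classified = sit + stand + lpa + mvpa
    if classified <= 0:
        raise ZeroPartError("all waking behaviours average to zero")
    if abs(classified - waking) > 1.0 and residual == "error":
        raise ValueError(
            f"classified waking behaviours ({classified:.1f} min) differ from "
            f"waking time ({waking:.1f} min) by more than 1 min"
        )
    scale = waking / classified
    parts = np.array([sit * scale, stand * scale, lpa * scale, mvpa * scale, sleeping])
    if np.any(parts <= 0):
        bad = PARTS[int(np.argmin(parts))]
        raise ZeroPartError(f"behaviour '{bad}' averages to zero; participant excluded")
    return close(parts, TOTAL_MINUTES)


def aggregate_participants(
    days: pd.DataFrame, epochs: pd.DataFrame, residual: str = "scale"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reduce day-level tables to participant compositions.

    ``days``: participant_id, day_index, recorded_hours, waking_minutes,
    sitting_minutes, standing_minutes, is_last_day. ``epochs`` (long format):
    participant_id, day_index, duration_min, cadence.

    Returns (compositions, exclusions); compositions has the five canonical
    behaviour columns plus n_valid_days, exclusions has participant_id and
    reason.
    """
    rows, excl = [], []
    epochs_by_key: dict[tuple, list[tuple[float, float]]] = {}
    for (pid, di), grp in epochs.groupby(["participant_id", "day_index"], sort=False):
        epochs_by_key[(pid, di)] = list(zip(grp["duration_min"], grp["cadence"]))
    for pid, grp in days.groupby("participant_id", sort=False):
        grp = grp.sort_values("day_index")
        recs = [
            DayRecord(
                day_index=int(r.day_index),
                recorded_hours=float(r.recorded_hours),
                waking_minutes=float(r.waking_minutes),
                sitting_minutes=float(r.sitting_minutes),
                standing_minutes=float(r.standing_minutes),
                stepping_epochs=tuple(epochs_by_key.get((pid, int(r.day_index)), ())),
                is_last_day=bool(r.is_last_day),
            )
            for r in grp.itertuples()
        ]
        try:
            valid = filter_valid_days(recs)
            comp = average_daily_composition(valid, residual=residual)
        except (ParticipantInvalidError, ZeroPartError) as e:
            excl.append({"participant_id": pid, "reason": str(e)})
            continue
        row = {"participant_id": pid, "n_valid_days": len(valid)}
        row.update(dict(zip(PARTS, comp)))
        rows.append(row)
    comp_df = pd.DataFrame(rows, columns=["participant_id", "n_valid_days", *PARTS])
    excl_df = pd.DataFrame(excl, columns=["participant_id", "reason"])
    return comp_df, excl_df
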