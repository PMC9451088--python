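"""CSV ingestion for time-use datasets.

Two layouts are supported:

* participant-level (wide): one row per participant with the 7 activity
  columns (min/day), covariates and outcomes — the layout ``simulate`` writes
  and ``fit`` consumes;
* day-level: one row per participant-day with columns ``id``, ``day_type``
  (weekday/weekend) and the 7 activity columns, aggregated to weekly
  compositions with the 5:2 weekday:weekend weighting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .coda import DAY_MINUTES, PART_NAMES, weighted_weekly_composition

log = logging.getLogger(__name__)

#: Daily totals further than this from the closure constant are dropped, not
#: silently renormalised.
TOTAL_TOLERANCE_MINUTES = 1.0


def read_participant_csv(path) -> pd.DataFrame:
    """Read a wide participant-level CSV, validating the activity columns."""
    df = pd.read_csv(path)
    missing = [p for p in PART_NAMES if p not in df.columns]
    if missing:
        raise ValueError(f"missing activity columns: {missing}")
    vals = df[list(PART_NAMES)].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative activity durations in input")
    return df


def daily_to_weekly(daily: pd.DataFrame, total: float = DAY_MINUTES
                    ) -> tuple[pd.DataFrame, dict]:
    """Aggregate a day-level table to one weekly composition per participant.

    Participants are dropped (and reported) when a day type is absent, a
    duration is negative, or a day's total is off the closure constant by more
    than ±1 min. Returns (weekly table indexed by id, drop report).
    """
    required = ["id", "day_type", *PART_NAMES]
    missing = [c for c in required if c not in daily.columns]
    if missing:
        raise ValueError(f"missing columns in day-level table: {missing}")
    weekly_rows = []
    dropped: dict[str, list] = {"bad_total": [], "negative": [], "missing_day_type": []}
    for pid, grp in daily.groupby("id", sort=True):
        vals = grp[list(PART_NAMES)].to_numpy(dtype=float)
        if np.any(vals < 0):
            dropped["negative"].append(pid)
            continue
        if np.any(np.abs(vals.sum(axis=1) - total) > TOTAL_TOLERANCE_MINUTES):
            dropped["bad_total"].append(pid)
            continue
        types = grp["day_type"].tolist()
        try:
            comp = weighted_weekly_composition(vals, types, total=total)
        except ValueError:
            dropped["missing_day_type"].append(pid)
            continue
        weekly_rows.append([pid, *comp.values])
    for reason, ids in dropped.items():
        if ids:
            log.warning("dropped %d participants (%s): %s", len(ids), reason, ids)
    weekly = pd.DataFrame(weekly_rows, columns=["id", *PART_NAMES])
    return weekly, dropped
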