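"""Walking-bout-duration aggregation: bout -> day -> week hierarchy.

Each gait characteristic is averaged over a day's qualifying bouts
(unweighted), then over the contributing days, separately for each of the
14 duration conditions plus the all-bout and lab conditions.  Duration bins
are half-open intervals (lower, upper]; the cumulative (``le*``) and range
bins overlap by design, while {le10, gt10le30, gt30le60, gt60le120, gt120}
form a disjoint partition of all positive durations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .characteristics import CHARACTERISTICS

INF = math.inf


@dataclass(frozen=True)
class DurationBin:
    label: str
    lower: float  # exclusive
    upper: float  # inclusive (may be inf)

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("bin lower bound must be below upper bound")

    def contains(self, duration: float) -> bool:
        return self.lower < duration <= self.upper


DURATION_BINS: list[DurationBin] = [
    DurationBin("le5", 0.0, 5.0),
    DurationBin("le10", 0.0, 10.0),
    DurationBin("le30", 0.0, 30.0),
    DurationBin("le60", 0.0, 60.0),
    DurationBin("le90", 0.0, 90.0),
    DurationBin("le120", 0.0, 120.0),
    DurationBin("gt5le10", 5.0, 10.0),
    DurationBin("gt10le30", 10.0, 30.0),
    DurationBin("gt30le60", 30.0, 60.0),
    DurationBin("gt60le90", 60.0, 90.0),
    DurationBin("gt60le120", 60.0, 120.0),
    DurationBin("gt90le120", 90.0, 120.0),
    DurationBin("gt60", 60.0, INF),
    DurationBin("gt120", 120.0, INF),
]

BIN_BY_LABEL = {b.label: b for b in DURATION_BINS}

# disjoint partition of (0, inf) used for the conservation identity
PARTITION_LABELS = ["le10", "gt10le30", "gt30le60", "gt60le120", "gt120"]

CONDITIONS = ["lab", "all_wb", "le5", "le10", "le30", "le60", "le90", "le120",
              "gt5le10", "gt10le30", "gt30le60", "gt60le90", "gt60le120",
              "gt90le120", "gt60", "gt120"]

NESTED_LE_ORDER = ["le5", "le10", "le30", "le60", "le90", "le120"]


def assign_bins(duration: float) -> list[DurationBin]:
    """Every bin whose (lower, upper] interval contains ``duration``."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return [b for b in DURATION_BINS if b.contains(duration)]


def aggregate_participant(per_bout: pd.DataFrame,
                          bins: list[DurationBin] | None = None,
                          step_weighted: bool = False) -> pd.DataFrame:
    """Aggregate one participant's per-bout table into condition rows.

    ``per_bout`` needs columns day, duration_s, n_steps and the 14
    characteristics.  For each condition the day's qualifying bouts are
    averaged (unweighted by default; ``step_weighted`` weights bouts by
    their step count), then the daily means are averaged over contributing
    days.  A condition with no qualifying bout yields NaN cells.
    """
    bins = DURATION_BINS if bins is None else bins
    rows = []
    for label, sub in [("all_wb", per_bout)] + [
            (b.label, per_bout[per_bout["duration_s"].gt(b.lower)
                               & per_bout["duration_s"].le(b.upper)])
            for b in bins]:
        row = {"condition": label, "n_bouts": int(len(sub)),
               "n_days": int(sub["day"].nunique()) if len(sub) else 0}
        if len(sub):
            if step_weighted:
                daily = sub.groupby("day").apply(
                    lambda d: pd.Series({c: _wmean(d[c], d["n_steps"])
                                         for c in CHARACTERISTICS}),
                    include_groups=False)
            else:
                daily = sub.groupby("day")[CHARACTERISTICS].mean()
            week = daily.mean(axis=0)  # unweighted across days
            row.update(week.to_dict())
        else:
            row.update({c: np.nan for c in CHARACTERISTICS})
        rows.append(row)
    return pd.DataFrame(rows)


def _wmean(x: pd.Series, w: pd.Series) -> float:
    ok = x.notna()
    if not ok.any():
        return np.nan
    return float(np.average(x[ok], weights=w[ok]))


def aggregate_cohort(per_bout: pd.DataFrame, lab: pd.DataFrame,
                     step_weighted: bool = False) -> pd.DataFrame:
    """Build the participant x condition aggregated table for a cohort.

    ``per_bout``: real-world per-bout characteristics with participant_id,
    group, day, duration_s, n_steps columns.  ``lab``: one row per
    participant with the same characteristic columns (the single 2-min lab
    bout).  Returns rows keyed by (participant_id, group, condition).
    """
    out = []
    participants = lab[["participant_id", "group"]].drop_duplicates()
    for _, prow in participants.iterrows():
        pid, grp = prow["participant_id"], prow["group"]
        lrow = lab[lab["participant_id"] == pid].iloc[0]
        out.append({"participant_id": pid, "group": grp, "condition": "lab",
                    "n_bouts": 1, "n_days": 1,
                    **{c: lrow[c] for c in CHARACTERISTICS}})
        sub = per_bout[per_bout["participant_id"] == pid]
        if len(sub):
            agg = aggregate_participant(sub, step_weighted=step_weighted)
            for _, arow in agg.iterrows():
                out.append({"participant_id": pid, "group": grp, **arow.to_dict()})
        else:
            for cond in CONDITIONS[1:]:
                out.append({"participant_id": pid, "group": grp,
                            "condition": cond, "n_bouts": 0, "n_days": 0,
                            **{c: np.nan for c in CHARACTERISTICS}})
    df = pd.DataFrame(out)
    df["condition"] = pd.Categorical(df["condition"], categories=CONDITIONS,
                                     ordered=True)
    return df.sort_values(["participant_id", "condition"]).reset_index(drop=True)
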