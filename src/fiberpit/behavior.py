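"""Elevation-ratio scoring of conditional approach and PIT lever choice.

The elevation ratio cs/(cs + pre) compares responding during a cue window
to the 2-min baseline immediately before cue onset; 0.5 is the
indifference point.  For Pavlovian acquisition the response is the rate of
food-port entries during the cue probe period (after onset, before the
first reward delivery).  For the PIT test, lever presses during each cue
are split into presses on the lever that earned the same outcome as the
presented cue (Same) versus the other lever (Different), each scored
against its own pre-cue baseline; food-port entries during the cue are
scored the same way.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ContingencyMap, EventLog, SessionSchedule

logger = logging.getLogger(__name__)

PRE_WINDOW_S = 120.0  # 2-min baseline immediately prior to cue onset


@dataclass
class ElevationScore:
    """cs/(cs + pre) elevation statistic; NaN ratio when both terms are 0."""

    cs_rate_per_min: float
    pre_rate_per_min: float
    ratio: float

    @classmethod
    def from_rates(cls, cs: float, pre: float) -> "ElevationScore":
        total = cs + pre
        ratio = cs / total if total > 0 else math.nan
        return cls(cs_rate_per_min=cs, pre_rate_per_min=pre, ratio=ratio)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ratio)


@dataclass
class PITResult:
    """Subject-level PIT summary: Same/Different lever and food-port ratios."""

    same_ratio: ElevationScore
    different_ratio: ElevationScore
    foodport_ratio: ElevationScore
    press_counts: pd.DataFrame    # per trial x lever x period counts
    contingency: ContingencyMap


def entry_rate(
    log: EventLog, kind: str, window: tuple, label: str | None = None
) -> float:
    """Events per minute of the given kind within ``[start_s, end_s)``."""
    start, end = window
    if end <= start:
        raise ValueError(f"inverted window [{start}, {end})")
    times = log.times(kind, label)
    count = int(np.count_nonzero((times >= start) & (times < end)))
    return count / ((end - start) / 60.0)


def _mean_defined(ratios) -> float:
    """Mean of the defined (non-NaN) ratios; NaN if none are defined."""
    vals = [r for r in ratios if not math.isnan(r)]
    return float(np.mean(vals)) if vals else math.nan


def _across_cs_mean(per_trial: pd.DataFrame, col: str = "ratio") -> float:
    """Average ``col`` across trials within each cue, then across cues."""
    cs_means = per_trial.groupby("cs_id")[col].apply(
        lambda s: _mean_defined(s.to_list())
    )
    return _mean_defined(cs_means.to_list())


def pavlovian_elevation(
    schedule: SessionSchedule, log: EventLog
) -> tuple:
    """Elevation ratio of food-port approach during the cue probe period.

    Per trial: probe entry rate over [onset, first delivery) (cue offset if
    unrewarded) against the entry rate over the 2 min immediately before
    onset; ratio = probe/(probe + pre).  Trials whose baseline window would
    precede the session start are flagged and skipped.  Returns
    ``(per_trial_table, session_ratio)`` where the session ratio averages
    across trials within each cue and then across the two cues.
    """
    if not schedule.trials:
        raise ValueError("schedule has no trials")
    rows = []
    for idx, trial in enumerate(schedule.trials):
        pre_start = trial.onset_s - PRE_WINDOW_S
        if pre_start < 0:
            logger.info("pavlovian_elevation: trial %d skipped "
                        "(baseline precedes session start)", idx)
            continue
        rewards = sorted(trial.reward_times_s)
        probe_end = rewards[0] if rewards else trial.offset_s
        if probe_end <= trial.onset_s:
            logger.info("pavlovian_elevation: trial %d skipped "
                        "(empty probe window)", idx)
            continue
        cs_rate = entry_rate(log, "foodport_entry", (trial.onset_s, probe_end))
        pre_rate = entry_rate(log, "foodport_entry", (pre_start, trial.onset_s))
        score = ElevationScore.from_rates(cs_rate, pre_rate)
        rows.append(
            {
                "trial": idx,
                "cs_id": trial.cs_id,
                "cs_rate_per_min": cs_rate,
                "pre_rate_per_min": pre_rate,
                "ratio": score.ratio,
            }
        )
    per_trial = pd.DataFrame(
        rows, columns=["trial", "cs_id", "cs_rate_per_min",
                       "pre_rate_per_min", "ratio"]
    )
    if per_trial.empty:
        raise ValueError("no scorable trials in session")
    return per_trial, _across_cs_mean(per_trial)


def classify_same_lever(cs_id: str, contingency: ContingencyMap) -> str:
    """The lever that, during training, earned the outcome this cue predicts."""
    if cs_id not in contingency.cs_to_outcome:
        raise KeyError(f"cs_id {cs_id!r} not in contingency")
    return contingency.outcome_to_lever()[contingency.cs_to_outcome[cs_id]]


def pit_lever_scores(
    schedule: SessionSchedule, log: EventLog, contingency: ContingencyMap
) -> PITResult:
    """Same/Different lever elevation ratios for a PIT test session.

    Per trial, presses are counted over the cue window [onset, offset) and
    the 2-min baseline [onset - 120 s, onset), split by whether the lever
    matches the presented cue's trained outcome; ratios
    count_cs/(count_cs + count_pre) are averaged across trials then cues.
    Trials whose baseline would start before the extinction period has run
    120 s are flagged and skipped.
    """
    rows, count_rows = [], []
    for idx, trial in enumerate(schedule.trials):
        pre_start = trial.onset_s - PRE_WINDOW_S
        if pre_start < 0:
            logger.info("pit_lever_scores: trial %d skipped "
                        "(baseline precedes session start)", idx)
            continue
        same = classify_same_lever(trial.cs_id, contingency)
        counts = {}
        for lever in contingency.lever_to_outcome:
            presses = log.times("lever_press", lever)
            cs_n = int(np.count_nonzero(
                (presses >= trial.onset_s) & (presses < trial.offset_s)))
            pre_n = int(np.count_nonzero(
                (presses >= pre_start) & (presses < trial.onset_s)))
            role = "same" if lever == same else "different"
            counts[role] = (cs_n, pre_n)
            count_rows.append(
                {"trial": idx, "cs_id": trial.cs_id, "lever": lever,
                 "role": role, "cs_presses": cs_n, "pre_presses": pre_n}
            )
        row = {"trial": idx, "cs_id": trial.cs_id}
        for role in ("same", "different"):
            cs_n, pre_n = counts[role]
            row[f"{role}_ratio"] = ElevationScore.from_rates(cs_n, pre_n).ratio
            row[f"{role}_cs"] = cs_n
            row[f"{role}_pre"] = pre_n
        rows.append(row)
    if not rows:
        raise ValueError("no scorable PIT trials")
    per_trial = pd.DataFrame(rows)

    def _score(role: str) -> ElevationScore:
        ratio = _across_cs_mean(per_trial, f"{role}_ratio")
        # summary rates: total presses over total window time, per minute
        window_min = len(per_trial) * (
            schedule.trials[0].offset_s - schedule.trials[0].onset_s
        ) / 60.0
        pre_min = len(per_trial) * PRE_WINDOW_S / 60.0
        return ElevationScore(
            cs_rate_per_min=per_trial[f"{role}_cs"].sum() / window_min,
            pre_rate_per_min=per_trial[f"{role}_pre"].sum() / pre_min,
            ratio=ratio,
        )

    foodport = pit_foodport_score(schedule, log)
    return PITResult(
        same_ratio=_score("same"),
        different_ratio=_score("different"),
        foodport_ratio=foodport,
        press_counts=pd.DataFrame(count_rows),
        contingency=contingency,
    )


def pit_foodport_score(schedule: SessionSchedule, log: EventLog) -> ElevationScore:
    """Food-port elevation ratio for the PIT test.

    Entries counted over the full cue window and the 2-min pre-cue
    baseline; ratio entries_cs/(entries_cs + entries_pre) per trial,
    averaged across trials then cues; 0/0 trials are excluded.
    """
    rows = []
    total_cs = total_pre = 0
    for idx, trial in enumerate(schedule.trials):
        pre_start = trial.onset_s - PRE_WINDOW_S
        if pre_start < 0:
            continue
        entries = log.times("foodport_entry")
        cs_n = int(np.count_nonzero(
            (entries >= trial.onset_s) & (entries < trial.offset_s)))
        pre_n = int(np.count_nonzero(
            (entries >= pre_start) & (entries < trial.onset_s)))
        total_cs += cs_n
        total_pre += pre_n
        rows.append(
            {"trial": idx, "cs_id": trial.cs_id,
             "ratio": ElevationScore.from_rates(cs_n, pre_n).ratio}
        )
    if not rows:
        raise ValueError("no scorable PIT trials")
    per_trial = pd.DataFrame(rows)
    n = len(per_trial)
    cs_minutes = n * (schedule.trials[0].offset_s - schedule.trials[0].onset_s) / 60.0
    pre_minutes = n * PRE_WINDOW_S / 60.0
    return ElevationScore(
        cs_rate_per_min=total_cs / cs_minutes,
        pre_rate_per_min=total_pre / pre_minutes,
        ratio=_across_cs_mean(per_trial),
    )
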