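"""Peri-event alignment and per-trial peak/AUC quantification.

Z-scored traces are aligned to cue onset, reward delivery, reward
retrieval (first food-port entry at or after a delivery) and unrewarded
probe entries; peak and trapezoidal AUC are computed per trial over a 3-s
post-event window and the immediately preceding 3-s baseline, then
averaged across trials, across cues, and across two-session bins of the
conditioning sequence (1, 2, 3/4, 5/6, 7/8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CorrectedTrace, EventLog, SessionSchedule

logger = logging.getLogger(__name__)

#: conditioning-session bins used for the across-training comparison
SESSION_BINS = ((1,), (2,), (3, 4), (5, 6), (7, 8))
BIN_LABELS = ("1", "2", "3/4", "5/6", "7/8")

MEASURES = ("peak_pre", "peak_post", "auc_pre", "auc_post")


@dataclass
class DerivedEvents:
    """Event times derived from a schedule plus its behavioral log."""

    cs_onsets: dict                      # cs_id -> list of onset times
    reward_deliveries: list              # (time_s, outcome_id, trial_idx)
    reward_retrievals: list              # (time_s, delivery_time_s, trial_idx)
    probe_entries: list                  # entry times before first delivery


@dataclass
class PeriEventTensor:
    """Trials x samples matrix of zdff around one event class."""

    event_kind: str
    window_pre_s: float
    window_post_s: float
    data: np.ndarray
    relative_time_s: np.ndarray
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def derive_events(schedule: SessionSchedule, log: EventLog) -> DerivedEvents:
    """Derive alignment events from the schedule and the event log.

    A reward retrieval is the first food-port entry at or after a delivery
    (inclusive boundary) and before the next delivery of that trial or the
    session end; deliveries with no qualifying entry yield no retrieval.
    Probe entries are food-port entries between cue onset and that trial's
    first delivery (cue offset if there is none).
    """
    log_onsets = log.times("cs_on")
    sched_onsets = np.array([t.onset_s for t in schedule.trials if t.cs_id])
    if log_onsets.size != sched_onsets.size or not np.allclose(
        log_onsets, sched_onsets
    ):
        raise ValueError("cs_on markers in the log do not match the schedule")

    entries = log.times("foodport_entry")
    cs_onsets: dict = {}
    deliveries, retrievals, probes = [], [], []
    for idx, trial in enumerate(schedule.trials):
        if trial.cs_id:
            cs_onsets.setdefault(trial.cs_id, []).append(trial.onset_s)
        rewards = sorted(trial.reward_times_s)
        for i, r in enumerate(rewards):
            deliveries.append((r, trial.outcome_id, idx))
            upper = rewards[i + 1] if i + 1 < len(rewards) else log.end_s
            cand = entries[(entries >= r) & (entries < upper)]
            if cand.size:
                retrievals.append((float(cand[0]), r, idx))
        probe_end = rewards[0] if rewards else trial.offset_s
        in_probe = entries[(entries >= trial.onset_s) & (entries < probe_end)]
        probes.extend(float(t) for t in in_probe)
    return DerivedEvents(
        cs_onsets=cs_onsets,
        reward_deliveries=deliveries,
        reward_retrievals=retrievals,
        probe_entries=probes,
    )


def extract_peri_event(
    trace: CorrectedTrace,
    event_times,
    window_pre_s: float = 3.0,
    window_post_s: float = 3.0,
    event_kind: str = "event",
) -> PeriEventTensor:
    """Cut zdff snippets around each event on the trace's own grid.

    Events whose full window falls outside the recording are dropped (the
    count is logged and recorded on the tensor).  An empty event list gives
    an empty tensor.
    """
    t = np.asarray(trace.time_s)
    dt = float(np.median(np.diff(t)))
    n_pre = int(round(window_pre_s / dt))
    n_post = int(round(window_post_s / dt))
    rel = np.arange(-n_pre, n_post + 1) * dt

    rows, dropped = [], 0
    for e in np.sort(np.asarray(event_times, dtype=float)):
        i0 = int(np.searchsorted(t, e, side="left"))
        lo, hi = i0 - n_pre, i0 + n_post
        if lo < 0 or hi >= len(t) or i0 >= len(t):
            dropped += 1
            continue
        rows.append(trace.zdff[lo : hi + 1])
    if dropped:
        logger.info("extract_peri_event(%s): dropped %d event(s) with "
                    "truncated windows", event_kind, dropped)
    data = np.vstack(rows) if rows else np.empty((0, len(rel)))
    return PeriEventTensor(
        event_kind=event_kind,
        window_pre_s=window_pre_s,
        window_post_s=window_post_s,
        data=data,
        relative_time_s=rel,
        n_dropped=dropped,
    )


def quantify_trial(tensor: PeriEventTensor) -> pd.DataFrame:
    """Per-trial peak and AUC over the pre and post windows.

    ``peak_post`` is the maximum of zdff over (0, +post]; ``peak_pre`` over
    [-pre, 0); AUCs are trapezoidal integrals over [-pre, 0] and [0, +post]
    (the event sample is the shared integration boundary), in Z*s.  No
    baseline subtraction is performed inside the windows: the pre-event
    values are the comparison baseline downstream.
    """
    if tensor.n_trials == 0:
        raise ValueError("cannot quantify an empty peri-event tensor")
    rel = tensor.relative_time_s
    pre_peak = rel < 0
    post_peak = rel > 0
    pre_auc = rel <= 0
    post_auc = rel >= 0
    rows = []
    for row in tensor.data:
        rows.append(
            {
                "peak_pre": float(row[pre_peak].max()),
                "peak_post": float(row[post_peak].max()),
                "auc_pre": float(np.trapezoid(row[pre_auc], rel[pre_auc])),
                "auc_post": float(np.trapezoid(row[post_auc], rel[post_auc])),
            }
        )
    return pd.DataFrame(rows)


def average_trials(tables_per_cs: dict) -> pd.Series:
    """Average measures across trials within each cue, then across cues.

    The across-cue average is unweighted, so unequal trial counts between
    cues do not bias the session summary.
    """
    cs_means = [
        table[list(MEASURES)].mean() for table in tables_per_cs.values() if len(table)
    ]
    if not cs_means:
        raise ValueError("no usable trials to average")
    return pd.concat(cs_means, axis=1).mean(axis=1)


@dataclass
class BinnedSummary:
    """Subject x bin summary table plus the inclusion bookkeeping."""

    table: pd.DataFrame                  # columns: subject, bin, measures
    included_subjects: list
    excluded_subjects: list = field(default_factory=list)


def bin_sessions(session_summaries: pd.DataFrame) -> BinnedSummary:
    """Average per-subject session summaries into two-session bins.

    ``session_summaries`` must have columns ``subject``, ``session`` (1-8)
    and the four measures; QC-failed sessions should already be absent.
    Bins are 1, 2, 3/4, 5/6, 7/8.  Subjects lacking a usable session in any
    bin are excluded and listed.
    """
    required = {"subject", "session", *MEASURES}
    missing = required - set(session_summaries.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    if not session_summaries["session"].between(1, 8).all():
        raise ValueError("sessions must be labeled 1..8")

    rows, included, excluded = [], [], []
    for subject, sub in session_summaries.groupby("subject"):
        sub_rows = []
        for sessions, label in zip(SESSION_BINS, BIN_LABELS):
            in_bin = sub[sub["session"].isin(sessions)]
            if in_bin.empty:
                sub_rows = None
                break
            means = in_bin[list(MEASURES)].mean()
            sub_rows.append({"subject": subject, "bin": label, **means.to_dict()})
        if sub_rows is None:
            excluded.append(subject)
            logger.info("bin_sessions: subject %s excluded (empty bin)", subject)
        else:
            included.append(subject)
            rows.extend(sub_rows)
    table = pd.DataFrame(rows, columns=["subject", "bin", *MEASURES])
    return BinnedSummary(table=table, included_subjects=included,
                         excluded_subjects=excluded)
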