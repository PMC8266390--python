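"""Readers/writers for the plain-text interchange formats.

* Event logs: TSV with columns ``time_s`` (3 decimals), ``event`` (closed
  vocabulary), ``label``.
* Photometry recordings: CSV with columns ``time_s``, ``channel``
  (415|470), ``fluorescence``.
* Session schedules: TSV with one row per trial:
  ``session_kind  session_index  trial  cs_id  onset_s  offset_s
  outcome_id  reward_times_s`` (semicolon-joined seconds) plus an
  ``extinction_end_s`` column so PIT schedules round-trip losslessly.

Malformed rows are reported with their line number; unknown event kinds
are rejected.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from .core import (
    EVENT_KINDS,
    CSTrial,
    Event,
    EventLog,
    SessionSchedule,
    TwoChannelRecording,
)


class FormatError(ValueError):
    """A malformed interchange file; the message names the offending line."""


def write_event_log(log: EventLog, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["time_s", "event", "label"])
        for e in log.events:
            writer.writerow([f"{e.time_s:.3f}", e.kind, e.label])


def read_event_log(path) -> EventLog:
    events = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["time_s", "event", "label"]:
            raise FormatError(f"{path}:1: expected header time_s/event/label")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            time_str, kind, label = row
            try:
                t = float(time_str)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad time {time_str!r}") from None
            if kind not in EVENT_KINDS:
                raise FormatError(f"{path}:{lineno}: unknown event kind {kind!r}")
            events.append(Event(t, kind, label))
    return EventLog(events)


def write_recording(rec: TwoChannelRecording, path) -> None:
    frame = pd.DataFrame(
        {
            "time_s": np.asarray(rec.time_s),
            "channel": np.asarray(rec.channel).astype(int),
            "fluorescence": np.asarray(rec.fluorescence),
        }
    )
    frame.to_csv(path, index=False, float_format="%.6g")


def read_recording(path, sample_rate_hz: float | None = None) -> TwoChannelRecording:
    frame = pd.read_csv(path)
    expected = ["time_s", "channel", "fluorescence"]
    if list(frame.columns) != expected:
        raise FormatError(f"{path}:1: expected header {','.join(expected)}")
    bad = set(frame["channel"].unique()) - {415, 470}
    if bad:
        raise FormatError(f"{path}: unknown channel labels {sorted(bad)}")
    if sample_rate_hz is None:
        t470 = frame.loc[frame["channel"] == 470, "time_s"].to_numpy()
        sample_rate_hz = (
            1.0 / float(np.median(np.diff(t470))) if len(t470) > 1 else 0.0
        )
    return TwoChannelRecording(
        time_s=frame["time_s"].to_numpy(dtype=float),
        channel=frame["channel"].to_numpy(dtype=int),
        fluorescence=frame["fluorescence"].to_numpy(dtype=float),
        sample_rate_hz=sample_rate_hz,
    )


_SCHEDULE_COLUMNS = [
    "session_kind", "session_index", "trial", "cs_id", "onset_s",
    "offset_s", "outcome_id", "reward_times_s", "extinction_end_s",
]


def write_schedule(schedule: SessionSchedule, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SCHEDULE_COLUMNS)
        for i, trial in enumerate(schedule.trials):
            writer.writerow(
                [
                    schedule.session_kind,
                    schedule.session_index,
                    i,
                    trial.cs_id,
                    f"{trial.onset_s:.6g}",
                    f"{trial.offset_s:.6g}",
                    trial.outcome_id,
                    ";".join(f"{t:.6g}" for t in trial.reward_times_s),
                    f"{schedule.extinction_end_s:.6g}",
                ]
            )


def read_schedule(path) -> SessionSchedule:
    trials = []
    kind, index, extinction = None, None, 0.0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _SCHEDULE_COLUMNS:
            raise FormatError(f"{path}:1: unexpected schedule header")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_SCHEDULE_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected "
                                  f"{len(_SCHEDULE_COLUMNS)} columns")
            try:
                kind = row[0]
                index = int(row[1])
                onset, offset = float(row[4]), float(row[5])
                rewards = [float(v) for v in row[7].split(";") if v]
                extinction = float(row[8])
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: {err}") from None
            trials.append(
                CSTrial(
                    cs_id=row[3],
                    onset_s=onset,
                    offset_s=offset,
                    reward_times_s=rewards,
                    outcome_id=row[6],
                )
            )
    if kind is None:
        raise FormatError(f"{path}: schedule file contains no trials")
    return SessionSchedule(
        session_kind=kind,
        session_index=index,
        trials=trials,
        extinction_end_s=extinction,
    )
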