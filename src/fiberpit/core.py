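"""Domain containers shared across the pipeline.

The pipeline moves data through a small set of typed containers:
session schedules (ground-truth trial structure), behavioral event
logs (timestamped food-port entries, lever presses, cue markers),
two-channel photometry recordings, and the corrected/derived products
of preprocessing and quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Closed vocabulary of behavioral event kinds.
EVENT_KINDS = frozenset(
    {
        "cs_on",
        "cs_off",
        "reward_delivery",
        "foodport_entry",
        "lever_press",
        "session_start",
        "session_end",
    }
)

#: Closed vocabulary of session kinds.
SESSION_KINDS = frozenset(
    {"conditioning", "unpaired", "pit", "instrumental", "magazine"}
)

CS_IDS = ("tone", "noise")
OUTCOME_IDS = ("sucrose", "pellet")
LEVER_IDS = ("left", "right")


@dataclass(frozen=True)
class ContingencyMap:
    """Counterbalanced cue->outcome and lever->outcome assignments.

    Both mappings must be bijections over the two cues/levers and two
    outcomes, mirroring the counterbalancing used when training animals
    (half the cohort gets tone->sucrose/noise->pellet, half the reverse;
    lever assignment is counterbalanced independently).
    """

    cs_to_outcome: dict
    lever_to_outcome: dict

    def __post_init__(self) -> None:
        for name, mapping, keys in (
            ("cs_to_outcome", self.cs_to_outcome, CS_IDS),
            ("lever_to_outcome", self.lever_to_outcome, LEVER_IDS),
        ):
            if set(mapping) != set(keys):
                raise ValueError(f"{name} must map exactly {keys}, got {set(mapping)}")
            if set(mapping.values()) != set(OUTCOME_IDS):
                raise ValueError(
                    f"{name} must be a bijection onto {OUTCOME_IDS}, "
                    f"got values {list(mapping.values())}"
                )

    def outcome_to_lever(self) -> dict:
        return {outcome: lever for lever, outcome in self.lever_to_outcome.items()}


@dataclass
class CSTrial:
    """One cue presentation (or reward-only period) within a session."""

    cs_id: str
    onset_s: float
    offset_s: float
    reward_times_s: list = field(default_factory=list)
    outcome_id: str = ""

    def __post_init__(self) -> None:
        if self.offset_s < self.onset_s:
            raise ValueError("trial offset precedes onset")
        for t in self.reward_times_s:
            if not (self.onset_s <= t <= self.offset_s):
                raise ValueError(
                    f"reward time {t} outside trial window "
                    f"[{self.onset_s}, {self.offset_s}]"
                )


@dataclass
class SessionSchedule:
    """Ground-truth trial structure of one behavioral session."""

    session_kind: str
    session_index: int
    trials: list
    extinction_end_s: float = 0.0

    def __post_init__(self) -> None:
        if self.session_kind not in SESSION_KINDS:
            raise ValueError(f"unknown session_kind {self.session_kind!r}")
        onsets = [t.onset_s for t in self.trials]
        if onsets != sorted(onsets):
            raise ValueError("trials must be ordered by onset")
        for a, b in zip(self.trials, self.trials[1:]):
            if b.onset_s < a.offset_s:
                raise ValueError("CS windows overlap")

    @property
    def end_s(self) -> float:
        """Nominal session end: last trial offset plus a 120-s tail."""
        if not self.trials:
            return max(self.extinction_end_s, 0.0) + 120.0
        return self.trials[-1].offset_s + 120.0


@dataclass(frozen=True)
class Event:
    time_s: float
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class EventLog:
    """Time-ordered behavioral event stream for one session."""

    events: list

    def __post_init__(self) -> None:
        times = [e.time_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")

    def times(self, kind: str, label: str | None = None) -> np.ndarray:
        """Times of events of a given kind (optionally filtered by label)."""
        return np.array(
            [
                e.time_s
                for e in self.events
                if e.kind == kind and (label is None or e.label == label)
            ]
        )

    @property
    def end_s(self) -> float:
        ends = self.times("session_end")
        if ends.size:
            return float(ends[-1])
        return float(self.events[-1].time_s) if self.events else 0.0

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class TwoChannelRecording:
    """Interleaved 415/470 nm fluorescence samples in long format."""

    time_s: np.ndarray
    channel: np.ndarray  # integer wavelength labels, 415 or 470
    fluorescence: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if len(self.channel) != n or len(self.fluorescence) != n:
            raise ValueError("time_s, channel, fluorescence must have equal length")
        bad = set(np.unique(self.channel)) - {415, 470}
        if bad:
            raise ValueError(f"unknown channel labels {bad}")

    def channel_series(self, wavelength: int) -> tuple:
        """(times, fluorescence) for one excitation channel."""
        mask = self.channel == wavelength
        return np.asarray(self.time_s)[mask], np.asarray(self.fluorescence)[mask]


@dataclass
class IsosbesticFit:
    """OLS fit of the 415-nm reference onto the 470-nm signal."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("non-finite fit parameters")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")

    def predict(self, f415: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(f415, dtype=float) + self.intercept


@dataclass
class CorrectedTrace:
    """Motion/bleach-corrected dF/F on the 470-nm timebase."""

    time_s: np.ndarray
    dff: np.ndarray
    zdff: np.ndarray
    fit: IsosbesticFit
    session_mean_dff: float
    session_sd_dff: float

    @property
    def sample_rate_hz(self) -> float:
        dt = np.median(np.diff(self.time_s))
        return 1.0 / float(dt)


@dataclass
class QCReport:
    transient_rate_per_min: float
    r_squared: float
    passed: bool
    reasons: list

    def __post_init__(self) -> None:
        if self.passed != (not self.reasons):
            raise ValueError("passed must be equivalent to an empty reason list")
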