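"""Simulation and analysis configuration.

``SimConfig`` holds every knob of the synthetic session generator.  Session
design defaults follow the behavioral procedures being emulated (8
conditioning sessions of eight 2-min cues per type, 30-s random-time reward
schedules, 2-4 min ITIs, a PIT test of four presentations per cue after 5
min of extinction).  Signal and behavior parameters are phantom-scale
choices documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator (units in field names)."""

    seed: int = 0
    n_subjects: int = 10

    # session design
    n_conditioning_sessions: int = 8
    cs_per_type: int = 8              # 4 in the photometry variant
    cs_duration_s: float = 120.0
    rt_mean_interval_s: float = 30.0  # random-time reward schedule
    min_probe_s: float = 0.0          # 15 in the photometry variant
    iti_range_s: tuple = (120.0, 240.0)
    pit_extinction_s: float = 300.0
    pit_cs_reps: int = 4
    pit_iti_s: float = 240.0

    # photometry acquisition + artifact model
    sample_rate_hz: float = 20.0      # per excitation channel
    f0_470: float = 100.0
    f0_415: float = 80.0
    bleach_amp1: float = 0.5
    bleach_tau1_s: float = 900.0
    bleach_amp2: float = 0.12
    bleach_tau2_s: float = 90.0
    motion_sd: float = 4.0
    motion_tau_s: float = 0.5
    gain_415: float = 0.8             # shared-motion coupling into the 415 channel
    noise_sd: float = 0.3

    # calcium transient kernel and event amplitudes (peak dF/F units)
    tau_rise_s: float = 0.1
    tau_decay_s: float = 0.6
    amp_cs: float = 1.0
    amp_retrieval: float = 2.0
    habituation_rate: float = 0.3     # per-session decay of amp_cs, unpaired mode

    # behavior generator
    entry_rate_base_per_min: float = 2.0
    entry_gain_per_session: float = 0.5
    press_rate_base_per_min: float = 5.0
    tau_same: float = 1.0
    tau_diff: float = 0.2
    retrieval_latency_mean_s: float = 1.5

    def __post_init__(self) -> None:
        self.iti_range_s = tuple(float(v) for v in self.iti_range_s)
        self.validate()

    def validate(self) -> None:
        nonneg = [
            "n_subjects", "n_conditioning_sessions", "cs_per_type",
            "cs_duration_s", "min_probe_s", "pit_extinction_s", "pit_cs_reps",
            "pit_iti_s", "motion_sd", "motion_tau_s", "noise_sd", "amp_cs",
            "amp_retrieval", "habituation_rate", "entry_rate_base_per_min",
            "entry_gain_per_session", "press_rate_base_per_min", "tau_same",
            "tau_diff", "retrieval_latency_mean_s", "bleach_tau1_s",
            "bleach_tau2_s",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rt_mean_interval_s <= 0:
            raise ValueError("rt_mean_interval_s must be > 0")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        lo, hi = self.iti_range_s
        if lo < 0 or lo > hi:
            raise ValueError("iti_range_s must satisfy 0 <= low <= high")
        if not self.tau_rise_s < self.tau_decay_s:
            raise ValueError("tau_rise_s must be < tau_decay_s")
        if self.cs_duration_s > 0 and self.min_probe_s >= self.cs_duration_s:
            raise ValueError("min_probe_s must be < cs_duration_s")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def photometry_variant(cls, **kwargs) -> "SimConfig":
        """Conditioning design used when imaging: 4 cues per type per session
        (to limit photobleaching) and a minimum 15-s probe period before the
        first reward so cue and reward transients can be dissociated."""
        base = dict(cs_per_type=4, min_probe_s=15.0)
        base.update(kwargs)
        return cls(**base)


@dataclass
class AnalysisConfig:
    """Preprocessing/quantification settings (QC thresholds, event windows)."""

    qc_min_r2: float = 0.6
    qc_min_transient_rate_per_min: float = 0.1
    window_pre_s: float = 3.0
    window_post_s: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.qc_min_r2 <= 1.0:
            raise ValueError("qc_min_r2 must lie in [0, 1]")
        if self.window_pre_s <= 0 or self.window_post_s <= 0:
            raise ValueError("event windows must be positive")


#: config-file key -> AnalysisConfig attribute
_ANALYSIS_KEYS = {
    "qc.min_r2": "qc_min_r2",
    "qc.min_transient_rate_per_min": "qc_min_transient_rate_per_min",
    "windows.pre_s": "window_pre_s",
    "windows.post_s": "window_post_s",
}


def load_config(path) -> tuple:
    """Read a flat ``key: value`` config file.

    Keys are exactly the ``SimConfig`` field names plus the dotted analysis
    keys (``qc.min_r2``, ``qc.min_transient_rate_per_min``, ``windows.pre_s``,
    ``windows.post_s``).  Unknown keys raise ``KeyError`` naming the offender.
    Returns ``(SimConfig, AnalysisConfig)``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must be flat 'key: value' text")
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    sim_kwargs, ana_kwargs = {}, {}
    for key, value in raw.items():
        if key in sim_fields:
            if key == "iti_range_s":
                if isinstance(value, str):
                    value = [float(v) for v in value.split(",")]
                value = tuple(float(v) for v in value)
            sim_kwargs[key] = value
        elif key in _ANALYSIS_KEYS:
            ana_kwargs[_ANALYSIS_KEYS[key]] = float(value)
        else:
            raise KeyError(f"unknown config key {key!r}")
    return SimConfig(**sim_kwargs), AnalysisConfig(**ana_kwargs)


def dump_config(sim: SimConfig, analysis: AnalysisConfig, path) -> None:
    """Write a config file that ``load_config`` reads back identically."""
    lines = []
    for f in dataclasses.fields(SimConfig):
        value = getattr(sim, f.name)
        if isinstance(value, tuple):
            value = list(value)
        lines.append(f"{f.name}: {value}")
    for key, attr in _ANALYSIS_KEYS.items():
        lines.append(f"{key}: {getattr(analysis, attr)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
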