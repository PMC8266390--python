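"""Seeded generators for synthetic sessions, behavior, and photometry.

The generators emulate a two-outcome Pavlovian conditioning experiment with
an outcome-selective Pavlovian-to-instrumental transfer (PIT) test:

* Conditioning sessions present two 2-min auditory cues (tone, white noise)
  in pseudorandom order with variable 2-4 min inter-trial intervals.  During
  each cue the associated reward arrives on a 30-s random-time schedule,
  modelled as a memoryless (exponential-wait) arrival process, giving an
  average of four deliveries per standard 2-min cue.
* The imaging variant presents four cues per type per session and enforces a
  minimum 15-s probe period between cue onset and the first delivery.
* Instrumental sessions reinforce lever presses on a random-ratio-20 rule
  and stop after 30 earned outcomes or 45 min.
* The PIT test presents each cue four times, unrewarded, after 5 min of
  lever-pressing extinction, with a fixed 4-min ITI.

Behavior is an inhomogeneous Poisson process (food-port entries elevated
during cues as conditioning progresses; lever pressing elevated on the
Same/Different levers during PIT cues), and the photometry model injects
double-exponential calcium transients at cue onsets and reward retrievals
on top of multiplicative photobleaching and a low-pass motion artifact
shared between the 470-nm signal and 415-nm isosbestic channels.

All generators are pure functions of (config, rng state): the same seed
reproduces identical output.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from .config import SimConfig
from .core import (
    CS_IDS,
    LEVER_IDS,
    OUTCOME_IDS,
    ContingencyMap,
    CSTrial,
    Event,
    EventLog,
    SessionSchedule,
    TwoChannelRecording,
)

RANDOM_RATIO = 20           # each press reinforced with probability 1/20
INSTRUMENTAL_MAX_S = 2700.0  # 45-min session cap
INSTRUMENTAL_MAX_OUTCOMES = 30


def make_contingency(subject_index: int) -> ContingencyMap:
    """Counterbalanced cue->outcome and lever->outcome maps for a subject.

    Cue assignment alternates with subject parity so half of any even-sized
    cohort gets tone->sucrose/noise->pellet and half the reverse; lever
    assignment is counterbalanced independently (period 2 over subject
    pairs), so all four arrangements occur equally often in cohorts whose
    size is a multiple of 4.
    """
    if subject_index < 0:
        raise ValueError("subject_index must be >= 0")
    flip_cs = subject_index % 2
    flip_lever = (subject_index // 2) % 2
    outcomes = OUTCOME_IDS if not flip_cs else OUTCOME_IDS[::-1]
    lever_outcomes = OUTCOME_IDS if not flip_lever else OUTCOME_IDS[::-1]
    return ContingencyMap(
        cs_to_outcome=dict(zip(CS_IDS, outcomes)),
        lever_to_outcome=dict(zip(LEVER_IDS, lever_outcomes)),
    )


def generate_rt_schedule(
    duration_s: float,
    mean_interval_s: float,
    min_probe_s: float,
    rng: np.random.Generator,
) -> list:
    """Random-time delivery times over ``(min_probe_s, duration_s]``.

    Memoryless arrivals: exponential waits with the given mean, started at
    the end of the probe period.  A 2-min window at a 30-s mean interval
    with no probe yields four deliveries on average.
    """
    if duration_s < 0 or mean_interval_s <= 0 or min_probe_s < 0:
        raise ValueError("durations must be >= 0 and mean_interval_s > 0")
    if duration_s > 0 and min_probe_s >= duration_s:
        raise ValueError("min_probe_s must be < duration_s")
    times = []
    t = min_probe_s
    while True:
        t += rng.exponential(mean_interval_s)
        if t > duration_s:
            break
        times.append(float(t))
    return times


def _pseudorandom_order(items_per_type: dict, rng: np.random.Generator) -> list:
    """Uniform shuffle, rejected until no label occurs >2 times in a row."""
    seq = [label for label, n in items_per_type.items() for _ in range(n)]
    if not seq:
        return []
    if len(items_per_type) == 1:
        if len(seq) > 2:
            raise ValueError("cannot avoid >2 consecutive repeats of one label")
        return seq
    while True:
        order = list(rng.permutation(seq))
        runs_ok = all(
            not (order[i] == order[i + 1] == order[i + 2])
            for i in range(len(order) - 2)
        )
        if runs_ok:
            return order


def draw_iti(config: SimConfig, rng: np.random.Generator) -> float:
    """One inter-trial interval, uniform on ``iti_range_s`` (2-4 min by
    default, mean 3 min)."""
    lo, hi = config.iti_range_s
    return float(rng.uniform(lo, hi))


def generate_conditioning_session(
    config: SimConfig,
    contingency: ContingencyMap,
    session_index: int,
    rng: np.random.Generator,
    unpaired: bool = False,
) -> SessionSchedule:
    """One Pavlovian conditioning (or unpaired cue-only) session.

    ``cs_per_type`` presentations of each cue in pseudorandom order (no more
    than two consecutive identical cues), separated by uniform ITIs on
    ``iti_range_s``; each trial's reward times come from the random-time
    scheduler restricted past the probe period.  In unpaired mode the cues
    carry no rewards (rewards are delivered in a separate reward-only
    session, see :func:`generate_reward_only_session`).
    """
    if config.cs_per_type < 1:
        raise ValueError("cs_per_type must be >= 1")
    if not 1 <= session_index <= config.n_conditioning_sessions:
        raise ValueError("session_index out of range")
    order = _pseudorandom_order(
        {cs: config.cs_per_type for cs in CS_IDS}, rng
    )
    trials = []
    t = 0.0
    for cs in order:
        t += draw_iti(config, rng)
        onset = t
        offset = onset + config.cs_duration_s
        if unpaired:
            rewards = []
        else:
            rewards = [
                onset + r
                for r in generate_rt_schedule(
                    config.cs_duration_s,
                    config.rt_mean_interval_s,
                    config.min_probe_s,
                    rng,
                )
            ]
        trials.append(
            CSTrial(
                cs_id=cs,
                onset_s=onset,
                offset_s=offset,
                reward_times_s=rewards,
                outcome_id=contingency.cs_to_outcome[cs],
            )
        )
        t = offset
    kind = "unpaired" if unpaired else "conditioning"
    return SessionSchedule(session_kind=kind, session_index=session_index, trials=trials)


def generate_reward_only_session(
    config: SimConfig,
    rng: np.random.Generator,
    periods_per_outcome: int = 4,
) -> SessionSchedule:
    """Non-contingent reward session for the unpaired control group.

    Each outcome is delivered on the random-time schedule during
    ``periods_per_outcome`` 2-min periods (one outcome per period,
    pseudorandom period order, variable ITI), for an average of
    ``periods_per_outcome * cs_duration_s / rt_mean_interval_s`` deliveries
    of each outcome per session (16 at the standard settings).
    """
    order = _pseudorandom_order(
        {outcome: periods_per_outcome for outcome in OUTCOME_IDS}, rng
    )
    trials = []
    t = 0.0
    for outcome in order:
        t += draw_iti(config, rng)
        onset = t
        offset = onset + config.cs_duration_s
        rewards = [
            onset + r
            for r in generate_rt_schedule(
                config.cs_duration_s, config.rt_mean_interval_s, 0.0, rng
            )
        ]
        trials.append(
            CSTrial(
                cs_id="",
                onset_s=onset,
                offset_s=offset,
                reward_times_s=rewards,
                outcome_id=outcome,
            )
        )
        t = offset
    return SessionSchedule(session_kind="magazine", session_index=1, trials=trials)


def generate_pit_session(config: SimConfig, rng: np.random.Generator) -> SessionSchedule:
    """PIT test schedule: extinction, then unrewarded cues at a fixed ITI.

    After ``pit_extinction_s`` of lever-press extinction, each cue is
    presented ``pit_cs_reps`` times in pseudorandom order with a fixed
    ``pit_iti_s`` between offset and the next onset.  No rewards.
    """
    order = _pseudorandom_order({cs: config.pit_cs_reps for cs in CS_IDS}, rng)
    trials = []
    onset = config.pit_extinction_s
    for cs in order:
        trials.append(
            CSTrial(
                cs_id=cs,
                onset_s=onset,
                offset_s=onset + config.cs_duration_s,
                reward_times_s=[],
                outcome_id="",
            )
        )
        onset = onset + config.cs_duration_s + config.pit_iti_s
    return SessionSchedule(
        session_kind="pit",
        session_index=1,
        trials=trials,
        extinction_end_s=config.pit_extinction_s,
    )


def generate_instrumental_session(
    config: SimConfig,
    contingency: ContingencyMap,
    lever_id: str,
    press_rate_per_min: float,
    rng: np.random.Generator,
) -> EventLog:
    """Single-lever instrumental session under random-ratio-20 reinforcement.

    Presses arrive as a homogeneous Poisson process; each press is
    reinforced with probability 1/20; the session ends at 30 earned
    outcomes or 45 min, whichever comes first.
    """
    if lever_id not in LEVER_IDS:
        raise ValueError(f"unknown lever_id {lever_id!r}")
    if press_rate_per_min < 0:
        raise ValueError("press_rate_per_min must be >= 0")
    outcome = contingency.lever_to_outcome[lever_id]
    events = [Event(0.0, "session_start")]
    t, earned = 0.0, 0
    rate_per_s = press_rate_per_min / 60.0
    while rate_per_s > 0:
        t += rng.exponential(1.0 / rate_per_s)
        if t > INSTRUMENTAL_MAX_S:
            break
        events.append(Event(t, "lever_press", lever_id))
        if rng.random() < 1.0 / RANDOM_RATIO:
            earned += 1
            events.append(Event(t, "reward_delivery", outcome))
            if earned >= INSTRUMENTAL_MAX_OUTCOMES:
                break
    end = t if earned >= INSTRUMENTAL_MAX_OUTCOMES else INSTRUMENTAL_MAX_S
    events.append(Event(end, "session_end"))
    return EventLog(events)


def _poisson_times(
    rate_per_s: float, start: float, end: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson arrival times on [start, end)."""
    if rate_per_s <= 0 or end <= start:
        return np.empty(0)
    n = rng.poisson(rate_per_s * (end - start))
    return np.sort(rng.uniform(start, end, size=n))


def simulate_behavior(
    schedule: SessionSchedule,
    config: SimConfig,
    contingency: ContingencyMap,
    rng: np.random.Generator,
) -> EventLog:
    """Generate a behavioral event log consistent with a session schedule.

    Food-port entries are an inhomogeneous Poisson process: baseline rate
    ``entry_rate_base_per_min`` everywhere, multiplied by
    ``1 + entry_gain_per_session * session_index`` inside cue windows of
    conditioning sessions (the acquisition of conditional approach).  Every
    reward delivery is followed by one retrieval entry at an exponential
    latency.  PIT sessions additionally emit lever presses at
    ``press_rate_base_per_min`` per lever, multiplied during cues by
    ``1 + tau_same`` on the Same lever and ``1 + tau_diff`` on the
    Different lever.
    """
    session_end = schedule.end_s
    events = [Event(0.0, "session_start")]
    for trial in schedule.trials:
        if trial.cs_id:
            if trial.cs_id not in contingency.cs_to_outcome:
                raise ValueError(f"cs_id {trial.cs_id!r} missing from contingency")
            events.append(Event(trial.onset_s, "cs_on", trial.cs_id))
            events.append(Event(trial.offset_s, "cs_off", trial.cs_id))
        for r in trial.reward_times_s:
            events.append(Event(r, "reward_delivery", trial.outcome_id))

    # food-port entries: piecewise-constant rate across cue/non-cue segments
    base = config.entry_rate_base_per_min / 60.0
    cs_gain = (
        1.0 + config.entry_gain_per_session * schedule.session_index
        if schedule.session_kind == "conditioning"
        else 1.0
    )
    bounds = [0.0]
    for trial in schedule.trials:
        bounds.extend([trial.onset_s, trial.offset_s])
    bounds.append(session_end)
    in_cs = False
    for lo, hi in zip(bounds, bounds[1:]):
        rate = base * cs_gain if (in_cs and schedule.session_kind != "magazine") else base
        for t in _poisson_times(rate, lo, hi, rng):
            events.append(Event(float(t), "foodport_entry"))
        in_cs = not in_cs

    # one retrieval entry per delivery, exponential latency
    for trial in schedule.trials:
        for r in trial.reward_times_s:
            t_retr = r + rng.exponential(config.retrieval_latency_mean_s)
            if t_retr <= session_end:
                events.append(Event(float(t_retr), "foodport_entry"))

    if schedule.session_kind == "pit":
        press_base = config.press_rate_base_per_min / 60.0
        for lever in LEVER_IDS:
            segments = []  # (lo, hi, rate)
            prev = 0.0
            for trial in schedule.trials:
                segments.append((prev, trial.onset_s, press_base))
                same_lever = contingency.outcome_to_lever()[
                    contingency.cs_to_outcome[trial.cs_id]
                ]
                boost = config.tau_same if lever == same_lever else config.tau_diff
                segments.append((trial.onset_s, trial.offset_s, press_base * (1 + boost)))
                prev = trial.offset_s
            segments.append((prev, session_end, press_base))
            for lo, hi, rate in segments:
                for t in _poisson_times(rate, lo, hi, rng):
                    events.append(Event(float(t), "lever_press", lever))

    events.append(Event(session_end, "session_end"))
    events.sort(key=lambda e: (e.time_s, e.kind, e.label))
    return EventLog(events)


def transient_kernel(
    t: np.ndarray, tau_rise_s: float, tau_decay_s: float
) -> np.ndarray:
    """Peak-normalized double-exponential kernel (1-e^(-t/tr)) e^(-t/td).

    Zero for t < 0; scaled so its maximum over t >= 0 equals 1.
    """
    t = np.asarray(t, dtype=float)
    tp = np.clip(t, 0.0, None)
    raw = np.where(
        t >= 0, (1.0 - np.exp(-tp / tau_rise_s)) * np.exp(-tp / tau_decay_s), 0.0
    )
    # analytic argmax: t* = tr * ln(1 + td/tr)
    t_peak = tau_rise_s * np.log1p(tau_decay_s / tau_rise_s)
    peak = (1.0 - np.exp(-t_peak / tau_rise_s)) * np.exp(-t_peak / tau_decay_s)
    return raw / peak


def _bleach(t: np.ndarray, config: SimConfig) -> np.ndarray:
    """Two-exponential photobleaching factor, B(0) = 1, decaying toward
    1 - amp1 - amp2."""
    return (
        1.0
        - config.bleach_amp1 * (1.0 - np.exp(-t / config.bleach_tau1_s))
        - config.bleach_amp2 * (1.0 - np.exp(-t / config.bleach_tau2_s))
    )


def _ou_process(
    n: int, dt: float, tau: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples on a uniform grid (exact
    discretization), autocorrelation time ``tau``, marginal sd ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    phi = np.exp(-dt / tau)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), size=n)
    innov[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], innov)


def _retrieval_times(schedule: SessionSchedule, log: EventLog) -> list:
    """First food-port entry at/after each delivery, bounded by the next
    delivery of the same trial (or session end)."""
    entries = log.times("foodport_entry")
    found = []
    for trial in schedule.trials:
        rewards = sorted(trial.reward_times_s)
        for i, r in enumerate(rewards):
            upper = rewards[i + 1] if i + 1 < len(rewards) else log.end_s
            candidates = entries[(entries >= r) & (entries < upper)]
            if candidates.size:
                found.append(float(candidates[0]))
    return found


def simulate_photometry(
    schedule: SessionSchedule,
    log: EventLog,
    config: SimConfig,
    rng: np.random.Generator,
    channel_offset_s: float | None = None,
) -> TwoChannelRecording:
    """Two-channel recording for one session.

    470-nm signal: ``f0_470 * B(t) * (1 + s(t)) + m(t) + noise`` with
    ``B`` the bleach factor, ``s`` the summed calcium transients and ``m``
    the shared low-pass motion artifact; 415-nm reference:
    ``f0_415 * B(t) + gain_415 * m(t) + noise`` (no calcium term).
    Transients are injected at cue onsets (amplitude ``amp_cs``, decayed by
    ``habituation_rate`` per session in unpaired mode) and at reward
    retrievals (``amp_retrieval``).  Channels are acquired interleaved: the
    415 samples are offset by half a sample period by default
    (``channel_offset_s=None``); pass 0.0 for simultaneous acquisition.
    """
    fs = config.sample_rate_hz
    period = 1.0 / fs
    if channel_offset_s is None:
        channel_offset_s = period / 2.0
    if not 0.0 <= channel_offset_s < period:
        raise ValueError("channel_offset_s must lie in [0, sample period)")
    duration = max(log.end_s, schedule.end_s)
    n = int(np.floor(duration * fs)) + 1
    t470 = np.arange(n) * period
    t415 = t470 + channel_offset_s

    # shared motion artifact sampled at every acquisition time
    if channel_offset_s == 0.0:
        m470 = _ou_process(n, period, config.motion_tau_s, config.motion_sd, rng)
        m415 = m470
    else:
        # the union of the two channel grids is uniform at twice the rate
        # only for the half-period offset; otherwise alternate step sizes
        interleaved = np.empty(2 * n)
        interleaved[0::2] = t470
        interleaved[1::2] = t415
        dts = np.diff(interleaved)
        if np.allclose(dts, dts[0]):
            m_all = _ou_process(
                2 * n, float(dts[0]), config.motion_tau_s, config.motion_sd, rng
            )
        else:
            m_all = _ou_irregular(interleaved, config.motion_tau_s, config.motion_sd, rng)
        m470, m415 = m_all[0::2], m_all[1::2]

    # calcium transients (470 channel only)
    amp_cs = config.amp_cs
    if schedule.session_kind == "unpaired":
        amp_cs *= (1.0 - config.habituation_rate) ** (schedule.session_index - 1)
    transient_events = [(t.onset_s, amp_cs) for t in schedule.trials if t.cs_id]
    transient_events += [
        (t, config.amp_retrieval) for t in _retrieval_times(schedule, log)
    ]
    s = np.zeros(n)
    support = int(np.ceil((config.tau_rise_s + 10.0 * config.tau_decay_s) * fs))
    for t_e, amp in transient_events:
        if amp == 0:
            continue
        i0 = int(np.ceil((t_e - t470[0]) * fs))
        i0 = max(i0, 0)
        i1 = min(i0 + support, n)
        if i0 >= n:
            continue
        s[i0:i1] += amp * transient_kernel(
            t470[i0:i1] - t_e, config.tau_rise_s, config.tau_decay_s
        )

    f470 = (
        config.f0_470 * _bleach(t470, config) * (1.0 + s)
        + m470
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    f415 = (
        config.f0_415 * _bleach(t415, config)
        + config.gain_415 * m415
        + rng.normal(0.0, config.noise_sd, size=n)
    )

    time = np.concatenate([t470, t415])
    chan = np.concatenate([np.full(n, 470), np.full(n, 415)])
    fluor = np.concatenate([f470, f415])
    order = np.lexsort((chan, time))
    return TwoChannelRecording(
        time_s=time[order],
        channel=chan[order],
        fluorescence=fluor[order],
        sample_rate_hz=fs,
    )


def _ou_irregular(
    times: np.ndarray, tau: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact OU sampling at arbitrary sorted times (scalar recursion)."""
    n = len(times)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    dts = np.diff(times)
    phis = np.exp(-dts / tau)
    sds = sd * np.sqrt(1.0 - phis**2)
    innov = rng.normal(0.0, 1.0, size=n - 1)
    for i in range(1, n):
        out[i] = phis[i - 1] * out[i - 1] + sds[i - 1] * innov[i - 1]
    return out
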