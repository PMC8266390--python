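"""Isosbestic correction, dF/F, Z-scoring, and session quality control.

The 415-nm isosbestic channel carries motion artifact and photobleaching
but no calcium-dependent fluorescence, so an ordinary least-squares fit of
the 415 signal to the 470 signal provides a per-session reference whose
residual fraction, (470 - fitted 415) / fitted 415, is the motion- and
bleach-corrected dF/F.  The dF/F trace is then Z-scored against its own
whole-session mean and standard deviation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core import CorrectedTrace, IsosbesticFit, QCReport, TwoChannelRecording


class DegenerateFitError(ValueError):
    """Raised when the isosbestic regression is ill-posed (constant 415)."""


def deinterleave(rec: TwoChannelRecording) -> tuple:
    """Resample the interleaved channels onto a common timebase.

    The 470-nm timestamps become the master grid; the 415-nm samples are
    linearly interpolated onto it (nearest-value extension outside the 415
    support).  Returns ``(time_s, f470, f415_interp)``.
    """
    t470, f470 = rec.channel_series(470)
    t415, f415 = rec.channel_series(415)
    for name, t in (("470", t470), ("415", t415)):
        if len(t) < 2:
            raise ValueError(f"channel {name} needs >= 2 samples, got {len(t)}")
    f415_interp = np.interp(t470, t415, f415)
    return t470, f470, f415_interp


def fit_isosbestic(f470: np.ndarray, f415: np.ndarray) -> IsosbesticFit:
    """Least-squares linear fit of the 415 reference to the 470 signal.

    OLS of f470 on f415 over the whole session; the fitted values
    ``slope * f415 + intercept`` are the scaled reference used for dF/F.
    """
    f470 = np.asarray(f470, dtype=float)
    f415 = np.asarray(f415, dtype=float)
    if f470.shape != f415.shape or f470.size < 3:
        raise ValueError("f470 and f415 must have equal length >= 3")
    if np.ptp(f415) == 0:
        raise DegenerateFitError("415 channel is constant; regression is degenerate")
    res = stats.linregress(f415, f470)
    return IsosbesticFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def compute_dff(
    f470: np.ndarray, f415: np.ndarray, fit: IsosbesticFit
) -> np.ndarray:
    """dF/F = (470 - fitted 415) / fitted 415, per sample."""
    fitted = fit.predict(f415)
    bad = np.flatnonzero(fitted <= 0)
    if bad.size:
        raise ValueError(
            f"fitted 415 is non-positive at sample {bad[0]} "
            f"(value {fitted[bad[0]]:g}); dF/F undefined"
        )
    return (np.asarray(f470, dtype=float) - fitted) / fitted


def zscore_trace(dff: np.ndarray) -> tuple:
    """Z-score dF/F against its whole-session statistics.

    Uses the population standard deviation (ddof=0).  Returns
    ``(zdff, session_mean, session_sd)``.
    """
    dff = np.asarray(dff, dtype=float)
    if dff.size < 2:
        raise ValueError("need >= 2 samples to Z-score")
    mean = float(dff.mean())
    sd = float(dff.std(ddof=0))
    if sd == 0:
        raise ValueError("zero-variance dF/F cannot be Z-scored")
    return (dff - mean) / sd, mean, sd


def preprocess_recording(rec: TwoChannelRecording) -> CorrectedTrace:
    """Full per-session preprocessing: deinterleave, fit, dF/F, Z-score."""
    t, f470, f415 = deinterleave(rec)
    fit = fit_isosbestic(f470, f415)
    dff = compute_dff(f470, f415, fit)
    zdff, mean, sd = zscore_trace(dff)
    return CorrectedTrace(
        time_s=t,
        dff=dff,
        zdff=zdff,
        fit=fit,
        session_mean_dff=mean,
        session_sd_dff=sd,
    )


def _count_transients(
    dff: np.ndarray, threshold: float, min_width: int, min_separation: int
) -> int:
    """Count suprathreshold runs of at least ``min_width`` samples,
    merging runs separated by fewer than ``min_separation`` samples."""
    above = dff > threshold
    if not above.any():
        return 0
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(dff)]])
    keep = (ends - starts) >= min_width
    starts, ends = starts[keep], ends[keep]
    if starts.size == 0:
        return 0
    gaps = starts[1:] - ends[:-1]
    return int(1 + np.count_nonzero(gaps >= min_separation))


def qc_session(
    trace: CorrectedTrace,
    min_r2: float = 0.6,
    min_transient_rate_per_min: float = 0.1,
) -> QCReport:
    """Session-level quality control.

    A session is excluded if no transient calcium fluctuations rise above
    the isosbestic-corrected noise floor, or if the isosbestic fit is poor
    (r-squared below ``min_r2``, e.g. from excessive motion artifact).

    A transient is an excursion of dF/F above 3 x 1.4826 x MAD (a robust
    3-sigma level) that stays above threshold for at least 0.25 s; runs
    closer together than 1 s count as one event.  The sustained-width
    requirement keeps isolated suprathreshold noise samples, which occur at
    a few per minute in any Gaussian noise floor, from counting as calcium
    events.
    """
    dff = np.asarray(trace.dff, dtype=float)
    med = float(np.median(dff))
    mad = float(np.median(np.abs(dff - med)))
    threshold = med + 3.0 * 1.4826 * mad
    fs = trace.sample_rate_hz
    if mad == 0:
        n_peaks = 0
    else:
        n_peaks = _count_transients(
            dff, threshold, min_width=max(int(round(0.25 * fs)), 1),
            min_separation=max(int(round(1.0 * fs)), 1),
        )
    duration_min = (trace.time_s[-1] - trace.time_s[0]) / 60.0
    rate = n_peaks / duration_min if duration_min > 0 else 0.0

    reasons = []
    if rate < min_transient_rate_per_min or n_peaks == 0:
        reasons.append("no_transients")
    if trace.fit.r_squared < min_r2:
        reasons.append("poor_fit")
    return QCReport(
        transient_rate_per_min=float(rate),
        r_squared=trace.fit.r_squared,
        passed=not reasons,
        reasons=reasons,
    )
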