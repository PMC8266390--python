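# Methods

This note documents the generative model behind the synthetic sessions,
the analysis pipeline's numerical choices, and the design decisions taken
where the procedure admitted more than one reasonable reading.

## Session design emulated by the generator

The generator reproduces a two-outcome Pavlovian conditioning experiment
with an outcome-selective Pavlovian-to-instrumental transfer (PIT) test:

- **Pavlovian conditioning** — 8 sessions; per session, `cs_per_type`
  presentations of each of two 2-min auditory cues (tone, white noise) in
  pseudorandom order, with a variable 2–4-min inter-trial interval (ITI;
  uniform on [120, 240] s, mean 3 min). During each cue its assigned reward
  (sucrose or pellet; counterbalanced across subjects) is delivered on a
  30-s random-time schedule. The standard design uses 8 cues per type; the
  imaging variant (`SimConfig.photometry_variant()`) uses 4 per type and
  enforces a minimum 15-s probe period between cue onset and the first
  delivery so cue and reward responses can be dissociated.
- **Unpaired control** — the same cue schedule with no rewards, plus a
  separate reward-only session of four 2-min periods per outcome under the
  same 30-s schedule (mean 16 deliveries per outcome).
- **Instrumental conditioning** — single-lever sessions, each press
  reinforced with probability 1/20 (random-ratio 20), terminating at 30
  earned outcomes or 45 min.
- **PIT test** — after 300 s of lever-press extinction, each cue is
  presented four times, unrewarded, in pseudorandom order with a fixed
  240-s ITI.

**Random-time schedule.** Implemented as a memoryless arrival process:
exponential waits with mean `rt_mean_interval_s`, restricted to
`(min_probe_s, cs_duration_s]`. A standard 2-min cue at the 30-s schedule
therefore averages 4 deliveries. In the imaging variant the probe
restriction shortens the delivery window, so the expected count is 3.5,
not 4; the 4-per-cue average describes the standard design.

**Pseudorandom order** is a uniform shuffle rejected until no cue type
occurs more than twice in a row — a deliberately light reading of
"pseudorandom" sufficient for the order constraints the analyses assume.

## Behavioral model

Food-port entries form an inhomogeneous Poisson process: baseline rate
`entry_rate_base_per_min` (default 2/min), multiplied inside conditioning
cues by `1 + entry_gain_per_session * session_index` (default gain 0.5) to
emulate acquisition of conditional approach. Each reward delivery is
followed by exactly one retrieval entry at an exponential latency (mean
1.5 s) — a simplification; real animals occasionally miss deliveries. PIT
sessions add per-lever presses at `press_rate_base_per_min` (default
5/min), multiplied during cues by `1 + tau_same` on the lever whose
trained outcome matches the cue and `1 + tau_diff` on the other (defaults
1.0 and 0.2, giving the Same > Different choice bias of an intact control
group; setting `tau_same = tau_diff` emulates a cohort in which transfer
is abolished).

## Photometry model

Per channel, samples at `sample_rate_hz` (20 Hz), the 415-nm channel
offset by half a sample period (the interleaved-acquisition reading of a
shared camera clock; an option allows simultaneous timestamps):

    F470(t) = f0_470 · B(t) · (1 + s(t)) + m(t) + e(t)
    F415(t) = f0_415 · B(t) + gain_415 · m(t) + e'(t)

- `B(t)` — two-exponential photobleaching factor,
  `1 − a1(1 − e^(−t/τ1)) − a2(1 − e^(−t/τ2))`, multiplicative on the
  baseline of both channels.
- `m(t)` — zero-mean Ornstein–Uhlenbeck motion artifact (sd `motion_sd`,
  autocorrelation time `motion_tau_s`), shared across channels and scaled
  into the 415 channel by `gain_415`; with
  `gain_415 = f0_415 / f0_470` the artifact is an exact affine function
  across channels and cancels in ΔF/F.
- `s(t)` — summed calcium transients: a peak-normalized double-exponential
  kernel `(1 − e^(−t/τ_rise)) e^(−t/τ_decay)` (defaults 0.1 s / 0.6 s,
  fast-indicator-like) injected at cue onsets (amplitude `amp_cs`, decayed
  by `habituation_rate` per session in unpaired mode) and at reward
  retrievals (`amp_retrieval`). Amplitudes are in peak-ΔF/F units.
- `e(t)` — iid Gaussian sensor noise (`noise_sd`).

**Default artifact scales.** `f0_470 = 100`, `f0_415 = 80` a.u., bleach
50 %/900 s plus 12 %/90 s, `motion_sd = 4`, `noise_sd = 0.3`. These were
chosen so that the default phantom behaves like an accepted recording:
with transient amplitudes of order 1–2 ΔF/F, the isosbestic regression
needs substantial shared bleach/motion variance to reach r² ≈ 0.75–0.80
(and ≈ 0.995 when amplitudes are zero). The amplitudes themselves are
phantom-scale conventions, not biological estimates; what the pipeline's
tests validate is the *relative* machinery (cancellation, recovery,
ordering), which is amplitude-invariant.

**What the generator does not model:** lick/consumption dynamics,
missed retrievals, rate drift within sessions, wavelength-dependent bleach
differences between channels, hemodynamic contamination, or any direct
circuit-level group differences — cohort effects are induced only through
behavior/signal parameters. Passing tests therefore demonstrate that the
analysis recovers what this phantom family encodes, not that it is robust
to every pathology of real recordings.

## Preprocessing and QC

- **Isosbestic correction** — OLS of the 470 signal on the 415 signal over
  the entire session (no windowed or robust variant); the 415 channel is
  first linearly interpolated onto the 470 timestamps (nearest-value
  extension at the edges). ΔF/F = (470 − fitted 415)/fitted 415; an error
  is raised, naming the first offending sample, if the fitted reference is
  not strictly positive.
- **Z-scoring** uses the population (ddof = 0) standard deviation over the
  whole session, ITIs included. The sample/population distinction is
  negligible at session length but is fixed for exact testability.
- **QC** — a session passes if the fit's r² ≥ 0.6 *and* transients occur
  at ≥ 0.1/min (both config-exposed). A transient is an excursion of ΔF/F
  above a robust 3σ level (3 × 1.4826 × MAD about the median) sustained
  for ≥ 0.25 s, with excursions closer than 1 s merged. The sustained-width
  requirement is essential: isolated samples exceed a 3σ threshold at
  roughly 1.6/min in any Gaussian noise floor, so a bare local-maximum
  criterion would count noise as transients; a quarter-second of sustained
  elevation is vanishingly improbable for white noise at 20 Hz but routine
  for a calcium transient with a 0.6-s decay.

## Event quantification

- Peri-event windows are 3 s pre / 3 s post on the trace's own grid; the
  post-window peak is the maximum over (0, +3 s], the baseline peak over
  [−3 s, 0); AUCs are trapezoidal integrals over [−3, 0] and [0, +3]
  (the event sample is the shared integration boundary), in Z·s. No
  baseline subtraction is applied inside windows — pre vs post are
  compared downstream as a paired contrast.
- Events whose windows exceed the recording are dropped and counted, not
  padded.
- Retrieval = first food-port entry at or after a delivery (inclusive
  boundary, fixed for grid determinism), bounded by the next delivery of
  the same trial so one entry cannot serve two deliveries.
- Averaging is across trials within each cue, then unweighted across the
  two cues; session summaries are binned 1, 2, 3/4, 5/6, 7/8, and a
  subject is retained only with at least one QC-passing session per bin.
- The amplitude-recovery check is run at retrieval amplitudes 0.1–0.5
  ΔF/F, below the fixed cue amplitude: because the Z-score normalizes by
  whole-session variance, the Z peak grows linearly with amplitude only
  while the varied transient is a minor contributor to that variance and
  saturates by construction beyond it.

## Behavioral scoring

- Elevation ratio = CS/(CS + preCS) on rates (conditioning; the probe
  window varies in length) or counts (PIT; windows are equal). The pre
  window is always the 120 s immediately before onset; windows are
  half-open `[start, end)`, so boundary events belong to the later window.
- 0/0 ratios are undefined and excluded from trial averaging rather than
  imputed at 0.5, to avoid biasing toward indifference.
- The conditioning probe window ends at the first *delivery*, even if the
  retrieval occurs later.
- Trials whose 120-s baseline would precede the session start are flagged
  and skipped (cannot occur with the default designs: the minimum ITI and
  the 300-s PIT extinction both cover the baseline).
- Note a small-sample property of rate-based ratios: with unequal window
  lengths and low counts, the null expectation of the ratio falls below
  0.5 (the shorter window's rate is noisier); with equal windows the null
  is exactly 0.5 by exchangeability.

## Statistics

- t tests are two-tailed; identical paired samples return t = 0, p = 1,
  while a constant non-zero difference (zero variance) is an error.
- Greenhouse–Geisser ε = (Σλ)² / ((k−1) Σλ²) from the eigenvalues of the
  double-centered within-subject covariance; equivalently from orthonormal
  contrast scores, which is how multi-factor effects are handled (Kronecker
  products of normalized Helmert contrasts; each effect is tested against
  its own effect-by-subject error term). ε is identically 1 for two-level
  factors.
- The correction is applied unconditionally (no Mauchly pretest),
  multiplying numerator and denominator degrees of freedom by ε.
- The split-plot (mixed) ANOVA supports unequal group sizes; with a single
  between factor the weighted (Type I) and Type III sums of squares
  coincide for all terms. ε for within terms uses the pooled within-group
  covariance. Designs with missing cells are rejected, not approximated.
- On null data (iid normal cells) the GG-corrected one-way RM ANOVA is
  slightly conservative (rejection ≈ 0.035–0.04 at α = 0.05), as expected
  when ε̂ < 1 under true sphericity.

## Reproducibility and problem sizes

All generators are pure functions of (config, generator state); the
pipeline derives per-subject, per-session streams from a single master
seed via `numpy.random.SeedSequence.spawn`, and reruns with the same
config and seed are byte-identical, including the run manifest (file paths
are stored relative to the output directory). Simulation-based checks use
10,000 draws for scheduler/ITI calibration, 2,000 replicates for
unpaired-session and type-I-error calibration, 500 replicates of 10+10
subject cohorts for the PIT interaction power check, and 8-subject
cohorts at 5 amplitude levels for parameter recovery — sizes at which the
Monte-Carlo error is comfortably inside each check's tolerance while the
whole suite stays fast on one CPU.
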