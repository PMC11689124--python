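# Methods

This note documents the models, defaults and numerical choices behind
`cardiotfa`, and what the synthetic-data tests do and do not establish about
real recordings.

## Signal model

The emulated protocol drives arterial blood pressure (BP) with a paced
squat–stand oscillation at 0.05 or 0.10 Hz while end-tidal CO₂ is clamped at
one of three stages (hypocapnia ~25, eucapnia ~40, hypercapnia ~55 mmHg).
The per-beat systolic and diastolic BP levels each carry the same additive
sinusoid `A·sin(2πft)` evaluated at the beat onset. Because the forcing is
additive and identical for both levels, every cardiac-cycle component of the
beat series (systolic, diastolic, and consequently mean) oscillates with
amplitude A and zero relative phase, which makes the injected velocity
transfer *exactly* linear in the oscillation — the property the recovery
tests rely on.

Each velocity channel is constructed so that its per-beat component series
equals `baseline + gain · osc_c(t + phase/2πf) (+ noise)`, where `osc_c` is
the sinusoid fitted at the forcing frequency to the corresponding BP
component series. Positive phase therefore means velocity leads pressure,
matching the physiological reading of an autoregulatory phase lead, and the
cross-spectral estimate `arg(conj(X)·Y)` returns it with the same sign.

## Pulse kernel

One beat is a half-raised-cosine upstroke from the diastolic foot to the
systolic peak over a fraction `systolic_fraction` of the beat, followed by an
exponential run-off (`decay_rate`, 1/s) whose end-of-beat residual is
absorbed by a linear ramp. Two design details matter:

- **End-diastolic ledge.** The run-off terminates `end_diastolic_offset`
  (default 2%) of the pulse height *above the larger of the beat's own foot
  and the next beat's foot*. Without the ledge, whenever diastolic levels
  change quickly between beats (which the forcing guarantees), the minimum
  of a half-open beat window reads the neighbouring beat's foot, which
  attenuates and phase-advances the extracted diastolic series by several
  percent. With the ledge, the minimum between two systolic peaks is the
  intervening foot by construction, for any forcing slope.
- **Per-beat systolic fraction.** A two-parameter kernel cannot hit three
  independent per-beat targets (max, min, and time-average). The kernel's
  beat mean has a closed form, monotone in the systolic fraction, so the
  simulator inverts it per beat (vectorized bisection, 48 iterations) to
  make the velocity beat mean equal its injected target exactly. The
  achievable mean fraction is bounded above by 0.5 of the pulse height; with
  noisy beat targets a small percentage of beats (notably hypocapnic PCA,
  where the diastolic and mean baselines sit close) can request more and are
  clipped with a `RuntimeWarning`. Noiseless recovery conditions never clip.

R-R intervals jitter with a Gaussian sd of 2% of the mean interval,
truncated at ±10%. PETCO₂ is a breath-wise raised-cosine excursion whose
per-breath peaks equal the stage target plus optional jitter, emulating
end-tidal clamping that holds peaks within ~1 mmHg of target.

## Generator defaults

- 10 female + 10 male participants; 3 stages × 2 pacing frequencies; 240-s
  recordings.
- Forcing amplitude 10 mmHg. The protocol literature does not fix the BP
  swing a squat–stand produces; reported mean-BP spectral powers at the
  pacing bin imply sinusoid amplitudes of roughly 10–20 mmHg, and 10 mmHg is
  a conservative choice that also keeps the three component bands
  (diastolic < mean < systolic) of each channel well separated.
- Stage-level gain/phase/baseline defaults are loosely calibrated to
  published squat–stand TFA magnitudes: phase falls and gain tends to rise
  from hypocapnia through eucapnia to hypercapnia (e.g. mean-MCAv phase
  0.85/0.47/0.19 rad at 0.05 Hz), and baseline velocity rises with CO₂
  (vasodilation), scaled ×0.80/×1.00/×1.25 across stages. They are
  plausible simulation conditions, not reproductions of any measured cohort.
- Participant heterogeneity: heart rate ~ U(80, 105) beats/min; diastolic
  pressure ~ N(75, 6) and pulse pressure ~ N(45, 6) mmHg (clipped);
  multiplicative gain and baseline factors ~ N(1, 0.08) (clipped ±25%); an
  additive phase offset ~ N(0, 0.05) rad; a ±5% sex factor on baseline
  velocity only.
- Velocity beat-level measurement noise 1 cm/s (sd); set to zero for
  recovery studies.
- Sample rate 250 Hz. The systolic value of a discretized sharp peak
  under-reads by ~curvature·Δt²/8; because velocity peak curvature is
  modulated by the forcing, at 100 Hz this error leaks into the smallest
  systolic oscillations (PCA) at the level of ~2% gain and ~0.03 rad phase,
  while at 250 Hz the worst-case component bias is several-fold below the
  recovery tolerances. The rate is configurable; acquisition hardware in
  this field typically samples at 1000 Hz.

## Processing defaults

- Beat detection: systolic peaks via a refractory peak search (60/hr_max
  refractory, prominence ≥ 25% of the robust trace range), onsets at the
  minimum between consecutive peaks. Beats are detected on BP only and the
  same boundaries decompose the velocity channels, avoiding inter-channel
  beat mismatch. A beat spans the half-open interval [onset_i, onset_{i+1}).
- Artifact screening: a systolic value deviating from the 11-beat centred
  rolling median by more than 4 robust SDs is replaced by a cubic spline
  through unflagged beats. The robust SD is the largest of 1.4826×MAD of
  the rolling-median residuals, the median absolute beat-to-beat systolic
  difference, and 0.5% of the median systolic level — the two floors keep a
  smooth, low-noise series (where the centre of an odd window *is* its
  median and the MAD degenerates) from self-flagging its own slow
  oscillation. More than 20% flagged raises an error instead of rewriting
  the series: isolated artifacts affect well under 1% of beats, so mass
  flagging signals a systematic change. Note that a within-series screen is
  blind to global level shifts by construction.
- Resampling: natural cubic spline through (onset time, component value),
  evaluated at 4 Hz, endpoints held (no extrapolation); the pipeline pins
  the grid to the full record span so window arithmetic sees the nominal
  duration.
- Welch: 80-s periodic Hanning windows, 50% overlap, per-window linear
  detrend, density normalization (unit-variance white noise integrates
  to 1), mean averaging across the five windows of a 240-s record.
  Coherence is magnitude-squared. An optional 3-point triangular smoother
  over frequency can be applied to Pxx, Pyy and Sxy before metric formation;
  it is off by default because no reproducible definition of the smoothing
  used by commercial TFA packages exists, and the defaults must be exactly
  reproducible from stated settings.
- Point estimates are single-bin reads at the bin nearest the requested
  frequency (exact bins at 0.05/0.10 Hz on the default grid). nGain divides
  by the component series' own segment mean. Estimates with coherence below
  the critical value 0.46 (a convention constant for α = 0.01 with five
  windows, not re-derived here) are flagged, never dropped. Phase is
  reported in (−π, π] without unwrapping; wraparound (an adjacent-bin jump
  exceeding π) is screened over the autoregulation band containing the point
  frequency, restricted to bins meeting the coherence criterion — phase is
  not interpretable where coherence is inadequate, and for narrowband
  synthetic data off-forcing bins carry only leakage whose phase alternates
  sign.

## Inference

Each metric × vessel × component × frequency cell is modelled separately
(no multiple-testing correction, mirroring standard practice for these
designs): `value ~ stage + sex` with a participant random intercept, fitted
by maximum likelihood so the likelihood-ratio test against the
intercept-plus-random-effect null is valid; the LR statistic is referred to
χ² with 3 degrees of freedom (two stage contrasts + one sex contrast). Wald
95% CIs and p-values per coefficient come from the ML fit. Convergence
warnings mark the result as `converged=False` rather than failing silently.
The asymptotic χ² reference is known to be mildly anticonservative for ML
fixed-effect LR tests at small group counts; the acceptance script measures
the realized type-I rate at the emulated design size (20 participants,
3 stages) over 1000 simulated tables.

The a-priori sample-size operation uses the large-sample normal
approximation `n = ceil((z₁₋α + z_power)² / f²)` for a one-tailed
single-coefficient test (`z₁₋α/₂` for two tails). With f² = 0.35, α = 0.05
and power 0.80 it returns 18; an exact noncentral-F computation would differ
slightly and is deliberately not the default, because only the normal
approximation reproduces the planning arithmetic of the emulated protocol.

Calibration studies (`simulate_metric_table`) use a phase-like metric:
eucapnic level 0.47 rad, between-participant sd 0.1, residual sd 0.1, stage
effects +0.38 (hypocapnia) and −0.28 (hypercapnia) where effects are
injected, at 10 + 10 participants.

## What the synthetic tests do and do not show

The generator produces exactly linear, single-frequency transfer with
stationary parameters, near-periodic beats and clamp-quality PETCO₂. Passing
recovery tests therefore establishes that the pipeline's estimators are
unbiased and internally consistent under the model's own assumptions — they
do not establish robustness to nonlinear or frequency-dependent
autoregulation, non-stationarity, breathing-coupled BP variability, Doppler
signal dropout, or vessel-diameter changes under CO₂ (velocity is only a
flow index if diameter is constant). Problem sizes throughout (240-s
records, 20-participant cohorts, 1000/200 calibration replicates) are the
emulated protocol's own design sizes.

## Known limitations

- The pulse kernel is a minimal parametric shape; it has no dicrotic notch
  and its end-diastolic ledge is a construction device, so waveform-
  morphology analytics are out of scope.
- `apply_transfer` requires all three component truths per vessel and
  systolic targets strictly above diastolic targets; extreme forcing
  amplitudes or noise levels violate this and raise.
- The within-series artifact screen cannot detect calibration-level shifts.
- LR p-values rely on the asymptotic χ² reference; no small-sample
  correction (e.g. Kenward–Roger) is offered because the ML/LRT pairing is
  the procedure being emulated.
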