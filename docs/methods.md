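# Methods

This note documents the models, conventions and numerical choices behind
`hrvagree`: what the synthetic data emulate, how the reference metrics are
defined, exactly which variant of each agreement statistic is computed, and
what the package's own validation experiments do and do not demonstrate.

## The study design being emulated

The package simulates resting-state device-validation studies of the kind
run on commercial wearables: a small cohort of subjects performs many short
trials; in each trial a commercial device and a reference multi-lead ECG
record simultaneously; the device's reported mean HR and rMSSD are compared
against the same quantities computed from the reference ECG over the exact
trial window.  The default `StudyDesign` follows that structure: 5
subjects, 148 trials, a panel of 7 device/app pairings, trial epochs of
either 3 or 5 minutes (set per device, as real devices fix their own
recording window), and a 512 Hz reference sampling rate.  Published studies
of this kind do not report per-subject trial counts or the device-to-trial
allocation, so the default design allocates trials near-equally across the
panel (remainder to the first devices) and cycles subjects round-robin;
both are configurable.

Between-subject physiology is drawn per subject: resting HR ~ N(65, 7²) bpm
and rMSSD ~ N(60, 15²) ms, clipped to plausible resting ranges, with
within-subject trial-to-trial wobble of 3 bpm / 6 ms — values typical of
healthy young adults at rest.  They are defaults, not estimates.

## Ground-truth RR model

`simulate_rr_series` modulates the interval sequence directly:

    RR(t_i) = base + A_LF sin(2π·0.10·t + φ_LF) + A_HF sin(2π·0.25·t + φ_HF)
              + A_VLF sin(π t / T) + ε_i,   ε_i ~ N(0, σ²)

with `base = 60000 / mean HR` ms and phases drawn per seed.  This is a
statistical stand-in for resting sinus rhythm — LF and HF oscillations at
their conventional centre frequencies plus a half-cycle very-low-frequency
drift — not an integral-pulse-frequency cardiac model; anyone needing beat
generation from a continuous modulator can substitute their own generator,
since everything downstream consumes only `RRSeries`.

The model's rMSSD has a closed form: at mean beat interval τ a sinusoid of
amplitude A and frequency f contributes `2A² sin²(πfτ)` to the mean squared
successive difference and white jitter contributes `2σ²`.  When a target
rMSSD is requested, the HF amplitude and jitter SD are rescaled by a common
factor found by bisection so the closed form hits the target; a target
below the floor set by the fixed LF/VLF amplitudes raises
`CalibrationError`.  Over 100 seeds the realized rMSSD mean lands within
10% of target and realized mean HR within 2% of nominal (both are tested).
A 250 ms hard floor guards the truth model against nonphysical intervals
under extreme noise configurations; with the default amplitudes it never
engages.

## ECG rendering and R-peak detection

`render_ecg` centres one Ricker (Mexican-hat) template — 80 ms support,
scale a = width/6, 1 mV peak — at each beat time and adds white Gaussian
noise at the requested SNR relative to the clean signal power.  A single
synthetic channel stands in for a multi-lead montage (lead placement is
physical, not computational), and any sharp biphasic template is adequate
for exercising peak detection; sampling below 128 Hz is rejected as unable
to represent the template.

`detect_r_peaks` implements the Pan–Tompkins stages: 5–15 Hz second-order
Butterworth band-pass (applied zero-phase, so no group-delay correction is
needed and the filtered peak stays aligned with the R wave), derivative,
squaring, 150 ms centred moving-window integration, adaptive dual
signal/noise thresholds with 0.125/0.875 running updates, a 200 ms
refractory period, and a search-back pass triggered at 1.66× the running
RR average with a halved threshold.  Each accepted fiducial is refined to
the local maximum of the band-passed signal within ±100 ms.  Detection is
invariant to DC offset (removed by the band-pass) and an all-zero or
peak-free record returns an empty result with a warning rather than
raising.  On clean synthetic ECG the round trip reproduces the generator's
intervals to within one sample (±1000/fs ms); sensitivity and positive
predictivity are ≥99% down to 10 dB SNR (measured over 50 seeds in the
validation experiments).

RR intervals outside a physiologic gate of [300, 2000] ms are flagged for
per-trial exclusion, never interpolated — no ectopic-correction step is
modelled.  Epoch segmentation uses half-open windows `[start, start+T)` so
a boundary beat is never counted by two adjacent epochs; segmentation is
idempotent and timestamps are trusted as exact (no re-alignment).

## Reference metrics

- **Mean HR** = 60000 / mean(RR): beats per elapsed time over the epoch.
  The alternative, mean(60000/RR), up-weights short intervals; the elapsed-
  time convention matches what an "average HR" over an epoch means and is
  the one consistent with integer-bpm device outputs.
- **Minimum HR**: minimum over sliding windows of the windowed mean HR.
  Ring-style devices report this; their window length is unpublished, so
  it is a knob with a 10 s default.
- **rMSSD** is computed on the smoothing-priors-detrended interval
  sequence by default (raw rMSSD is always carried alongside).  The trend
  is `(I + λ²D₂ᵀD₂)⁻¹ z` on the sequence indexed by beat number; the
  detrender acts as a high-pass with response
  `G(ω) = λ²a(ω) / (1 + λ²a(ω))`, `a(ω) = 16 sin⁴(ω/2)`, whose half-power
  cut-off is solved in closed form.  With λ = 400 interpreted at a 4 Hz
  effective rate the cut-off is ≈ 0.0397 Hz — below the LF band, so
  detrending removes VLF drift while leaving the variability that rMSSD is
  meant to index.  λ = 0 returns an identically zero fluctuation; λ → ∞
  converges to ordinary least-squares line residuals (lines are the null
  space of the second difference), which the tests exercise at λ = 10⁸.

Numerically the trend solve uses banded Cholesky on the pentadiagonal
normal equations (O(n), exact at epoch scale).  Because those equations
condition on λ², extreme λ can lose positive definiteness in double
precision; the solver then falls back to the equivalent stacked least
squares `[I; λD₂]·trend ≈ [z; 0]`, which conditions on λ and recovers the
OLS limit to < 10⁻³ ms.

## Device error models

`DeviceErrorModel` corrupts a copy of the truth in a fixed, testable
order: truncate to the device epoch (half-open, same rule as
segmentation), drop interior beats with probability `missed_beat_prob`,
insert a beat uniformly inside a gap with probability `extra_beat_prob`,
jitter beat times with N(0, σ_jitter), then recompute the summary metrics
and apply summary-level errors — proportional noise (one CV applied to
both HR and rMSSD), additive bias per metric, and optional integer
rounding of HR.  Beat-level corruption before summary-level bias keeps the
corruption order unambiguous; with zero miss/insert probabilities the beat
count is conserved exactly.

The default 7-device panel's error magnitudes echo the published
performance pattern of real consumer panels — a chest strap that reports
integer HR essentially perfectly but degrades on 3-minute rMSSD; ECG-
coupled apps with sub-bpm biases; finger-PPG apps with moderate
proportional noise; a ring that reports minimum rather than mean HR (and
is therefore excluded from mean-HR comparisons); and a camera-PPG app with
~11 bpm HR bias, ~78 ms rMSSD bias and heavy noise.  Because a single CV
couples HR and rMSSD noise, the panel reproduces the *pattern* of
published tables, not their exact values; it is a study template, not a
fitted model of any real device.

## Agreement statistics: exact conventions

- **APE** = |device − reference| / reference × 100; the reference must be
  strictly positive (HR and rMSSD are).
- **Outlier removal**: Tukey outer fences Q3 + 3·IQR / Q1 − 3·IQR,
  quartiles by linear interpolation between order statistics (numpy/R
  type 7), applied once per device/metric group, on the APE values, before
  *all* downstream statistics.  The quartile estimator is configurable
  because fence membership can flip near boundaries; groups of fewer than
  4 values are passed through with a warning.  With IQR = 0 the fences
  collapse to the quartiles, so any value off the mode is flagged — the
  correct degenerate behaviour, and the reason report round trips must be
  bit-exact (a 1-ulp CSV perturbation of a perfect device's zero APEs
  would otherwise flip membership).
- **Lin's CCC** uses population (1/n) moments (the 1989 sample version):
  `2s_xy / (s_x² + s_y² + (x̄−ȳ)²)`.  |CCC| ≤ |Pearson r| always and
  CCC = 1 only for identical pairs; constant input is an error, not a 0.
- **Bland–Altman** differences are device − reference (positive bias =
  overestimation), bias = mean(d), LOA = bias ± 1.96·SD with sample SD
  (ddof 1); 95% CI of the bias via t·SD/√n and of each LOA via the classic
  t·SD·√(3/n) approximation.  The multiplier and alpha are parameters.
- **Bias test**: two-sided one-sample t of mean(d) = 0,
  p_adj = min(1, m·p) with m the Bonferroni family size — by default the
  number of devices present for the metric, since correction is applied
  within each metric family.  Zero-variance differences (a perfect device)
  have no defined t statistic; the report records NA rather than 0 or 1.

HR comparisons use the device's value as reported (integer where the error
model rounds) against the un-rounded reference by default; a
`round_reference` flag switches to integer-vs-integer comparison, under
which an integer-rounding zero-noise device attains MAPE exactly 0.  Both
modes exist because real studies rarely state which convention they used;
the choice is recorded in the report metadata.

Report tables are written with fixed 2-decimal formatting (exact zeros as
"0"), APE tables sorted ascending by MAPE and Bland–Altman tables by LOA
range; `report.json` carries the unrounded values, the config, and any
per-group errors.  Trials are treated as independent: no mixed-effects
modelling of within-subject correlation is attempted, mirroring common
practice in these studies — a caveat for inference on real data.

## Validation experiments and their problem sizes

`hrvagree.experiments` (driven by `scripts/acceptance.py` and the
acceptance tests) measures what the pipeline recovers when truth is known:

- **Parameter recovery**: devices with injected additive bias and
  proportional CV, 200 trials each; the BA bias should match the injected
  bias within 10% (±0.5 bpm near zero) and the LOA width
  2·1.96·CV·rms(reference) within 10%.  A single 200-trial study
  estimates the difference SD with ~5% Monte-Carlo error, so the
  experiment averages 4 replicates — the target is the estimator's
  systematic error, not the luck of one draw.
- **Perfect-device identity**: a zero-error device over 12 trials whose
  reference goes through the full signal path (render at 512 Hz → detect →
  extract → segment → detrended rMSSD).  Residual disagreement bounds the
  pipeline's intrinsic error floor: MAPE < 0.5%, |bias| < 0.5 units,
  CCC > 0.999, observed roughly an order of magnitude inside those bounds.
- **Type-I control**: 10⁴ replicates of a 6-device null family (n = 20
  each); the family-wise rejection rate of the Bonferroni-corrected tests
  stays at/below 0.05 up to binomial noise.  The replicate loop is
  vectorised and spot-checked against the scalar test routine.
- **Detector performance**: 50 seeds × 60 s records, clean and 10 dB SNR;
  pooled sensitivity and PPV ≥ 99% at a 50 ms match tolerance.
- **Rank fidelity**: a 7-device panel whose proportional CV doubles device
  to device (0.015 → 0.96), 30 trials per device, 20 simulated studies;
  the rMSSD MAPE ordering should reproduce the injected ordering in ≥95%
  of studies.  At n = 30 adjacent MAPE gaps are ~3.3 SE wide, so the check
  tests the pipeline rather than sampling luck.

These experiments validate the *statistical machinery* under the
generator's assumptions.  They do not establish anything about real
devices: the generator has no motion artifact, electrode noise,
respiration-driven baseline wander, PPG pulse-transit physics, or skin-tone
effects, its noise is Gaussian and stationary, and its device errors are
simple parametric corruptions.  Passing these checks means the pipeline
measures device error faithfully when device error is what it models.

## Known limitations

- One proportional CV per device couples HR and rMSSD noise; real apps
  have metric-specific error structure.
- The RR generator's closed-form calibration assumes the sinusoid phases
  decorrelate over the epoch; very short epochs (< ~60 s) bias realized
  rMSSD relative to target.
- The detector is tuned for the synthetic template; real ECG with severe
  baseline wander or ectopy would need the artifact handling this package
  deliberately leaves out of scope.
- Quartile-rule ambiguity means reported IQRs and fence decisions can
  differ from software using other quantile types on the same data; the
  rule is a config knob precisely for such comparisons.
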