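# Methods

This note documents the models, algorithms and design choices behind
`qtiholter`, and what the synthetic data can and cannot establish.

## The measurement model

A Holter recording is reduced to at most one (QT, RR) point per
non-overlapping 30-s window:

1. **Beat detection.** The channel is band-passed (5–25 Hz, 3rd-order
   Butterworth, zero phase), squared and smoothed over 120 ms;
   candidate peaks at a 300-ms refractory distance are thresholded at
   a quarter of the 80th-percentile candidate energy (QRS energies sit
   orders of magnitude above T-wave and noise candidates, so the two
   modes separate robustly) and refined to the raw-signal maximum
   within ±40 ms. Positive-dominant R waves are assumed, matching the
   generator's morphology.
2. **Template averaging.** Beats are aligned on the R peak and
   averaged per window. A beat enters the average only if its
   correlation with the window mean — computed on a ±150 ms window
   around the R peak — is at least 0.9. Restricting the correlation to
   the QRS neighbourhood matters: the full 1.05-s segment necessarily
   contains the neighbouring beat's QRS at an RR-dependent offset, and
   correlating over it rejects beats by their RR rather than their
   morphology, which selectively biases the window's RR statistics.
   Windows with fewer than 15 accepted beats yield no template. The
   template's RR is the mean of accepted normal-to-normal intervals of
   the same window (template and RR are paired per window).
3. **QRS onset / isoelectric level.** The baseline is the median of
   the PQ segment (70–45 ms before R); onset is the latest sample
   before R at which two consecutive samples deviate from that
   baseline by less than 1.5% of the R amplitude. The isoelectric
   level is the template voltage at onset.
4. **Tangent T end.** The T apex is the largest excursion from the
   isoelectric level in the window onset + 120 ms to onset +
   min(600 ms, 0.9·RR). On the terminal limb (downslope of an upright
   T, upslope of an inverted T) the steepest point of a 5-point
   smoothed derivative is located; the tangent line is then fitted by
   least squares over the contiguous run of samples (capped at ±8)
   whose smoothed slope stays within 80% of the maximum, and the T end
   is where that line crosses the isoelectric level. On an exactly
   linear limb the fitted line *is* the limb, so the construction is
   closed-form exact; fitting a run rather than taking the single
   steepest derivative sample removes the steeper-by-selection bias
   that white noise otherwise induces (picking the noisiest derivative
   sample shortens QT systematically by several ms at realistic noise).
   Apex excursions below 0.05 mV, tangent slopes shallower than the
   amplitude falling over 500 ms, and intersections beyond
   min(750 ms, 0.9·RR) after onset are flagged `no_t_wave`.

Validity rules: measurements outside (100, 700] ms are flagged
(`qt_gt_700` above 700 ms) and excluded from regression input; useful
registration is the total duration of windows with an `ok`
measurement, and a recording under 4 h of it is invalid. Whether the
700-ms filter applies per template or per recording is a protocol
ambiguity; it is applied per template here, which also reproduces the
recording-level exclusion (a recording long everywhere loses all its
templates and falls under the 4-h rule).

## The subject model

`QTRRModel.fit()` is unweighted OLS of template QT on template RR
(scipy's `linregress`), with the Pearson correlation of the same
points. QTi is the fitted value at RR = 1,000 ms; the 600–1,400 ms
grid is evaluated on the same line. Extrapolation outside the observed
RR range is permitted but flagged — roughly a sixth of real subjects
never reach RR 1,000 ms, and their QTi is still defined. The default
minimum of 480 points ties the regression validity rule to the 4-h
useful-registration rule (480 valid 30-s windows = 4 h); both are
parameters, and deliberately short runs (demos, reduced-duration
simulation studies) scale them together. Degenerate inputs: zero RR
spread is a fit failure; zero QT spread returns slope 0 with r defined
as 0.

## Cohort diagnostics

AUC is the midrank Mann–Whitney estimator computed from placement
values; its variance (and the covariance of two correlated AUCs in the
paired comparison) is DeLong's, with a normal-approximation 95% CI and
two-sided z-test. A curve compared against itself has zero variance of
the placement differences and p exactly 1. "Optimal" cut-offs maximize
the Youden index J = sensitivity + specificity − 1 over observed
thresholds, ties broken toward the lower threshold; positivity is
score ≥ cut-off throughout (high QTi and steep slope are abnormal).
Likelihood ratios follow the standard 2×2 definitions, with LR+ = ∞ at
specificity 1. No multiplicity adjustment is applied. The repeat-
recording comparison is a classical paired two-sided t-test.

## The synthetic generator

The generator's role is to provide recordings whose ground truth is
known exactly, calibrated to the published group distributions.

- **Cohort presets.** `reference_cohort()` carries the per-sex control
  and pooled-LQTS cells (n = 102/99 controls, 115/139 carriers; QTi
  390 ± 19 / 409 ± 21 ms controls, 465 ± 36 / 475 ± 34 ms carriers;
  slopes 0.147 ± 0.031 / 0.189 ± 0.048 controls, 0.212 ± 0.093 /
  0.220 ± 0.088 carriers; mean RR 845/810 and 906/864 ms).
  `genotype_cohort()` resolves carriers into LQT1/LQT2/LQT3 with their
  subtype QTi (460/486/497 ms) and slope (0.180 → sex-split
  0.162/0.193, 0.276 → 0.279/0.273, 0.315) distributions. Subjects
  draw α and QTi from their cell and derive β = QTi − 1000·α, because
  the published tables parameterize QTi, not the intercept; draws are
  clipped to α ∈ [0.02, 0.6] and below the value that would make β
  non-positive (immaterial at the preset parameters).
- **RR model.** One 24-h sinusoid (default amplitude 80 ms, longest RR
  18 h into the recording) plus AR(1) jitter (stationary SD 30 ms,
  coefficient 0.9). These within-subject numbers are free parameters
  chosen to give a realistic day/night RR range — the published
  tables report only between-subject RR spread — and they control the
  RR leverage available to the regression.
- **Beats.** P/Q/R/S as Gaussian deflections (R amplitude 1 mV, R peak
  40 ms after QRS onset); the T wave rises as a half-cosine and falls
  along an exactly linear terminal limb that reaches baseline at
  precisely QT after onset, so the tangent method has a closed-form
  recoverable target. Per-beat QT is α·RR_prev + β + N(0, 5 ms) by
  default, with RR_prev the sample-aligned preceding interval, capped
  at 92% of the cycle. Ectopic beats (default 0.2%) are wide,
  P-less and discordant, carry no QT annotation, and exist to exercise
  the morphology-based rejection. White noise (0.02 mV) and two slow
  baseline-wander sinusoids (≤ 0.06 mV) are added per channel; extra
  channels are gain-scaled copies with independent noise. Defaults:
  200 Hz, 2 channels.
- `simulate_qt_rr_points` produces the template-level scatter directly
  (window-averaged RR, QT noise shrunk by √beats-per-window) for
  statistical-level studies where waveform rendering adds nothing.

**What passing tests show — and don't.** The generator's beats are
morphologically stereotyped, its T-end is geometrically ideal by
construction, and its noise is stationary and Gaussian. Recovery of α
to ±0.01 and QTi to ±3 ms therefore validates the *algorithmic chain*
(detection → averaging → tangent → regression), not performance on
clinical recordings, where T-wave morphology variants (biphasic,
notched, low-amplitude), non-stationary artifacts and rhythm disorders
dominate the error budget. Conversely, the cohort-level AUCs,
cut-offs and slope-rule specificities depend only on the group
distributions, which are taken directly from the published tables, so
their reproduction is a property of the statistics, not of the signal
model.

## Problem sizes

Simulation studies are sized for a single-CPU run: parameter-recovery
sweeps use 50 subjects at 2-h duration (with the validity rules scaled
to 1 h / 200 points accordingly), the template-count check uses one
full 24-h recording, cohort AUC reproduction averages 1,000 replicate
Gaussian cohorts per sex, slope-rule specificities use 10⁶ draws, and
the repeat-recording stability study uses 30 cohort replicates of 20
subjects at the measurement-scatter level. Larger runs change nothing
but the Monte-Carlo error.

## Known limitations

- Linear QT–RR only; subject-specific curvilinear models and QT
  hysteresis (the QT lag behind abrupt RR changes) are out of scope.
- The beat detector assumes positive-dominant R waves at Holter-like
  sampling rates (≥ 128 Hz); it is not a general-purpose arrhythmia-
  robust detector.
- The Youden criterion is one defensible reading of "optimal cut-off";
  a different criterion shifts recovered cut-offs by a few ms.
- DeLong CIs use the normal approximation; no exact small-sample CI.
- ISHNE support targets the standard 1.0 layout (16-bit little-endian,
  per-lead nV resolution); vendor dialects with variable-format
  sample blocks are not parsed.
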