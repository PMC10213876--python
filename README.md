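# qtiholter

Individualized QT interval (QTi) analysis of 24-h Holter ECG for
long-QT-syndrome (LQTS) screening — with a calibrated synthetic-Holter
generator so the entire measurement chain is testable end to end.

## The problem

The QT interval varies with heart rate. Clinical practice corrects the
QT measured at an arbitrary rate to the value expected at 60 beats/min
using a generalized formula (Bazett: QTc = QT/√RR), but generalized
formulas encode an average rate dependence that individual subjects —
and especially carriers of congenital LQTS mutations, whose QT rate
dependence is itself altered — do not follow. About a quarter of
mutation carriers have a normal resting QTc ("concealed" LQTS).

The individualized alternative measures the subject's *own* QT–RR
relation over a full day. A 24-h recording is reduced to one averaged
beat waveform per 30-s window (up to 2,880 templates); on each
template the T-wave end is located by the **tangent method** — the
intersection of the maximum-slope tangent on the T wave's terminal
limb with the isoelectric line (the voltage at QRS onset) — and each
QT is paired with the mean RR of its window. Ordinary least squares
over these points gives

```
QT = α · RR + β
```

where α (the **QT–RR slope**) quantifies QT rate dependence, and

```
QTi = α · 1000 + β
```

is the fitted QT at an RR interval of 1,000 ms: a measured quantity on
the subject's own regression line, with no correction formula
involved. Cohort-level ROC analysis of QTi with sex-specific cut-offs
(430 ms in males, 445 ms in females; a high QTi is abnormal) then
separates LQTS carriers from controls; steep QT–RR slopes (≥ 0.25,
≥ 0.30) serve as highly specific secondary markers.

Templates with QT > 700 ms are filtered out, and a recording with
fewer than 4 h of windows yielding a valid measurement is excluded.

## What is in the package

- `qtiholter.simulate` — synthetic multichannel Holter recordings with
  known QT–RR ground truth: circadian + AR(1) RR model, beats whose
  T wave terminal limb is exactly linear (so the tangent target is
  closed-form), noise, baseline wander, ectopic beats, flat-T and
  long-QT pathologies; cohort presets calibrated to published control
  and LQTS group distributions.
- `qtiholter.processing` — R-peak detection, 30-s template averaging
  with morphology-based beat rejection, QRS-onset location, tangent
  T-end location, per-recording validity accounting.
- `qtiholter.regression` — `QTRRModel` / `QTRRResults`: the per-subject
  OLS fit, Pearson r, QTi at 1,000 ms and on the 600–1,400 ms grid
  with extrapolation flags.
- `qtiholter.diagnostics` — `QTiCohortModel` / `QTiCohortResults`:
  midrank (Mann–Whitney) AUC with DeLong confidence intervals, DeLong
  paired ROC comparison, Youden cut-offs, sensitivity / specificity /
  accuracy / likelihood ratios, slope-threshold rules and the paired-t
  repeat-recording comparison.
- `qtiholter.ishne` — reader/writer for the ISHNE 1.0 Holter `.ecg`
  format.
- `qtiholter.cli` — `qtiholter simulate | measure | fit | evaluate |
  run-all`.

## Worked example

```python
import numpy as np
from qtiholter import (reference_cohort, sample_subject,
                       generate_recording, subject_qti)

rng = np.random.default_rng(11)
spec = reference_cohort()
profile = sample_subject(spec, "LQTS", "female", rng)
print("true slope:", round(profile.alpha_true, 3),
      "true QTi:", round(profile.qti_true, 1))

recording, truth = generate_recording(profile, duration_s=6 * 3600, rng=rng)
results, report = subject_qti(recording)
print(results.summary())
```

prints

```
true slope: 0.223 true QTi: 521.2
QT-RR linear regression (QT = alpha * RR + beta)
------------------------------------------------
n points                   720
alpha (QT-RR slope)     0.2170  (SE 0.0074)
beta (ms)                302.2  (SE 7.3)
Pearson r                0.737
RR range (ms)          899 - 1073
QTi at 1,000 ms          519.1 ms
```

The 6-h recording yields 720 valid 30-s templates; the fitted slope
0.217 and QTi 519.1 ms recover the subject's programmed values (0.223,
521.2 ms) to within the sampling error of the scatter. A QTi of 519 ms
in a female is far above the 445-ms cut-off: test-positive.

At cohort level:

```python
import pandas as pd
from qtiholter import QTiCohortModel

# cohort: DataFrame with subject_id, sex, label (1 = LQTS), qti_1000, alpha
results = QTiCohortModel(cohort).fit()
print(results.summary())
```

```
QTi cohort diagnostics (n = 455)
====================================================
male: AUC 0.984 (95% CI 0.967-1.000), Youden cut-off 422 ms (sens 91%, spec 99%)
female: AUC 0.961 (95% CI 0.940-0.983), Youden cut-off 437 ms (sens 90%, spec 96%)
pooled rule (male >= 430 ms, female >= 445 ms):
  sensitivity 83%  specificity 98%  accuracy 89%
  LR+ 33.4  LR- 0.17
slope >= 0.25: sens 35%, spec 96%
slope >= 0.30: sens 19%, spec 100%
```

Here the cohort was drawn from the `reference_cohort()` preset (one
random replicate, hence cut-offs a few ms from their population
values); the AUCs near 0.97/0.96, the near-430/445-ms Youden cut-offs
and the highly specific slope rules are the expected behaviour of the
method on cohorts with these group distributions.

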