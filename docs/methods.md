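# Methods

This note records the scientific and numerical choices behind `qthf`: what is
modelled, what is assumed, which knobs matter, and what the synthetic tests
do and do not establish about real ECGs.

## Signal model and the band-power estimator

The quantity of interest is the power of the 85–130 Hz component of the ECG
along one QT complex.  We use a continuous wavelet transform with an analytic
Morlet kernel, center-frequency parameter ω₀ = 6, implemented directly in the
frequency domain: the filter at center frequency f is the Gaussian
`exp(-(ν-f)²/(2σ²))` with σ = f/ω₀ applied to positive frequencies only
(doubled, so the output is the analytic signal of the band component).  The
band is sampled at 1 Hz spacing (46 voices).

**Normalization.** Wavelet power conventions differ across libraries, so the
package pins its own: squared coefficient magnitudes are scaled by
`ω₀ / (2√π f)`, which makes the band-integrated power of a mid-band tone of
amplitude A equal the tone's mean power A²/2.  This calibration is enforced
by a test against an independent periodogram (agreement within 10%; observed
≈ 7% low, from the Gaussian tails truncated at the band edges).

**Band-edge taper.** The estimator is a bank of Gaussian filters, so signal
at the very edges of the 85–130 Hz band is captured with roughly half
weight.  A broadband injection spanning 85–115 Hz is therefore recovered at
≈ 0.84 of its true energy — uniformly across patients, leads, and
conditions, so group contrasts, ratios, and attenuation percentages are
unaffected.  Absolute metric values should be read as estimator-convention
dependent, as they are for any published wavelet pipeline.

**Edge effects.** The transform runs on the representative beat with at
least 250 ms of real signal on each side of the QT window before clipping,
which keeps the cone of influence of the 85 Hz kernel (σ_t ≈ 11 ms) well
clear of the window edges.

**Metrics.** Peak Power is the maximum of p(t); the three Total powers are
trapezoidal time-integrals with the J-point sample split half/half between
the QRS and ST terms so that `Total = QRS + ST` is exact.  Powers are
reported divided by 10³ (the conventional 10³ nV² scale).  The QRS/ST ratio
is undefined (NaN) when Total ST Power is zero.  Lead→patient aggregation
takes arithmetic means of powers and the mean of per-lead ratios — published
group-level ratios are not the ratio of group-mean powers, which shows that
ratios are averaged at the individual level; we keep that convention at
every aggregation step.

## Delineation

All delineation is per lead, on a zero-phase 40 Hz low-passed copy (windows
are then applied to the unfiltered samples):

* R peaks: Pan–Tompkins-style derivative-energy detection on a 5–25 Hz
  band-passed copy (squared, 120 ms moving average, 30% adaptive threshold,
  300 ms refractory), refined to the raw |signal| maximum within ±50 ms.
* QRS onset/offset: outward scan from the steepest flank for the first
  sustained (4 ms) drop of the smoothed derivative magnitude below 5% of its
  QRS maximum, within −80/+120 ms of R.
* T end: tangent method — the tangent at the steepest point of the T
  downslope (slope from a ±12 ms least-squares line) extrapolated to the
  baseline (median of the low-passed beat).
* Representative beat: pointwise median of R-aligned beats; a beat is
  rejected when its correlation with the running template is below 0.9.
  Single accepted beat ⇒ the representative equals that beat.  QT durations
  outside 0.2–0.7 s are flagged.

Under white noise at 20 dB SNR the representative-beat fiducials stay within
10 ms of ground truth (tested over 200 beats); single-beat delineation
degrades to ~15 ms worst case at that SNR, which is why the pipeline always
delineates the median beat.

## Synthetic cohort generator

The generator exists to give every downstream stage a ground-truth surface,
not to be physiological.  One beat is a sum of raised-cosine P and R bumps
plus a T wave with a cos² rise and a linear fall, Gaussian-smoothed
(σ = 5 ms) so the template's own power above 85 Hz is far below 1% of its
total (verified by an FFT oracle).  The linear T downslope makes the tangent
T-end estimate land on the true support end by construction.  Fiducials are
the exact placement indices.

High-frequency substrate content is a Tukey-tapered (taper fraction 0.1)
oscillation — a tone, or a sum of random-phase tones spanning a configured
bandwidth (default 85–115 Hz) — confined to the QRS and/or ST window and
rescaled so the injected energy is exactly A²·T/2 regardless of taper and
phase draw.  The post-drug record scales injected amplitudes by
(1 − drug_attenuation_fraction), i.e. power by its square; with the default
fraction 0.3, Total Power attenuation on injection-dominated beats is
1 − 0.7² ≈ 51%.

Default study conditions (chosen once):

| parameter | default | rationale |
|---|---|---|
| group sizes | 43 / 112 / 182 | the three study groups (spontaneous, induced, negative responders) |
| ST-window amplitude means | 433 / 421 / 272 nV | put group-mean Total ST Power near 28 / 27 / 11 (10³ nV² units) via A²·T/2 |
| QRS-window amplitude means | 610 / 840 / 648 nV | same construction for the QRS metric |
| amplitude SDs | ≈ 30% of the mean | between-patient spread |
| injection band | 100 ± 15 Hz | substrate content spread across the analysis band |
| noise_sd | 0.5 µV RMS | small white acquisition noise; median of 8 beats keeps its in-band residual ≈ 1–2 units |
| drug_attenuation_fraction | 0.3 | no published value; fixed at a moderate effect |
| record length | 8 beats at 60 bpm, 1 kHz (500 Hz in large batch runs) | enough beats for the median; ≥ 500 Hz keeps Nyquist clear of 130 Hz |
| outcome models | logistic; Total ST Power OR 1.25 per 10³ nV² unit, age/covariate effects small | independent covariates keep recovery tests interpretable |

Continuous covariates enter the outcome models centered at their configured
means, so the intercept sets baseline prevalence.  With an OR of 1.25 per
metric unit and a metric SD of ~10 units the diagnostic signal is strong
(full-model AUC ≈ 0.9); the simulated effect sizes are test conditions, not
estimates of the clinical effect.

What the generator does **not** emulate: realistic QRS morphology and the
Brugada type I–III repolarization patterns, beat-to-beat variability,
respiration and baseline wander, muscle artifact, pharmacokinetics, or any
correlation structure among clinical covariates.  Passing tests therefore
establish that the pipeline measures what it claims on signals with known
content — not that the clinical effect sizes would be reproduced on patient
data.  Mains interference is off by default but available
(`mains_hum_amplitude`: 50 Hz plus a 0.3-weighted 100 Hz harmonic, the
latter inside the analysis band) for sensitivity studies; whether mains
filtering is appropriate before this analysis is an open practical question.

## Statistics

Dispatch: unpaired Student t (two groups) or one-way ANOVA (three or more)
for continuous variables; chi-square without continuity correction
(switchable) for categorical.  Logistic fits are maximum likelihood with
Wald CIs; effects are reported as **odds ratios** — source tables for this
kind of analysis sometimes label such columns "HR", but the models specified
and fitted here are logistic, so OR is the correct reading.  Perfect
separation is detected and flagged (with a weakly-ridged fallback fit)
rather than silently diverging; singular designs raise an error naming the
collinear columns.  No multiple-testing correction is applied.

AUCs are Mann–Whitney statistics computed from midrank placement values; the
DeLong comparison uses the empirical covariance of the paired placement
values, with p = 1 by convention when the two score vectors are identical.
Type-I error of the t, chi-square and DeLong procedures is verified at
5% ± 1.5% under simulated nulls (2000 replicates each), and the AUC and
odds-ratio pathways are pinned to brute-force pair-counting and 2×2
cross-product oracles.

The incremental-value analysis — the pipeline's headline output — fits the
reduced (clinical) and full (clinical + Total ST Power) models on the same
subjects, scores both with fitted probabilities, and reports ΔAUC with the
paired DeLong p.  An intercept-only reduced model yields AUC 0.5 exactly.

## Problem sizes and determinism

Everything is a pure function of the configuration seed; identical
config + seed gives byte-identical outputs.  Batch runs in the test suite
and the acceptance script use 500 Hz records with 3–8 beats and two-lead
(V1/V2) cohorts where only right-precordial metrics are needed; replicate
studies use 100 cohorts of n = 300.  These sizes are the package's own
choices for desk-scale reproduction of a 337-patient design.

## Known limitations

* WFDB ingestion is stubbed (informative error): only the CSV dialect is
  read.  No resampling is performed; sub-500 Hz records are rejected rather
  than upsampled, since resampling filters would alter in-band content.
* The tangent T-end method is biased early on smoothly rounded T waves;
  the synthetic template's near-linear downslope avoids this by design, and
  expert fiducial overrides (CSV sidecar) are supported for real data.
* Absolute power values depend on the stated normalization convention and
  on band-edge taper; comparisons across groups/conditions are the intended
  use.
* The covariate-selection rule for multivariate models is explicit (caller
  supplied); no automatic variable selection is implemented.
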