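# qthf — high-frequency wavelet power of the ECG QT interval

`qthf` quantifies the 85–130 Hz content of the QT complex on standard
12-lead ECGs and asks whether that content improves diagnosis and risk
stratification in Brugada syndrome (BrS).  Intracardiac mapping studies
locate the BrS arrhythmogenic substrate in the right-ventricular outflow
tract epicardium, where electrograms show abnormal high-frequency potentials
extending through the late QRS and into the ST segment.  If those potentials
leak into the surface ECG, a time–frequency decomposition of the QT interval
should see them — without the long, noise-sensitive recordings that
signal-averaged late-potential analysis requires.

The package is aimed at cardiac-electrophysiology researchers who want a
tested, reproducible implementation of the method: a synthetic ECG cohort
generator with exact ground truth, QT delineation, the wavelet band-power
computation, and the biostatistics layer used to judge incremental
predictive value.

## Method

For each lead a representative (median) beat is built from the R-aligned
beats of the record, and its QT window `[QRS onset, T end]` is delineated.
A continuous wavelet transform (analytic Morlet, ω₀ = 6) is evaluated on a
1 Hz grid of center frequencies spanning the band B = [85, 130] Hz, and the
squared magnitudes, normalized to a power spectral density, are integrated
across the band to give the in-band power at each time epoch:

    p(t) = Σ_{f ∈ B} |W(f, t)|² · ω₀ / (2√π f) · Δf        [nV²]

From p(t) five metrics are computed (reported in 10³ nV² units):

* **Peak Power** = max_t p(t)
* **Total Power** = ∫ p dt over the QT window
* **Total QRS Power** = ∫ p dt over [QRS onset, J point]
* **Total ST Power** = ∫ p dt over [J point, T end]
* **QRS/ST ratio** = Total QRS Power / Total ST Power

Integration is trapezoidal with the J-point sample shared between the two
sub-integrals, so `Total = QRS + ST` holds exactly.  Patient-level metrics
average the per-lead values over a lead subset (all precordial, or right
precordial V1–V2); the ratio averages per-lead ratios rather than dividing
mean powers.

The statistics layer compares metrics across groups (Student t / one-way
ANOVA / chi-square), fits univariate and multivariate logistic models for
(a) a positive response to sodium-blocker drug challenge and (b) arrhythmic
events during follow-up, and tests whether adding Total ST Power to the
clinical covariates increases the ROC area, using the DeLong test for
correlated ROC curves.

## Worked example

```python
from qthf import (BeatTemplateParams, HfInjection, generate_record,
                  build_representative_beat, band_power_timecourse,
                  compute_metrics)

params = BeatTemplateParams()                      # 60 bpm, 1 kHz, 12 leads
inj = HfInjection(center_frequency=100.0, bandwidth=30.0,
                  amplitude=0.00045, window="ST", phase_seed=7)
record, truth = generate_record(params, n_beats=8, noise_sd=0.0005,
                                rng=1, injection=inj)
beat = build_representative_beat(record, "V1")
m = compute_metrics(band_power_timecourse(beat))
print(f"beats averaged : {beat.n_beats_averaged}")
print(f"QT duration    : {beat.segment.qt_duration(1000.0)*1e3:.0f} ms")
print(f"Total Power    : {m.total_power:8.3f}")
print(f"Total QRS Power: {m.total_qrs_power:8.3f}")
print(f"Total ST Power : {m.total_st_power:8.3f}")
```

prints

```
beats averaged : 7
QT duration    : 404 ms
Total Power    :   31.329
Total QRS Power:    0.673
Total ST Power :   30.656
```

The injected 0.45 µV, 85–115 Hz oscillation confined to the ST segment
carries a true in-band energy of 30.5 (10³ nV² units, = A²·T/2); the
pipeline recovers it in Total ST Power while the spectrally clean QRS
contributes almost nothing.  One noisy beat of the eight was rejected by the
correlation gate of the median-beat builder.

The same analysis runs from the shell:

```sh
qthf simulate --config cohort.yaml --out cohort/ --seed 7
qthf run-all  --input cohort/ --out run/ --leads right_precordial
```

`run/` then contains per-patient metrics (`metrics.csv`), the group
comparison table (`table_groups.csv`), univariate/multivariate model tables
(`table_models.csv`), the ROC comparison (`roc_comparison.json`), per-patient
drug attenuation (`attenuation.csv`), and a `manifest.json` recording the
config hash, seed and per-stage record counts.

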