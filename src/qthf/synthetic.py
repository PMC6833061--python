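"""Synthetic ECG cohort generator with known ground truth.

Every downstream stage of the pipeline (delineation, wavelet band power,
group statistics) is tested against cohorts produced here, because the
quantities of interest — fiducial positions, injected high-frequency energy,
covariate effect sizes — are all known exactly by construction.

The beat template is deliberately *not* a physiological model: P wave and R
wave are raised-cosine (Hann) bumps and the T wave has a smooth rise and a
near-linear downslope, all low-pass smoothed so that the intrinsic spectral
content above 85 Hz is negligible.  What matters for testing is (a) exact
fiducial geometry and (b) clean spectral separation between the template and
the injected 85–130 Hz components that model the abnormal high-frequency
potentials recorded over the arrhythmogenic substrate in Brugada syndrome.

Amplitudes in the public API are in mV (the familiar ECG unit); records are
stored in nV like everything else in the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal.windows import tukey

from .ecg_io import CANONICAL_LEADS, EcgRecord, GROUP_LABELS, write_ecg

MV_TO_NV = 1e6

#: fractions of the ST interval occupied by (isoelectric gap, T rise, T fall)
_T_GAP_FRAC, _T_RISE_FRAC, _T_FALL_FRAC = 0.20, 0.55, 0.25
_P_DURATION_S = 0.10      # P-wave width
_PR_INTERVAL_S = 0.16     # P onset to QRS onset
_SMOOTH_SIGMA_S = 0.005   # Gaussian smoothing of the template
_TAPER_FRACTION = 0.1     # Tukey taper of injected oscillations


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass
class BeatTemplateParams:
    """Geometry and amplitudes of one synthetic beat.

    Durations are in ms, amplitudes in mV, sampling_rate in Hz.
    ``lead_scales`` multiplies the template per lead (12 entries, one per
    canonical lead order); injected high-frequency components are *not*
    scaled by it.
    """

    heart_rate: float = 60.0
    r_amplitude: float = 1.0
    qrs_duration: float = 100.0
    st_duration: float = 300.0
    p_amplitude: float = 0.15
    t_amplitude: float = 0.30
    lead_scales: tuple = tuple(1.0 for _ in CANONICAL_LEADS)
    sampling_rate: float = 1000.0

    def validate(self) -> None:
        if self.sampling_rate < 500:
            raise ConfigurationError(
                f"sampling_rate {self.sampling_rate} Hz below the 500 Hz floor"
            )
        if not 20 < self.heart_rate < 250:
            raise ConfigurationError(f"heart_rate {self.heart_rate} outside (20, 250)")
        if self.qrs_duration <= 0:
            raise ConfigurationError(f"qrs_duration {self.qrs_duration} must be > 0")
        if self.st_duration <= 0:
            raise ConfigurationError(f"st_duration {self.st_duration} must be > 0")
        period = 60.0 / self.heart_rate
        needed = 0.30 + (self.qrs_duration + self.st_duration) / 1e3 + 0.27
        if needed > period:
            raise ConfigurationError(
                f"beat of {needed * 1e3:.0f} ms does not fit a {period * 1e3:.0f} ms "
                "cycle: lower heart_rate or shorten qrs_duration/st_duration"
            )

    @property
    def period_samples(self) -> int:
        return int(round(60.0 / self.heart_rate * self.sampling_rate))


# QtSegment lives in delineation; import late to avoid a cycle at module load.
def _make_segment(r_peak, qrs_onset, qrs_offset, t_end):
    from .delineation import QtSegment

    return QtSegment(r_peak=r_peak, qrs_onset=qrs_onset,
                     qrs_offset=qrs_offset, t_end=t_end)


def _template_waveform(params: BeatTemplateParams):
    """One beat of the single-lead template (unit lead scale), plus fiducials."""
    fs = params.sampling_rate
    n = params.period_samples
    x = np.zeros(n)

    i_on = int(round(0.30 * fs))
    i_off = i_on + int(round(params.qrs_duration / 1e3 * fs))
    i_tend = i_off + int(round(params.st_duration / 1e3 * fs))
    i_r = i_on + (i_off - i_on) // 2

    def hann_bump(center_amp, lo, hi):
        m = hi - lo + 1
        if m >= 3 and lo >= 0 and hi < n:
            x[lo:hi + 1] += center_amp * np.hanning(m)

    # R wave
    hann_bump(params.r_amplitude * MV_TO_NV, i_on, i_off)
    # P wave
    p_on = i_on - int(round(_PR_INTERVAL_S * fs))
    p_off = p_on + int(round(_P_DURATION_S * fs))
    hann_bump(params.p_amplitude * MV_TO_NV, p_on, p_off)
    # T wave: flat gap, cos^2 rise, linear fall ending exactly at i_tend
    st_n = i_tend - i_off
    t_start = i_off + int(round(_T_GAP_FRAC * st_n))
    t_peak = t_start + int(round(_T_RISE_FRAC * st_n))
    amp = params.t_amplitude * MV_TO_NV
    if t_peak > t_start:
        k = np.arange(t_start, t_peak + 1)
        x[k] += amp * 0.5 * (1 - np.cos(np.pi * (k - t_start) / (t_peak - t_start)))
    if i_tend > t_peak:
        k = np.arange(t_peak + 1, i_tend + 1)
        x[k] += amp * (i_tend - k) / (i_tend - t_peak)

    x = gaussian_filter1d(x, sigma=_SMOOTH_SIGMA_S * fs, mode="nearest")
    return x, (i_r, i_on, i_off, i_tend)


def generate_beat(params: BeatTemplateParams):
    """Generate one averaged beat per lead plus its ground-truth fiducials.

    Returns
    -------
    (EcgRecord, QtSegment)
        The record holds one beat cycle for each canonical lead; the segment
        gives the exact sample indices at which the template pieces were
        placed.
    """
    params.validate()
    wave, (i_r, i_on, i_off, i_tend) = _template_waveform(params)
    scales = np.asarray(params.lead_scales, dtype=float)
    if scales.shape != (len(CANONICAL_LEADS),):
        raise ConfigurationError(
            f"lead_scales must have {len(CANONICAL_LEADS)} entries, got {scales.shape}"
        )
    data = scales[:, None] * wave[None, :]
    rec = EcgRecord(data, list(CANONICAL_LEADS), params.sampling_rate)
    return rec, _make_segment(i_r, i_on, i_off, i_tend)


@dataclass
class HfInjection:
    """A band-limited oscillation confined to the QRS and/or ST window.

    center_frequency / bandwidth in Hz, amplitude in mV.  With zero bandwidth
    a single tone is injected; otherwise a sum of unit tones with random
    phases spanning the band.  The oscillation is Tukey-tapered (taper
    fraction 0.1) and rescaled so that the energy added to the window equals
    amplitude^2 * window_duration / 2 regardless of taper or phase draw.
    """

    center_frequency: float = 100.0
    bandwidth: float = 0.0
    amplitude: float = 0.0005
    window: str = "ST"
    phase_seed: int = 0

    def validate(self, sampling_rate: float) -> None:
        if self.amplitude < 0:
            raise ConfigurationError(f"amplitude {self.amplitude} must be >= 0")
        if self.window not in ("QRS", "ST", "BOTH"):
            raise ConfigurationError(f"window {self.window!r} not one of QRS/ST/BOTH")
        top = self.center_frequency + self.bandwidth / 2
        if top >= sampling_rate / 2:
            raise ConfigurationError(
                f"injection reaches {top} Hz, at or above Nyquist "
                f"({sampling_rate / 2} Hz)"
            )


def _window_bounds(seg, window: str):
    if window == "QRS":
        return seg.qrs_onset, seg.qrs_offset
    if window == "ST":
        return seg.qrs_offset, seg.t_end
    return seg.qrs_onset, seg.t_end


def make_injection_waveform(n_samples: int, seg, inj: HfInjection, fs: float) -> np.ndarray:
    """The additive oscillation (nV) on the full beat grid; zero outside the window."""
    lo, hi = _window_bounds(seg, inj.window)
    if lo < 0 or hi >= n_samples:
        raise ConfigurationError("injection window does not fit inside the beat")
    m = hi - lo + 1
    out = np.zeros(n_samples)
    if inj.amplitude == 0 or m < 8:
        return out
    rng = np.random.default_rng(inj.phase_seed)
    t = np.arange(m) / fs
    if inj.bandwidth <= 0:
        raw = np.cos(2 * np.pi * inj.center_frequency * t + rng.uniform(0, 2 * np.pi))
    else:
        n_comp = max(3, int(round(inj.bandwidth)) + 1)
        freqs = np.linspace(inj.center_frequency - inj.bandwidth / 2,
                            inj.center_frequency + inj.bandwidth / 2, n_comp)
        phases = rng.uniform(0, 2 * np.pi, n_comp)
        raw = np.cos(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    raw *= tukey(m, _TAPER_FRACTION)
    rms = math.sqrt(float(np.mean(raw**2)))
    target_rms = inj.amplitude * MV_TO_NV / math.sqrt(2.0)
    out[lo:hi + 1] = raw * (target_rms / rms)
    return out


def inject_hf_component(beat: EcgRecord, seg, inj: HfInjection,
                        leads: list[str] | None = None) -> EcgRecord:
    """Return a copy of ``beat`` with the injection added to the given leads
    (all leads by default)."""
    inj.validate(beat.sampling_rate)
    delta = make_injection_waveform(beat.n_samples, seg, inj, beat.sampling_rate)
    out = beat.copy()
    names = beat.lead_names if leads is None else leads
    for name in names:
        out.data[beat.lead_names.index(name)] += delta
    return out


def injected_window_energy(amplitude_mv: float, seg, window: str, fs: float) -> float:
    """Closed-form injected energy amplitude^2 * T / 2, in nV^2 * s."""
    lo, hi = _window_bounds(seg, window)
    duration = (hi - lo + 1) / fs
    return (amplitude_mv * MV_TO_NV) ** 2 * duration / 2.0


# --------------------------------------------------------------------------
# cohort-level generation

@dataclass
class GroupHf:
    """Normal distribution of injected HF amplitudes (nV) for one group."""

    qrs_amp_mean: float
    qrs_amp_sd: float
    st_amp_mean: float
    st_amp_sd: float


def _default_group_hf():
    # Amplitudes chosen so that the group-mean ST / QRS metrics land near the
    # all-precordial values reported for spontaneous-BrS / induced-BrS / NR
    # cohorts: metric (10^3 nV^2 units) = A^2 * T_window / 2 / 10^3.
    return {
        "Spont-BrS": GroupHf(610.0, 180.0, 433.0, 130.0),
        "Induct-BrS": GroupHf(840.0, 250.0, 421.0, 126.0),
        "NR": GroupHf(648.0, 194.0, 272.0, 82.0),
    }


def _default_prevalences():
    return {
        "male": 0.72, "fh_scd": 0.47, "fh_brs": 0.25, "syncope": 0.28,
        "cardiac_syncope": 0.07, "pes_positive": 0.04, "scn5a": 0.20,
    }


def _default_drug_coefs():
    # Log-odds of a positive drug challenge; total_st_power enters per
    # reported unit (10^3 nV^2), centered at the configured overall mean.
    return {
        "intercept": -0.3, "age": 0.02, "male": -0.3, "fh_scd": 0.2,
        "fh_brs": 0.3, "syncope": -0.1, "total_st_power": math.log(1.25),
    }


def _default_event_coefs():
    return {
        "intercept": -2.8, "cardiac_syncope": 1.6, "syncope": 0.8,
        "male": 0.1, "total_st_power": 0.02,
    }


@dataclass
class CohortConfig:
    """Full specification of a synthetic study cohort.

    Group sizes default to the study design (43 spontaneous-BrS, 112
    drug-induced BrS, 182 negative responders).  ``drug_attenuation_fraction``
    scales injected HF *amplitudes* on the post-drug record by (1 - fraction).
    Outcome coefficients are log-odds; continuous covariates (age, true Total
    ST Power in reported units) are centered at their configured means so the
    intercept sets the baseline prevalence.
    """

    n_per_group: tuple = (43, 112, 182)
    hf: dict = field(default_factory=_default_group_hf)
    drug_attenuation_fraction: float = 0.3
    age_mean: float = 41.0
    age_sd: float = 14.5
    prevalences: dict = field(default_factory=_default_prevalences)
    drug_model_coefs: dict = field(default_factory=_default_drug_coefs)
    event_model_coefs: dict = field(default_factory=_default_event_coefs)
    noise_sd: float = 0.0005          # mV RMS of additive white noise
    mains_hum_amplitude: float = 0.0  # mV; 50 Hz + 100 Hz harmonic, off by default
    seed: int = 0
    beat: BeatTemplateParams = field(default_factory=BeatTemplateParams)
    n_beats: int = 8
    leads: tuple = tuple(CANONICAL_LEADS)
    post_drug: bool = True

    def validate(self) -> None:
        self.beat.validate()
        if len(self.n_per_group) != 3 or any(n < 0 for n in self.n_per_group):
            raise ConfigurationError(f"n_per_group {self.n_per_group} invalid")
        if not 0 <= self.drug_attenuation_fraction < 1:
            raise ConfigurationError(
                f"drug_attenuation_fraction {self.drug_attenuation_fraction} outside [0, 1)"
            )
        for k, p in self.prevalences.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"prevalence {k}={p} outside [0, 1]")
        for g in GROUP_LABELS:
            if g not in self.hf:
                raise ConfigurationError(f"hf amplitudes missing for group {g!r}")
        unknown = set(self.leads) - set(CANONICAL_LEADS)
        if unknown:
            raise ConfigurationError(f"unknown leads {sorted(unknown)}")
        if self.n_beats < 1:
            raise ConfigurationError("n_beats must be >= 1")


@dataclass
class PatientTruth:
    """Ground truth for one synthetic patient."""

    fiducials: tuple          # per-beat-template (r, onset, offset, t_end)
    beat_period: int          # samples between beats
    n_beats: int
    qrs_amp_nv: float
    st_amp_nv: float
    true_qrs_power: float     # reported units, 10^3 nV^2
    true_st_power: float
    lp_drug: float
    lp_event: float


@dataclass
class CohortResult:
    records: list             # EcgRecord, baseline first, then post-drug
    clinical: "pd.DataFrame"  # noqa: F821 - pandas imported lazily below
    truth: dict               # patient_id -> PatientTruth
    config: CohortConfig


def _reported_power(amp_nv: float, seg, window: str, fs: float) -> float:
    lo, hi = _window_bounds(seg, window)
    return amp_nv**2 * ((hi - lo + 1) / fs) / 2.0 / 1e3


def generate_cohort(config: CohortConfig) -> CohortResult:
    """Draw a full cohort: ECG records, clinical table, ground truth.

    Output is a pure function of ``config`` (including its seed): two calls
    with equal configs are bit-identical.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    beat_clean, seg = generate_beat(config.beat)
    fs = config.beat.sampling_rate
    n_beat = beat_clean.n_samples
    lead_idx = [list(CANONICAL_LEADS).index(l) for l in config.leads]
    base_wave = beat_clean.data[lead_idx]

    # reference means for centering the outcome models
    st_ref = float(np.mean([
        _reported_power(self_hf.st_amp_mean, seg, "ST", fs) for self_hf in
        (config.hf[g] for g in GROUP_LABELS)
    ]))

    records: list[EcgRecord] = []
    rows = []
    truth: dict[str, PatientTruth] = {}
    prefixes = {"Spont-BrS": "S", "Induct-BrS": "I", "NR": "N"}
    noise_nv = config.noise_sd * MV_TO_NV

    for group, n_group in zip(GROUP_LABELS, config.n_per_group):
        hf = config.hf[group]
        for k in range(n_group):
            pid = f"{prefixes[group]}{k + 1:03d}"
            a_qrs = max(0.0, rng.normal(hf.qrs_amp_mean, hf.qrs_amp_sd))
            a_st = max(0.0, rng.normal(hf.st_amp_mean, hf.st_amp_sd))
            seeds = rng.integers(0, 2**31 - 1, size=2)
            delta = (
                make_injection_waveform(
                    n_beat, seg,
                    HfInjection(100.0, 30.0, a_qrs / MV_TO_NV, "QRS", int(seeds[0])),
                    fs)
                + make_injection_waveform(
                    n_beat, seg,
                    HfInjection(100.0, 30.0, a_st / MV_TO_NV, "ST", int(seeds[1])),
                    fs)
            )

            covs = {
                "age": float(rng.normal(config.age_mean, config.age_sd)),
            }
            for name, p in config.prevalences.items():
                covs[name] = int(rng.random() < p)
            covs["spont_type1"] = int(group == "Spont-BrS")

            true_st = _reported_power(a_st, seg, "ST", fs)
            true_qrs = _reported_power(a_qrs, seg, "QRS", fs)

            def _lp(coefs):
                lp = coefs.get("intercept", 0.0)
                lp += coefs.get("age", 0.0) * (covs["age"] - config.age_mean)
                lp += coefs.get("total_st_power", 0.0) * (true_st - st_ref)
                for name in config.prevalences:
                    lp += coefs.get(name, 0.0) * covs[name]
                lp += coefs.get("spont_type1", 0.0) * covs["spont_type1"]
                return float(lp)

            lp_drug = _lp(config.drug_model_coefs)
            lp_event = _lp(config.event_model_coefs)
            covs["drug_test_positive"] = int(rng.random() < 1 / (1 + math.exp(-lp_drug)))
            covs["event"] = int(rng.random() < 1 / (1 + math.exp(-lp_event)))

            conditions = [("baseline", 1.0)]
            if config.post_drug:
                conditions.append(("post_drug", 1.0 - config.drug_attenuation_fraction))
            for condition, scale in conditions:
                one = base_wave + (scale * delta)[None, :]
                data = np.tile(one, (1, config.n_beats))
                if noise_nv > 0:
                    data = data + rng.normal(0.0, noise_nv, size=data.shape)
                if config.mains_hum_amplitude > 0:
                    t = np.arange(data.shape[1]) / fs
                    hum = config.mains_hum_amplitude * MV_TO_NV * (
                        np.sin(2 * np.pi * 50.0 * t) + 0.3 * np.sin(2 * np.pi * 100.0 * t)
                    )
                    data = data + hum[None, :]
                records.append(EcgRecord(data, list(config.leads), fs,
                                         patient_id=pid, condition=condition))

            rows.append({"patient_id": pid, "group": group, **covs})
            truth[pid] = PatientTruth(
                fiducials=(seg.r_peak, seg.qrs_onset, seg.qrs_offset, seg.t_end),
                beat_period=n_beat, n_beats=config.n_beats,
                qrs_amp_nv=a_qrs, st_amp_nv=a_st,
                true_qrs_power=true_qrs, true_st_power=true_st,
                lp_drug=lp_drug, lp_event=lp_event,
            )

    columns = ["patient_id", "group", "age", "male", "fh_scd", "fh_brs",
               "syncope", "cardiac_syncope", "spont_type1", "pes_positive",
               "scn5a", "drug_test_positive", "event"]
    clinical = pd.DataFrame(rows, columns=columns)
    return CohortResult(records, clinical, truth, config)


def generate_record(params: BeatTemplateParams, n_beats: int = 10,
                    noise_sd: float = 0.0, rng=None,
                    injection: HfInjection | None = None):
    """A multi-beat single-template record, for delineation tests.

    Returns (EcgRecord, list of per-beat QtSegments).
    """
    rec, seg = generate_beat(params)
    delta = 0.0
    if injection is not None:
        injection.validate(params.sampling_rate)
        delta = make_injection_waveform(rec.n_samples, seg, injection,
                                        params.sampling_rate)
    one = rec.data + np.asarray(delta)[None, :] if injection is not None else rec.data
    data = np.tile(one, (1, n_beats))
    if noise_sd > 0:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        data = data + rng.normal(0.0, noise_sd * MV_TO_NV, size=data.shape)
    segs = []
    n = rec.n_samples
    for b in range(n_beats):
        segs.append(_make_segment(seg.r_peak + b * n, seg.qrs_onset + b * n,
                                  seg.qrs_offset + b * n, seg.t_end + b * n))
    record = EcgRecord(data, list(rec.lead_names), params.sampling_rate)
    return record, segs


def write_cohort(result: CohortResult, outdir, units: str = "mV") -> None:
    """Persist a cohort: one ECG CSV per patient per condition, clinical.csv,
    ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in result.records:
        write_ecg(rec, outdir / f"{rec.patient_id}_{rec.condition}.csv", units=units)
    result.clinical.to_csv(outdir / "clinical.csv", index=False)
    truth_json = {pid: asdict(t) for pid, t in result.truth.items()}
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_json, fh, indent=1, default=float)
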