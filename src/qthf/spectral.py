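"""High-frequency (85–130 Hz) wavelet power of the QT interval.

The core quantity is the in-band power-per-epoch function p(t): a continuous
wavelet transform (analytic Morlet, ω0 = 6) is evaluated on a 1 Hz grid of
center frequencies spanning the band, the squared coefficient magnitudes are
normalized to a power spectral density, and the density is integrated across
the band.  For a pure in-band tone of amplitude A the plateau of p(t) equals
the tone's mean power A²/2, which is how the normalization constant is pinned
(and cross-checked against an independent periodogram in the test suite —
wavelet power conventions differ between libraries and are worth not
trusting).

From p(t) restricted to [QRS onset, T end] the five summary metrics are:

* Peak Power        — max_t p(t)
* Total Power       — ∫ p dt over the whole QT window
* Total QRS Power   — ∫ p dt over [QRS onset, J point]
* Total ST Power    — ∫ p dt over [J point, T end]
* QRS/ST ratio      — Total QRS Power / Total ST Power

Integration is trapezoidal with the J-point sample shared half-and-half
between the QRS and ST integrals, so Total = QRS + ST holds exactly.  Power
metrics are reported divided by 10³ (the conventional 10³ nV² Hz⁻¹ scale).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .delineation import QtSegment, RepresentativeBeat
from .ecg_io import PRECORDIAL_LEADS, RIGHT_PRECORDIAL_LEADS

logger = logging.getLogger(__name__)

REPORT_SCALE = 1e3          # metrics reported in units of 10^3 nV^2
DEFAULT_OMEGA0 = 6.0
DEFAULT_CONTEXT_S = 0.25    # real-signal context kept on each side of the QT window


@dataclass(frozen=True)
class BandSpec:
    """Frequency band of interest, Hz."""

    f_low: float = 85.0
    f_high: float = 130.0

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(f"invalid band ({self.f_low}, {self.f_high})")
        if self.f_high >= sampling_rate / 2:
            raise ValueError(
                f"band edge {self.f_high} Hz at or above Nyquist ({sampling_rate / 2} Hz)"
            )

    def frequencies(self, df: float = 1.0) -> np.ndarray:
        return np.arange(self.f_low, self.f_high + df / 2, df)


@dataclass
class PowerFunction:
    """In-band power per time epoch over the QT window.

    ``t`` is in seconds relative to QRS onset; ``p`` is the band-integrated
    power (nV²), one value per sample of [qrs_onset, t_end].  ``j_index``
    locates the QRS offset (J point) within the arrays.
    """

    t: np.ndarray
    p: np.ndarray
    j_index: int
    sampling_rate: float


def morlet_cwt_power(x: np.ndarray, fs: float, freqs: np.ndarray,
                     omega0: float = DEFAULT_OMEGA0) -> np.ndarray:
    """PSD-normalized squared CWT magnitude, shape (n_freqs, n_samples), nV²/Hz.

    The analytic Morlet filter at center frequency f has the Gaussian
    frequency response exp(-(ν-f)²/(2σ²)) with σ = f/ω0 (constant-Q).  The
    normalization |W|²·ω0/(2√π f) makes the band-integrated power of an
    in-band tone equal A²/2 (see module docstring).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    nfft = 1 << max(8, int(math.ceil(math.log2(2 * n))))
    X = np.fft.fft(x, nfft)
    nu = np.fft.fftfreq(nfft, d=1.0 / fs)
    freqs = np.asarray(freqs, dtype=float)
    sigma = freqs / omega0
    # analytic filter bank: positive frequencies only, doubled
    H = np.exp(-((nu[None, :] - freqs[:, None]) ** 2) / (2.0 * sigma[:, None] ** 2))
    H[:, nu <= 0] = 0.0
    W = np.fft.ifft(X[None, :] * (2.0 * H), axis=1)[:, :n]
    psd = (np.abs(W) ** 2) * (omega0 / (2.0 * math.sqrt(math.pi) * freqs[:, None]))
    return psd


def band_power_timecourse(beat: RepresentativeBeat,
                          band: BandSpec = BandSpec(),
                          df: float = 1.0,
                          omega0: float = DEFAULT_OMEGA0,
                          context_s: float = DEFAULT_CONTEXT_S) -> PowerFunction:
    """p(t): cumulative in-band power at each epoch of the QT interval.

    The transform runs on the representative-beat waveform including at least
    ``context_s`` of real signal on each side of the QT window before the
    result is clipped to [qrs_onset, t_end], so the cone of influence at the
    lowest band frequency does not contaminate the window edges.
    """
    fs = beat.sampling_rate
    band.validate(fs)
    seg = beat.segment
    ctx = int(round(context_s * fs))
    if seg.qrs_onset - ctx < 0 or seg.t_end + ctx >= len(beat.waveform):
        logger.warning(
            "lead %s: only %.0f/%.0f ms of context around the QT window",
            beat.lead,
            1e3 * min(seg.qrs_onset, len(beat.waveform) - 1 - seg.t_end) / fs,
            1e3 * context_s,
        )
    freqs = band.frequencies(df)
    psd = morlet_cwt_power(beat.waveform, fs, freqs, omega0)
    p = psd.sum(axis=0) * df                       # integrate across the band
    p = p[seg.qrs_onset:seg.t_end + 1]
    t = np.arange(len(p)) / fs
    return PowerFunction(t=t, p=p, j_index=seg.qrs_offset - seg.qrs_onset,
                         sampling_rate=fs)


@dataclass
class SpectralMetrics:
    """The five summary metrics, power fields in 10³ nV² units.

    ``qrs_st_ratio`` is NaN when Total ST Power is zero (undefined ratio).
    """

    peak_power: float
    total_power: float
    total_qrs_power: float
    total_st_power: float
    qrs_st_ratio: float

    def as_dict(self) -> dict:
        return {
            "peak_power": self.peak_power,
            "total_power": self.total_power,
            "total_qrs_power": self.total_qrs_power,
            "total_st_power": self.total_st_power,
            "qrs_st_ratio": self.qrs_st_ratio,
        }


POWER_FIELDS = ("peak_power", "total_power", "total_qrs_power", "total_st_power")


def compute_metrics(pf: PowerFunction) -> SpectralMetrics:
    """Summaries of a power function; trapezoidal, exactly additive at the J point."""
    p, j = pf.p, pf.j_index
    if len(p) < 2 or not 0 < j < len(p) - 1:
        raise ValueError(f"degenerate QT window (length {len(p)}, J at {j})")
    dt = 1.0 / pf.sampling_rate
    qrs = float(np.trapezoid(p[:j + 1], dx=dt))
    st = float(np.trapezoid(p[j:], dx=dt))
    total = qrs + st
    peak = float(p.max())
    ratio = qrs / st if st > 0 else float("nan")
    if st == 0:
        logger.info("Total ST Power is zero; QRS/ST ratio flagged missing")
    return SpectralMetrics(
        peak_power=peak / REPORT_SCALE,
        total_power=total / REPORT_SCALE,
        total_qrs_power=qrs / REPORT_SCALE,
        total_st_power=st / REPORT_SCALE,
        qrs_st_ratio=ratio,
    )


LEAD_SUBSETS = {
    "all_precordial": PRECORDIAL_LEADS,
    "right_precordial": RIGHT_PRECORDIAL_LEADS,
}


def aggregate_patient(metrics_by_lead: dict[str, SpectralMetrics],
                      subset: str = "all_precordial") -> SpectralMetrics:
    """Patient-level metrics: arithmetic mean across the subset's leads.

    The ratio is the mean of per-lead ratios, NOT the ratio of mean powers —
    group-level summaries in this field average patient-level ratios, and the
    same convention is used at the lead level.  NaN per-lead ratios are
    excluded from the ratio mean.
    """
    try:
        wanted = LEAD_SUBSETS[subset]
    except KeyError:
        raise ValueError(f"unknown lead subset {subset!r}") from None
    present = [l for l in wanted if l in metrics_by_lead]
    if not present:
        raise ValueError(f"no leads of subset {subset!r} available")
    missing = [l for l in wanted if l not in metrics_by_lead]
    if missing:
        logger.warning("subset %s: missing leads %s", subset, ", ".join(missing))
    vals = {f: float(np.mean([getattr(metrics_by_lead[l], f) for l in present]))
            for f in POWER_FIELDS}
    ratios = [metrics_by_lead[l].qrs_st_ratio for l in present
              if not math.isnan(metrics_by_lead[l].qrs_st_ratio)]
    vals["qrs_st_ratio"] = float(np.mean(ratios)) if ratios else float("nan")
    return SpectralMetrics(**vals)


def compute_attenuation(baseline: SpectralMetrics,
                        post_drug: SpectralMetrics) -> dict[str, float]:
    """Per-metric drug attenuation, percent: 100·(baseline − post)/baseline.

    NaN where the baseline metric is zero.
    """
    out = {}
    for f in POWER_FIELDS:
        b, p = getattr(baseline, f), getattr(post_drug, f)
        out[f] = 100.0 * (b - p) / b if b != 0 else float("nan")
    return out
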