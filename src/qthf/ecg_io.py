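"""Reading and writing multi-lead ECG records and the clinical covariate table.

Internally every voltage is stored in nanovolts (nV) because the spectral
metrics downstream are reported in units of 10^3 nV^2 Hz^-1; unit conversion
happens exactly once, at ingestion.  Records must arrive sampled at >= 500 Hz:
the analysis band extends to 130 Hz and no resampling is performed (resampling
filters would alter in-band content).

The on-disk ECG format is a plain CSV dialect: a first column ``time_s``, one
column per lead named by its canonical label, a mandatory header row, and an
optional leading comment line ``# units=mV`` declaring the amplitude unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)
PRECORDIAL_LEADS: tuple[str, ...] = ("V1", "V2", "V3", "V4", "V5", "V6")
#: V1 and V2, the leads overlying the right ventricular outflow tract.
RIGHT_PRECORDIAL_LEADS: tuple[str, ...] = ("V1", "V2")

MIN_SAMPLING_RATE = 500.0

#: multiplicative factors to nV
_UNIT_TO_NV = {"nv": 1.0, "uv": 1e3, "µv": 1e3, "μv": 1e3, "mv": 1e6, "v": 1e9}

_CANONICAL_BY_LOWER = {name.lower(): name for name in CANONICAL_LEADS}

CLINICAL_COLUMNS = [
    "patient_id", "group", "age", "male", "fh_scd", "fh_brs", "syncope",
    "cardiac_syncope", "spont_type1", "pes_positive", "scn5a",
    "drug_test_positive", "event",
]

GROUP_LABELS = ("Spont-BrS", "Induct-BrS", "NR")


class EcgFormatError(ValueError):
    """Raised when an ECG file cannot be ingested under the pipeline's contract."""


def canonical_lead_name(name: str) -> str | None:
    """Return the canonical spelling of a lead label (case-insensitive), or None."""
    return _CANONICAL_BY_LOWER.get(name.strip().lower())


def unit_to_nv(units: str) -> float:
    try:
        return _UNIT_TO_NV[units.strip().lower()]
    except KeyError:
        raise EcgFormatError(
            f"unknown amplitude unit {units!r}; expected one of mV, uV, nV, V"
        ) from None


@dataclass
class EcgRecord:
    """A multi-lead sampled voltage signal.

    Attributes
    ----------
    data : (n_leads, n_samples) float array, amplitudes in nV.
    lead_names : ordered lead labels, unique, canonical spellings.
    sampling_rate : Hz.
    patient_id : identifier; empty for anonymous records.
    condition : "baseline" or "post_drug".
    """

    data: np.ndarray
    lead_names: list[str]
    sampling_rate: float
    patient_id: str = ""
    condition: str = "baseline"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.lead_names):
            raise ValueError(
                f"{self.data.shape[0]} signal rows for {len(self.lead_names)} lead names"
            )
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValueError("lead names must be unique")
        if self.condition not in ("baseline", "post_drug"):
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def lead(self, name: str) -> np.ndarray:
        canon = canonical_lead_name(name) or name
        try:
            return self.data[self.lead_names.index(canon)]
        except ValueError:
            raise KeyError(f"lead {name!r} not present in record") from None

    def has_lead(self, name: str) -> bool:
        canon = canonical_lead_name(name) or name
        return canon in self.lead_names

    def copy(self) -> "EcgRecord":
        return replace(self, data=self.data.copy(), lead_names=list(self.lead_names))


def write_ecg(record: EcgRecord, path, units: str = "mV") -> None:
    """Write a record in the CSV dialect (time_s + one column per lead)."""
    factor = unit_to_nv(units)
    t = np.arange(record.n_samples) / record.sampling_rate
    df = pd.DataFrame({"time_s": t})
    for i, name in enumerate(record.lead_names):
        df[name] = record.data[i] / factor
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# units={units}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_ecg(path, format: str = "csv", units: str | None = None) -> EcgRecord:
    """Read an ECG record, converting voltages to nV.

    Parameters
    ----------
    format : "csv" (the dialect above) or "wfdb" (requires the ``wfdb``
        package, which this installation does not ship).
    units : amplitude unit of the stored values; overridden by a
        ``# units=...`` comment line when present.

    Raises
    ------
    EcgFormatError
        Unknown units, missing header, or sampling rate below 500 Hz (the
        85-130 Hz analysis band requires a Nyquist frequency comfortably
        above 130 Hz).
    """
    if format == "wfdb":
        raise EcgFormatError(
            "WFDB ingestion requires the optional 'wfdb' package, which is not "
            "installed; convert the record to the CSV dialect instead"
        )
    if format != "csv":
        raise EcgFormatError(f"unknown ECG format {format!r}")

    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    declared = None
    if first.startswith("#"):
        body = first.lstrip("#").strip()
        key, _, val = body.partition("=")
        if key.strip().lower() == "units":
            declared = val.strip()
    df = pd.read_csv(path, skiprows=1 if first.startswith("#") else 0)
    df.columns = pd.Index([str(c).strip() for c in df.columns])
    if declared is not None:
        units = declared
    if units is None:
        raise EcgFormatError(f"{path}: no amplitude unit declared (pass units= or add '# units=')")
    factor = unit_to_nv(units)

    cols = [str(c) for c in df.columns]
    if not cols or cols[0] != "time_s":
        raise EcgFormatError(f"{path}: first column must be 'time_s', got {cols[:1]}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise EcgFormatError(f"{path}: record too short")
    dt = np.median(np.diff(t))
    fs = 1.0 / dt
    if fs < MIN_SAMPLING_RATE - 1e-6:
        raise EcgFormatError(
            f"{path}: sampling rate {fs:.1f} Hz is below the 500 Hz floor required "
            "for the 85–130 Hz analysis band"
        )

    lead_names: list[str] = []
    rows: list[np.ndarray] = []
    for col in cols[1:]:
        canon = canonical_lead_name(col)
        if canon is None:
            logger.warning("%s: ignoring non-lead column %r", path, col)
            continue
        lead_names.append(canon)
        rows.append(df[col].to_numpy(dtype=float) * factor)
    if not rows:
        raise EcgFormatError(f"{path}: no recognizable lead columns")
    missing = [l for l in CANONICAL_LEADS if l not in lead_names]
    if missing:
        logger.warning("%s: leads absent, analysis restricted: %s", path, ", ".join(missing))
    return EcgRecord(np.vstack(rows), lead_names, float(fs))


def read_clinical(path) -> pd.DataFrame:
    """Read the per-patient clinical covariate table."""
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise EcgFormatError(f"{path}: clinical table must have a patient_id column")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise EcgFormatError(f"{path}: duplicate patient_id values {dup}")
    if "group" in df.columns:
        bad = set(df["group"].dropna()) - set(GROUP_LABELS)
        if bad:
            raise EcgFormatError(f"{path}: unknown group labels {sorted(bad)}")
    return df


METRIC_TABLE_COLUMNS = [
    "patient_id", "condition", "lead_subset",
    "peak_power", "total_power", "total_qrs_power", "total_st_power", "qrs_st_ratio",
]


def write_metrics_table(table: pd.DataFrame, path) -> None:
    """Write a metrics/cohort table as CSV, floats at 6 significant digits.

    An empty table produces a header-only file and a logged warning.
    """
    if table.empty:
        logger.warning("writing empty table to %s (header only)", path)
    table.to_csv(path, index=False, float_format="%.6g")
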