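"""End-to-end orchestration: simulate → delineate → spectral → stats.

A run is a pure function of its RunConfig (including the seed on synthetic
input): the manifest records the config hash, seed, software version, and
per-stage record counts so that two runs with the same inputs are verifiably
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .delineation import (DelineationError, apply_override,
                          build_representative_beat, detect_r_peaks,
                          load_fiducial_overrides)
from .ecg_io import (EcgFormatError, EcgRecord, read_clinical, read_ecg,
                     write_metrics_table)
from .spectral import (BandSpec, LEAD_SUBSETS, SpectralMetrics, aggregate_patient,
                       band_power_timecourse, compute_attenuation, compute_metrics)
from .stats import (StatsError, comparison_rows_to_frame, group_comparison_table,
                    incremental_value_analysis, univariate_logistic)
from .synthetic import CohortConfig, CohortResult, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

EXIT_OK, EXIT_CONFIG_ERROR, EXIT_DATA_ERROR = 0, 2, 3

DEFAULT_DIAGNOSTIC_COVARIATES = ["age", "fh_brs"]
DEFAULT_PROGNOSTIC_COVARIATES = ["cardiac_syncope"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_dir: str | None = None          # existing cohort; None -> simulate
    simulate: CohortConfig | None = None
    band: BandSpec = field(default_factory=BandSpec)
    lead_subsets: tuple = ("all_precordial", "right_precordial")
    diagnostic_covariates: list = field(default_factory=lambda: list(DEFAULT_DIAGNOSTIC_COVARIATES))
    prognostic_covariates: list = field(default_factory=lambda: list(DEFAULT_PROGNOSTIC_COVARIATES))
    metric_column: str = "total_st_power"
    metric_subset: str = "right_precordial"
    fiducial_overrides: str | None = None
    out_dir: str = "qthf_run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        self.band.validate(1e9)  # fs-dependent part re-checked per record
        for s in self.lead_subsets:
            if s not in LEAD_SUBSETS:
                raise ValueError(f"unknown lead subset {s!r}")
        if self.input_dir is None and self.simulate is None:
            self.simulate = CohortConfig(seed=self.seed)


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (flat keys matching the fields)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    if "band" in raw:
        cfg.band = BandSpec(*[float(v) for v in raw.pop("band")])
    if "simulate" in raw:
        sim = raw.pop("simulate") or {}
        cohort = CohortConfig()
        for k, v in sim.items():
            if not hasattr(cohort, k):
                raise ValueError(f"unknown simulate key {k!r}")
            if k == "n_per_group" or k == "leads":
                v = tuple(v)
            setattr(cohort, k, v)
        cfg.simulate = cohort
    for k, v in raw.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config key {k!r}")
        if k == "lead_subsets":
            v = tuple(v)
        setattr(cfg, k, v)
    return cfg


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return float(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def analyze_record(record: EcgRecord, band: BandSpec,
                   overrides: dict | None = None) -> dict[str, SpectralMetrics]:
    """Per-lead spectral metrics for one record (leads that fail are skipped)."""
    out: dict[str, SpectralMetrics] = {}
    for lead in record.lead_names:
        try:
            peaks = detect_r_peaks(record, lead)
            if len(peaks) == 0:
                raise DelineationError("no R peaks")
            beat = build_representative_beat(record, lead, peaks)
            if overrides and (record.patient_id, lead) in overrides:
                beat = apply_override(beat, overrides[(record.patient_id, lead)])
            pf = band_power_timecourse(beat, band)
            out[lead] = compute_metrics(pf)
        except DelineationError as exc:
            logger.warning("patient %s lead %s excluded: %s",
                           record.patient_id, lead, exc)
    return out


def metrics_table(records: list[EcgRecord], band: BandSpec,
                  lead_subsets=("all_precordial", "right_precordial"),
                  overrides: dict | None = None) -> pd.DataFrame:
    """Long-form per-patient metrics: one row per (patient, condition, subset)."""
    rows = []
    for rec in records:
        by_lead = analyze_record(rec, band, overrides)
        for subset in lead_subsets:
            try:
                agg = aggregate_patient(by_lead, subset)
            except ValueError as exc:
                logger.warning("patient %s %s: %s", rec.patient_id, subset, exc)
                continue
            rows.append({"patient_id": rec.patient_id, "condition": rec.condition,
                         "lead_subset": subset, **agg.as_dict()})
    cols = ["patient_id", "condition", "lead_subset", "peak_power", "total_power",
            "total_qrs_power", "total_st_power", "qrs_st_ratio"]
    return pd.DataFrame(rows, columns=cols)


def attenuation_table(metrics: pd.DataFrame,
                      lead_subset: str = "right_precordial") -> pd.DataFrame:
    """Per-patient percent attenuation of each power metric after drug infusion."""
    sub = metrics[metrics["lead_subset"] == lead_subset]
    base = sub[sub["condition"] == "baseline"].set_index("patient_id")
    post = sub[sub["condition"] == "post_drug"].set_index("patient_id")
    rows = []
    for pid in base.index.intersection(post.index):
        b = SpectralMetrics(**{k: base.loc[pid, k] for k in
                               ("peak_power", "total_power", "total_qrs_power",
                                "total_st_power", "qrs_st_ratio")})
        p = SpectralMetrics(**{k: post.loc[pid, k] for k in
                               ("peak_power", "total_power", "total_qrs_power",
                                "total_st_power", "qrs_st_ratio")})
        rows.append({"patient_id": pid,
                     **{f"{k}_attenuation_pct": v
                        for k, v in compute_attenuation(b, p).items()}})
    return pd.DataFrame(rows)


def join_cohort(clinical: pd.DataFrame, metrics: pd.DataFrame,
                lead_subset: str = "right_precordial",
                condition: str = "baseline") -> pd.DataFrame:
    """Clinical table with the chosen subset's baseline metrics joined on."""
    sel = metrics[(metrics["lead_subset"] == lead_subset)
                  & (metrics["condition"] == condition)]
    sel = sel.drop(columns=["condition", "lead_subset"])
    return clinical.merge(sel, on="patient_id", how="left")


def load_cohort_dir(input_dir) -> tuple[list[EcgRecord], pd.DataFrame]:
    """Read every `<patient>_<condition>.csv` ECG plus clinical.csv from a directory."""
    input_dir = Path(input_dir)
    clinical = read_clinical(input_dir / "clinical.csv")
    records = []
    for path in sorted(input_dir.glob("*.csv")):
        if path.name == "clinical.csv":
            continue
        stem = path.stem
        pid, _, condition = stem.rpartition("_")
        if condition not in ("baseline", "post_drug") or not pid:
            # allow plain "<patient>.csv" as a baseline record
            pid, condition = stem, "baseline"
        rec = read_ecg(path, format="csv")
        rec.patient_id, rec.condition = pid, condition
        records.append(rec)
    if not records:
        raise EcgFormatError(f"no ECG records found in {input_dir}")
    return records, clinical


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Outputs: metrics.csv, attenuation.csv (when post-drug records exist),
    table_groups.csv, table_models.csv, roc_comparison.json, manifest.json.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(config), "seed": config.seed,
                      "version": __version__, "stages": {}}

    if config.input_dir is not None:
        records, clinical = load_cohort_dir(config.input_dir)
    else:
        sim = config.simulate
        result: CohortResult = generate_cohort(sim)
        records, clinical = result.records, result.clinical
    manifest["stages"]["input"] = {
        "patients": int(clinical.shape[0]), "records": len(records),
    }
    if clinical.empty:
        raise EcgFormatError("empty cohort: no patients to analyze")

    overrides = (load_fiducial_overrides(config.fiducial_overrides)
                 if config.fiducial_overrides else None)
    metrics = metrics_table(records, config.band, config.lead_subsets, overrides)
    write_metrics_table(metrics, out / "metrics.csv")
    analyzed = set(metrics["patient_id"])
    manifest["stages"]["spectral"] = {
        "patients_analyzed": len(analyzed),
        "patients_excluded": sorted(set(clinical["patient_id"]) - analyzed),
        "rows": int(metrics.shape[0]),
    }

    if (metrics["condition"] == "post_drug").any():
        atten = attenuation_table(metrics, config.metric_subset)
        write_metrics_table(atten, out / "attenuation.csv")
        manifest["stages"]["attenuation"] = {"patients": int(atten.shape[0])}

    cohort = join_cohort(clinical, metrics, config.metric_subset)
    write_metrics_table(cohort, out / "cohort.csv")

    # group-comparison table over the spectral metrics
    metric_vars = ["peak_power", "total_power", "total_qrs_power",
                   "total_st_power", "qrs_st_ratio"]
    try:
        rows = group_comparison_table(cohort.dropna(subset=["total_st_power"]),
                                      metric_vars, "group")
        comparison_rows_to_frame(rows).to_csv(out / "table_groups.csv", index=False)
        manifest["stages"]["group_table"] = {"variables": len(rows)}
    except StatsError as exc:
        logger.warning("group table skipped: %s", exc)
        manifest["stages"]["group_table"] = {"skipped": str(exc)}

    roc_json: dict = {}
    model_blocks = []
    for label, outcome, base in (
        ("diagnostic", "drug_test_positive", config.diagnostic_covariates),
        ("prognostic", "event", config.prognostic_covariates),
    ):
        sub = cohort
        if label == "diagnostic":
            # the drug challenge is only defined for tested patients
            sub = cohort[cohort["group"].isin(["Induct-BrS", "NR"])]
            if sub.empty:
                sub = cohort
        try:
            uni = univariate_logistic(sub, outcome,
                                      base + [config.metric_column])
            uni.insert(0, "model", label + "/univariate")
            model_blocks.append(uni.reset_index())
            inc = incremental_value_analysis(sub, base, config.metric_column, outcome)
            multi = inc.fit_full.table.copy()
            multi.insert(0, "model", label + "/multivariate")
            multi.index.name = "covariate"
            model_blocks.append(multi.reset_index())
            roc_json[label] = {
                "auc_full": inc.comparison.auc_full,
                "auc_reduced": inc.comparison.auc_reduced,
                "auc_difference": inc.comparison.auc_difference,
                "z": inc.comparison.z,
                "p_value": inc.comparison.p_value,
                "n": int(inc.roc_full.n_pos + inc.roc_full.n_neg),
            }
            manifest["stages"][label] = {"n": roc_json[label]["n"]}
        except StatsError as exc:
            logger.warning("%s model skipped: %s", label, exc)
            manifest["stages"][label] = {"skipped": str(exc)}
    if model_blocks:
        pd.concat(model_blocks, ignore_index=True).to_csv(
            out / "table_models.csv", index=False, float_format="%.6g")
    with open(out / "roc_comparison.json", "w", encoding="utf-8") as fh:
        json.dump(roc_json, fh, indent=1)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
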