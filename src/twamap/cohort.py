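"""Eligibility rules, exposure/outcome assembly and the analysis-ready cohort
table.

Eligibility follows the study design: operations with a valid CPB window and
invasive MAP sampled at at-least-five-minute resolution throughout CPB; one
operation per patient (the first qualifying one). Exclusions are data, not
errors — every excluded operation is counted by reason in an
:class:`AttritionReport` with the conservation invariant
``n_input == n_eligible + sum(exclusions)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence


import pandas as pd

from .config import PipelineConfig
from .exposure import resolution_check, twa_below
from .kdigo import baseline_creatinine, crrt_outcome, kdigo_stage
from .types import (
    AkiResult,
    AnalysisWindow,
    LabSeries,
    MapSeries,
    NoBaselineError,
    OperationRecord,
    SchemaError,
    UnknownDrugError,
)

__all__ = [
    "AttritionReport",
    "apply_eligibility",
    "vasopressor_dose_total",
    "compute_exposures",
    "adjudicate_outcomes",
    "build_cohort",
    "run_pipeline",
    "ckd_epi_2009",
    "egfr_stratum",
]


@dataclass
class AttritionReport:
    n_input: int = 0
    n_eligible: int = 0
    exclusions: dict[str, int] = field(default_factory=dict)

    def exclude(self, reason: str, n: int = 1) -> None:
        self.exclusions[reason] = self.exclusions.get(reason, 0) + n

    def check(self) -> None:
        if self.n_input != self.n_eligible + sum(self.exclusions.values()):
            raise AssertionError(f"attrition conservation violated: {self}")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_eligible": self.n_eligible,
            "exclusions": dict(self.exclusions),
        }


def apply_eligibility(
    operations: Sequence[OperationRecord],
    vitals: Mapping[object, MapSeries],
    max_gap_min: float = 5.0,
) -> tuple[list[OperationRecord], AttritionReport]:
    """Keep operations with a valid CPB window, MAP data covering CPB at the
    required resolution, and at most one operation per patient (first by
    absolute surgery start)."""
    report = AttritionReport(n_input=len(operations))
    ordered = sorted(operations, key=lambda o: (str(o.patient_id), o.surgery_start, str(o.op_id)))
    eligible: list[OperationRecord] = []
    seen_patients: set = set()
    for op in ordered:
        if op.invalid_reason is not None:
            report.exclude(op.invalid_reason)
            continue
        if not op.has_cpb:
            report.exclude("no_cpb")
            continue
        series = vitals.get(op.op_id)
        if series is None or series.n == 0:
            report.exclude("no_map_data")
            continue
        window = AnalysisWindow("cpb", op.cpb_start, op.cpb_stop)
        res = resolution_check(series, window, max_allowed_gap=max_gap_min)
        if not res.ok:
            report.exclude("insufficient_resolution")
            continue
        if op.patient_id in seen_patients:
            report.exclude("reoperation")
            continue
        seen_patients.add(op.patient_id)
        eligible.append(op)
    report.n_eligible = len(eligible)
    report.check()
    return eligible, report


def vasopressor_dose_total(
    doses: Mapping[str, float],
    weights: Optional[Mapping[str, float]] = None,
) -> float:
    """Norepinephrine-equivalent total over per-drug intraoperative doses.

    Raises :class:`UnknownDrugError` naming any drug absent from the weight
    table — silent zero-weighting would corrupt the covariate.
    """
    from .config import DEFAULT_VASOPRESSOR_WEIGHTS

    w = dict(DEFAULT_VASOPRESSOR_WEIGHTS if weights is None else weights)
    unknown = [d for d in doses if d not in w]
    if unknown:
        raise UnknownDrugError(f"no equivalence weight for drug(s): {unknown}")
    return float(sum(w[d] * v for d, v in doses.items()))


def compute_exposures(
    op: OperationRecord,
    series: MapSeries,
    thresholds: Sequence[float] = (65.0, 75.0),
    interpolate_crossings: bool = True,
) -> dict[str, float]:
    """TWA exposure columns for the CPB and post-CPB windows at each
    threshold. Post-CPB values are NaN when that window is absent or not
    computable (no samples past CPB stop)."""
    out: dict[str, float] = {"cpb_time": op.cpb_minutes}
    cpb = AnalysisWindow("cpb", op.cpb_start, op.cpb_stop)
    for thr in thresholds:
        key = f"twa{int(thr)}"
        out[f"{key}_cpb"] = twa_below(series, cpb, thr, interpolate_crossings).twa_below
        post_val = math.nan
        if op.cpb_stop < op.surgery_end:
            post = AnalysisWindow("post_cpb", op.cpb_stop, op.surgery_end)
            try:
                post_val = twa_below(series, post, thr, interpolate_crossings).twa_below
            except Exception:
                post_val = math.nan
        out[f"{key}_postcpb"] = post_val
    return out


def adjudicate_outcomes(
    op: OperationRecord,
    labs: Optional[LabSeries],
    crrt_postop,
    config: PipelineConfig,
) -> tuple[Optional[AkiResult], bool, Optional[str], list[str]]:
    """KDIGO adjudication + CRRT outcome for one eligible operation.

    Returns (aki_result, crrt, exclusion_reason, qc_notes); exclusion_reason
    is non-None when the patient cannot be adjudicated (no baseline, or no
    postoperative labs under the 'exclude' policy).
    """
    notes: list[str] = []
    crrt, crrt_notes = crrt_outcome(crrt_postop)
    notes.extend(crrt_notes)
    if labs is None or labs.n == 0:
        return None, crrt, "no_baseline", notes
    try:
        baseline = baseline_creatinine(labs, 0.0, config.baseline_policy)
    except NoBaselineError:
        return None, crrt, "no_baseline", notes
    result = kdigo_stage(
        labs, baseline, 0.0, rrt=crrt, horizon_days=config.horizon_days
    )
    if "no_postop_labs" in result.flags:
        if config.no_postop_labs_policy == "exclude":
            return None, crrt, "no_postop_labs", notes
        notes.append("no_postop_labs")
    return result, crrt, None, notes


# --- eGFR helper (labeled assumption: CKD-EPI 2009, strata 90/60/45/30/15) ---

def ckd_epi_2009(scr_mg_dl: float, age: float, female: bool) -> float:
    """Estimated GFR (mL/min/1.73m²), CKD-EPI 2009 creatinine equation
    without the race term."""
    kappa = 0.7 if female else 0.9
    alpha = -0.329 if female else -0.411
    ratio = scr_mg_dl / kappa
    egfr = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993 ** age
    if female:
        egfr *= 1.018
    return egfr


_EGFR_CUTS = (90.0, 60.0, 45.0, 30.0, 15.0)
_EGFR_LABELS = ("G1", "G2", "G3a", "G3b", "G4", "G5")


def egfr_stratum(egfr: float) -> str:
    for cut, label in zip(_EGFR_CUTS, _EGFR_LABELS):
        if egfr >= cut:
            return label
    return _EGFR_LABELS[-1]


def build_cohort(
    eligible: Sequence[OperationRecord],
    exposures: Mapping[object, Mapping[str, float]],
    outcomes: Mapping[object, tuple],
    patients: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
) -> tuple[pd.DataFrame, AttritionReport]:
    """Assemble one analysis-ready row per eligible operation.

    ``outcomes`` maps op_id -> (AkiResult | None, crrt, exclusion_reason).
    The missing-covariate policy (complete-case by default, median/mode
    imputation optionally) is applied here and counted in the returned
    attrition report (n_input = number of eligible operations).
    """
    cfg = config or PipelineConfig()
    report = AttritionReport(n_input=len(eligible))
    if patients.index.duplicated().any():
        raise SchemaError("duplicate patient keys in patients table")

    rows = []
    for op in eligible:
        aki_result, crrt, reason = outcomes[op.op_id][:3]
        if reason is not None:
            report.exclude(reason)
            continue
        if op.patient_id not in patients.index:
            report.exclude("no_patient_record")
            continue
        prow = patients.loc[op.patient_id]
        dose_cols = [c for c in patients.columns if c.startswith("dose_")]
        doses = {c[len("dose_"):]: float(prow[c]) for c in dose_cols if pd.notna(prow[c])}
        row: dict = {
            "patient_id": op.patient_id,
            "op_id": op.op_id,
            "surgery_type": op.surgery_type,
            "emergency": int(op.emergency),
            "aki": int(aki_result.aki),
            "aki_stage": int(aki_result.stage),
            "crrt": int(crrt),
            "baseline_scr": aki_result.baseline_scr,
            "vasopressor_dose": vasopressor_dose_total(doses, cfg.vasopressor_weights),
        }
        row.update({k: v for k, v in exposures[op.op_id].items()})
        for col in patients.columns:
            if col.startswith("dose_") or col in ("patient_id", "crrt_postop"):
                continue
            if col not in row:
                row[col] = prow[col]
        if "egfr_stratum" not in row or pd.isna(row.get("egfr_stratum")):
            egfr = ckd_epi_2009(
                float(aki_result.baseline_scr), float(row["age"]), str(row["sex"]) == "F"
            )
            row["egfr_stratum"] = egfr_stratum(egfr)
        rows.append(row)

    cohort = pd.DataFrame(rows)
    if len(cohort):
        needed = [c for c in cfg.covariates if c in cohort.columns]
        missing_cols = [c for c in cfg.covariates if c not in cohort.columns]
        if missing_cols:
            raise SchemaError(f"cohort missing covariate columns: {missing_cols}")
        incomplete = cohort[needed].isna().any(axis=1)
        if cfg.missing_policy == "complete_case":
            report.exclude("missing_covariates", int(incomplete.sum()))
            cohort = cohort[~incomplete].reset_index(drop=True)
        else:  # impute: median for numerics, mode for categoricals
            for c in needed:
                if cohort[c].isna().any():
                    if pd.api.types.is_numeric_dtype(cohort[c]):
                        cohort[c] = cohort[c].fillna(cohort[c].median())
                    else:
                        cohort[c] = cohort[c].fillna(cohort[c].mode().iloc[0])
    report.n_eligible = len(cohort)
    report.check()
    return cohort, report


def run_pipeline(
    vitals_path,
    operations_path,
    labs_path,
    patients_path,
    config: Optional[PipelineConfig] = None,
    events_path=None,
):
    """End-to-end: read tables, apply eligibility, compute exposures,
    adjudicate outcomes and build the cohort.

    Returns (cohort, report) where report bundles attrition and QC dicts.
    """
    from . import io as tio

    cfg = config or PipelineConfig()
    operations, ops_qc = tio.read_operations(operations_path, cfg.io, events_path)
    op_origins = {op.op_id: op.surgery_start for op in operations}
    # labs are anchored to the patient's first operation (the one kept by the
    # one-operation-per-patient rule)
    pat_origins: dict = {}
    for op in sorted(operations, key=lambda o: o.surgery_start):
        pat_origins.setdefault(op.patient_id, op.surgery_start)
    vitals, vitals_qc = tio.read_vitals(vitals_path, config=cfg.io, origins=op_origins)
    labs, labs_qc = tio.read_labs(labs_path, config=cfg.io, origins=pat_origins)
    patients = tio.read_patients(patients_path)

    eligible, attrition_ops = apply_eligibility(operations, vitals, cfg.max_gap_min)

    exposures: dict = {}
    outcomes: dict = {}
    qc_notes: list[str] = []
    for op in eligible:
        exposures[op.op_id] = compute_exposures(
            op, vitals[op.op_id], cfg.thresholds, cfg.interpolate_crossings
        )
        crrt_flag = None
        if op.patient_id in patients.index and "crrt_postop" in patients.columns:
            val = patients.loc[op.patient_id, "crrt_postop"]
            crrt_flag = None if pd.isna(val) else bool(val)
        aki_result, crrt, reason, notes = adjudicate_outcomes(
            op, labs.get(op.patient_id), crrt_flag, cfg
        )
        outcomes[op.op_id] = (aki_result, crrt, reason)
        qc_notes.extend(f"{op.patient_id}:{n}" for n in notes)

    cohort, attrition_build = build_cohort(eligible, exposures, outcomes, patients, cfg)

    # merged attrition: operations in -> analysis rows out
    merged = AttritionReport(n_input=attrition_ops.n_input)
    merged.exclusions = dict(attrition_ops.exclusions)
    for reason, n in attrition_build.exclusions.items():
        merged.exclude(reason, n)
    merged.n_eligible = attrition_build.n_eligible
    merged.check()

    report = {
        "attrition": merged.to_dict(),
        "attrition_operations": attrition_ops.to_dict(),
        "qc": {
            "vitals": vitals_qc.to_dict(),
            "operations": ops_qc.to_dict(),
            "labs": labs_qc.to_dict(),
        },
        "notes": qc_notes,
    }
    return cohort, report
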