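"""Pipeline configuration (validated with pydantic, loadable from YAML).

Every policy the source data do not pin down — artifact filters, duplicate
handling, baseline-creatinine definition, vasopressor equivalence weights,
reference levels for categorical encoding — is explicit configuration here.
"""
from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

# Covariate set used by the adjusted models (cohort-table column names).
MODEL_COVARIATES: tuple[str, ...] = (
    "age",
    "sex",
    "weight",
    "surgery_type",
    "emergency",
    "asa_status",
    "egfr_stratum",
    "euroscore2",
    "diabetes",
    "heart_failure",
    "hypertension",
    "copd",
    "peripheral_vascular_disease",
    "betablocker",
    "raas_blockade",
    "calcium_antagonist",
    "vasopressor_dose",
    "fluid_balance",
    "twa65_postcpb",
    "cpb_time",
    "prbc_units",
)

DEFAULT_VASOPRESSOR_WEIGHTS: dict[str, float] = {
    "norepinephrine": 1.0,
    "epinephrine": 1.0,
    "dopamine": 0.01,
    "dobutamine": 0.01,
    "vasopressin": 2.5,  # per unit
    "phenylephrine": 0.1,
}

DEFAULT_REFERENCE_LEVELS: dict[str, str] = {
    "sex": "F",
    "surgery_type": "CABG",
    "asa_status": "2",
    "egfr_stratum": "G1",
}


class VitalsColumns(BaseModel):
    op_id: str = "op_id"
    time: str = "time"
    parameter: str = "parameter"
    value: str = "value"


class OperationsColumns(BaseModel):
    op_id: str = "op_id"
    patient_id: str = "patient_id"
    surgery_type: str = "surgery_type"
    emergency: str = "emergency"
    surgery_start: str = "surgery_start"
    surgery_end: str = "surgery_end"
    cpb_start: str = "cpb_start"
    cpb_stop: str = "cpb_stop"


class EventsColumns(BaseModel):
    op_id: str = "op_id"
    time: str = "time"
    event: str = "event"
    cpb_start_label: str = "cpb_start"
    cpb_stop_label: str = "cpb_stop"


class LabsColumns(BaseModel):
    patient_id: str = "patient_id"
    time: str = "time"
    analyte: str = "analyte"
    value: str = "value"


class IOConfig(BaseModel):
    vitals: VitalsColumns = Field(default_factory=VitalsColumns)
    operations: OperationsColumns = Field(default_factory=OperationsColumns)
    events: EventsColumns = Field(default_factory=EventsColumns)
    labs: LabsColumns = Field(default_factory=LabsColumns)
    cpb_dialect: Literal["columns", "events"] = "columns"
    map_parameter: str = "map"
    map_min: float = 10.0
    map_max: float = 200.0
    creatinine_unit: str = "mg/dL"
    creatinine_min: float = 0.1
    creatinine_max: float = 30.0
    dedup_policy: Literal["mean"] = "mean"


class PipelineConfig(BaseModel):
    io: IOConfig = Field(default_factory=IOConfig)
    thresholds: tuple[float, float] = (65.0, 75.0)
    max_gap_min: float = 5.0
    interpolate_crossings: bool = True
    baseline_policy: Literal["most_recent_7d", "min_7d", "most_recent_30d"] = "most_recent_7d"
    horizon_days: float = 7.0
    no_postop_labs_policy: Literal["stage0", "exclude"] = "stage0"
    missing_policy: Literal["complete_case", "impute"] = "complete_case"
    vasopressor_weights: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_VASOPRESSOR_WEIGHTS)
    )
    covariates: tuple[str, ...] = MODEL_COVARIATES
    reference_levels: dict[str, str] = Field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_LEVELS)
    )
    exposure: str = "twa65_cpb"
    min_level_count: int = 10  # sparse categorical levels merged below this

    @field_validator("thresholds")
    @classmethod
    def _ordered(cls, v):
        if not v[0] < v[1]:
            raise ValueError("thresholds must be (primary, sensitivity) with primary < sensitivity")
        return v


def load_config(path: Optional[str] = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML; defaults when path is None."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def dump_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
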