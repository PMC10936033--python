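"""Readers and writers for INSPIRE-style relational CSV tables.

Vitals and labs are long-format (id, time, parameter/analyte, value);
operations and patients are wide-format. Times in the CSVs are seconds on a
per-patient absolute clock; readers subtract a per-id origin (surgery start)
so that all internal times are seconds from surgery start.

Every filtering decision is counted in a :class:`QCReport`, with the
conservation invariant ``rows_in == rows_kept + sum(dropped) + deduped``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import IOConfig, LabsColumns, OperationsColumns, VitalsColumns
from .types import (
    UMOL_PER_L_PER_MG_PER_DL,
    LabSeries,
    MapSeries,
    OperationRecord,
    SchemaError,
    UnknownUnitError,
)

__all__ = [
    "QCReport",
    "read_vitals",
    "read_operations",
    "read_labs",
    "read_patients",
    "write_cohort",
    "read_cohort",
    "write_json",
]


@dataclass
class QCReport:
    """Row-accounting for one reader invocation."""

    table: str
    rows_in: int = 0
    rows_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    deduped: int = 0
    notes: list[str] = field(default_factory=list)

    def drop(self, reason: str, n: int) -> None:
        if n:
            self.dropped[reason] = self.dropped.get(reason, 0) + int(n)

    @property
    def rows_dropped(self) -> int:
        return sum(self.dropped.values())

    def check(self) -> None:
        if self.rows_in != self.rows_kept + self.rows_dropped + self.deduped:
            raise AssertionError(f"QC conservation violated for {self.table}: {self}")

    def to_dict(self) -> dict:
        return {
            "table": self.table,
            "rows_in": self.rows_in,
            "rows_kept": self.rows_kept,
            "rows_dropped": self.rows_dropped,
            "dropped": dict(self.dropped),
            "deduped": self.deduped,
            "notes": list(self.notes),
        }


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required columns {missing}")


def read_vitals(
    path,
    parameter: Optional[str] = None,
    config: Optional[IOConfig] = None,
    origins: Optional[Mapping] = None,
) -> tuple[dict[object, MapSeries], QCReport]:
    """Read a long-format vitals CSV into one :class:`MapSeries` per operation.

    Rows are restricted to ``parameter`` (default from config), converted to
    time-from-surgery-start via ``origins`` (op_id -> absolute surgery start),
    filtered to the MAP plausibility window, and deduplicated at identical
    timestamps by averaging. All drops are counted in the QC report.
    """
    cfg = config or IOConfig()
    cols: VitalsColumns = cfg.vitals
    parameter = parameter if parameter is not None else cfg.map_parameter
    df = pd.read_csv(path)
    _require_columns(df, [cols.op_id, cols.time, cols.parameter, cols.value], "vitals")
    df = df[df[cols.parameter] == parameter]
    qc = QCReport("vitals", rows_in=len(df))

    t = pd.to_numeric(df[cols.time], errors="coerce")
    v = pd.to_numeric(df[cols.value], errors="coerce")
    bad = t.isna() | v.isna()
    qc.drop("nonnumeric", int(bad.sum()))
    df = pd.DataFrame({"op": df[cols.op_id], "t": t, "v": v})[~bad.values]

    if origins is not None:
        df["t"] = df["t"] - df["op"].map(lambda o: origins.get(o, 0.0))
    neg = df["t"] < 0
    qc.drop("negative_time", int(neg.sum()))
    df = df[~neg]

    implausible = (df["v"] < cfg.map_min) | (df["v"] > cfg.map_max)
    qc.drop("implausible_value", int(implausible.sum()))
    df = df[~implausible]

    n_before = len(df)
    grouped = df.groupby(["op", "t"], sort=True, as_index=False)["v"].mean()
    qc.deduped = n_before - len(grouped)
    qc.rows_kept = len(grouped)
    qc.check()

    out: dict[object, MapSeries] = {}
    for op_id, sub in grouped.groupby("op", sort=False):
        out[op_id] = MapSeries(op_id, sub["t"].to_numpy(float), sub["v"].to_numpy(float))
    return out, qc


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, float, np.integer, np.floating)):
        return bool(int(x))
    s = str(x).strip().lower()
    if s in ("true", "t", "1", "yes", "y"):
        return True
    if s in ("false", "f", "0", "no", "n"):
        return False
    raise ValueError(f"unparseable boolean {x!r}")


def _cpb_events_lookup(events_path, cfg: IOConfig) -> dict:
    ev_cols = cfg.events
    ev = pd.read_csv(events_path)
    _require_columns(ev, [ev_cols.op_id, ev_cols.time, ev_cols.event], "events")
    lookup: dict = {}
    for op_id, sub in ev.groupby(ev_cols.op_id):
        starts = sub.loc[sub[ev_cols.event] == ev_cols.cpb_start_label, ev_cols.time]
        stops = sub.loc[sub[ev_cols.event] == ev_cols.cpb_stop_label, ev_cols.time]
        lookup[op_id] = (
            float(starts.iloc[0]) if len(starts) else None,
            float(stops.iloc[0]) if len(stops) else None,
        )
    return lookup


def read_operations(
    path,
    config: Optional[IOConfig] = None,
    events_path=None,
) -> tuple[list[OperationRecord], QCReport]:
    """Read the operations table. Two CPB dialects are supported: CPB event
    times as columns on the operation row (default), or a separate long-format
    event table (``cpb_dialect: events``).

    Records violating the CPB ordering invariant are flagged with
    ``invalid_reason`` rather than silently repaired.
    """
    cfg = config or IOConfig()
    cols: OperationsColumns = cfg.operations
    df = pd.read_csv(path)
    required = [
        cols.op_id, cols.patient_id, cols.surgery_type, cols.emergency,
        cols.surgery_start, cols.surgery_end,
    ]
    _require_columns(df, required, "operations")
    qc = QCReport("operations", rows_in=len(df))

    events = None
    if cfg.cpb_dialect == "events":
        if events_path is None:
            raise SchemaError("cpb_dialect 'events' requires events_path")
        events = _cpb_events_lookup(events_path, cfg)
    else:
        _require_columns(df, [cols.cpb_start, cols.cpb_stop], "operations")

    records: list[OperationRecord] = []
    for _, row in df.iterrows():
        start_abs = float(row[cols.surgery_start])
        end_abs = float(row[cols.surgery_end])
        if events is not None:
            cpb_s, cpb_e = events.get(row[cols.op_id], (None, None))
        else:
            cpb_s = None if pd.isna(row[cols.cpb_start]) else float(row[cols.cpb_start])
            cpb_e = None if pd.isna(row[cols.cpb_stop]) else float(row[cols.cpb_stop])
        reason = None
        if not start_abs < end_abs:
            reason = "invalid_surgery_times"
        have_cpb = cpb_s is not None and cpb_e is not None
        if reason is None and have_cpb:
            if not (start_abs <= cpb_s < cpb_e <= end_abs):
                reason = "invalid_cpb_window"
        records.append(
            OperationRecord(
                op_id=row[cols.op_id],
                patient_id=row[cols.patient_id],
                surgery_type=str(row[cols.surgery_type]),
                emergency=_parse_bool(row[cols.emergency]),
                surgery_start=start_abs,
                surgery_end=end_abs - start_abs,
                cpb_start=(cpb_s - start_abs) if have_cpb else None,
                cpb_stop=(cpb_e - start_abs) if have_cpb else None,
                invalid_reason=reason,
            )
        )
    qc.rows_kept = len(records)
    qc.check()
    return records, qc


def read_labs(
    path,
    analyte: str = "creatinine",
    config: Optional[IOConfig] = None,
    origins: Optional[Mapping] = None,
) -> tuple[dict[object, LabSeries], QCReport]:
    """Read a long-format labs CSV into one sorted :class:`LabSeries` per
    patient, normalising units to mg/dL (``umol/L`` divides by 88.4; any other
    non-mg/dL label is a hard error)."""
    cfg = config or IOConfig()
    cols: LabsColumns = cfg.labs
    unit = cfg.creatinine_unit
    if unit in ("mg/dL", "mg/dl"):
        factor = 1.0
    elif unit in ("umol/L", "umol/l", "µmol/L", "μmol/L"):
        factor = 1.0 / UMOL_PER_L_PER_MG_PER_DL
    else:
        raise UnknownUnitError(f"unknown creatinine unit {unit!r}")
    df = pd.read_csv(path)
    _require_columns(df, [cols.patient_id, cols.time, cols.analyte, cols.value], "labs")
    df = df[df[cols.analyte] == analyte]
    qc = QCReport("labs", rows_in=len(df))

    t = pd.to_numeric(df[cols.time], errors="coerce")
    v = pd.to_numeric(df[cols.value], errors="coerce") * factor
    bad = t.isna() | v.isna()
    qc.drop("nonnumeric", int(bad.sum()))
    df = pd.DataFrame({"pid": df[cols.patient_id], "t": t, "v": v})[~bad.values]

    implausible = (df["v"] < cfg.creatinine_min) | (df["v"] > cfg.creatinine_max)
    qc.drop("implausible_value", int(implausible.sum()))
    df = df[~implausible]

    if origins is not None:
        df["t"] = df["t"] - df["pid"].map(lambda p: origins.get(p, 0.0))
    df = df.sort_values(["pid", "t"], kind="stable")
    qc.rows_kept = len(df)
    qc.check()

    out: dict[object, LabSeries] = {}
    for pid, sub in df.groupby("pid", sort=False):
        out[pid] = LabSeries(pid, sub["t"].to_numpy(float), sub["v"].to_numpy(float), analyte)
    return out, qc


def read_patients(path, id_column: str = "patient_id") -> pd.DataFrame:
    """Read the wide-format patients table, indexed by patient id. Duplicate
    ids are a hard error (key collision)."""
    df = pd.read_csv(path)
    _require_columns(df, [id_column], "patients")
    if df[id_column].duplicated().any():
        dups = df.loc[df[id_column].duplicated(), id_column].tolist()
        raise SchemaError(f"patients: duplicate patient ids {dups}")
    return df.set_index(id_column, drop=False)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the analysis-ready cohort table as CSV. Floats are written with
    full repr precision so a read-back round-trips to < 1e-12."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
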