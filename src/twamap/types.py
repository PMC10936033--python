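"""Core data containers and exceptions shared across the pipeline.

All internal times are seconds from surgery start (real valued). Readers are
responsible for converting absolute clocks; see :mod:`twamap.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SECONDS_PER_MINUTE = 60.0
SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0

UMOL_PER_L_PER_MG_PER_DL = 88.4  # creatinine molar conversion


class SchemaError(ValueError):
    """Input table is missing required columns."""


class InsufficientSamplesError(ValueError):
    """Fewer than two usable samples inside or bounding the analysis window."""


class WindowOutsideRangeError(ValueError):
    """Analysis window not covered by the sampled time range."""


class NoBaselineError(ValueError):
    """No qualifying preoperative creatinine under the chosen policy."""


class UnknownUnitError(ValueError):
    """Unit label not recognised; refusing to guess."""


class UnknownDrugError(KeyError):
    """Drug absent from the vasopressor equivalence weight table."""


class DegenerateOutcomeError(ValueError):
    """Outcome has a single class; logistic model cannot be fitted."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient after categorical encoding."""

    def __init__(self, columns: list[str]):
        self.columns = list(columns)
        super().__init__(f"design matrix rank deficient; collinear columns: {self.columns}")


@dataclass(frozen=True)
class MapSeries:
    """Irregularly sampled MAP trajectory for one operation.

    ``t`` is strictly increasing, in seconds from surgery start; ``v`` is MAP
    in mmHg. Both are 1-d float arrays of equal length.
    """

    op_id: object
    t: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError("t and v must be 1-d arrays of equal length")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("MAP values must be finite")

    @property
    def n(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class OperationRecord:
    """One surgical operation with optional CPB window (times in seconds from
    surgery start; ``surgery_start`` is therefore 0 and kept for provenance as
    the absolute origin used by the readers)."""

    op_id: object
    patient_id: object
    surgery_type: str
    emergency: bool
    surgery_start: float  # absolute origin (seconds on the source clock)
    surgery_end: float    # relative, seconds from surgery start
    cpb_start: Optional[float] = None  # relative
    cpb_stop: Optional[float] = None   # relative
    invalid_reason: Optional[str] = None

    @property
    def has_cpb(self) -> bool:
        return self.cpb_start is not None and self.cpb_stop is not None

    @property
    def cpb_minutes(self) -> Optional[float]:
        if not self.has_cpb:
            return None
        return (self.cpb_stop - self.cpb_start) / SECONDS_PER_MINUTE


@dataclass(frozen=True)
class LabSeries:
    """Ordered creatinine measurements for one patient (mg/dL), times in
    seconds from surgery start (negative = preoperative)."""

    patient_id: object
    t: np.ndarray
    value: np.ndarray
    analyte: str = "creatinine"

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "value", v)
        if t.size and not np.all(np.diff(t) >= 0):
            raise ValueError("lab timestamps must be sorted")

    @property
    def n(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class AnalysisWindow:
    """Time window for exposure computation, seconds from surgery start."""

    label: str  # "cpb" | "post_cpb"
    t_start: float
    t_stop: float

    def __post_init__(self):
        if not self.t_start < self.t_stop:
            raise ValueError("t_start must be < t_stop")

    @property
    def duration_min(self) -> float:
        return (self.t_stop - self.t_start) / SECONDS_PER_MINUTE


@dataclass(frozen=True)
class ExposureSummary:
    """Threshold-based hypotension exposure over one analysis window."""

    threshold: float          # mmHg
    auc_below: float          # mmHg * min
    twa_below: float          # mmHg
    minutes_below: float      # min
    window_duration: float    # min
    n_samples: int
    max_gap: float            # min


@dataclass(frozen=True)
class AkiResult:
    """KDIGO creatinine-criteria adjudication for one patient."""

    aki: bool
    stage: int
    onset_t: Optional[float]        # seconds from surgery start
    criterion: Optional[str]        # abs_increase_48h | relative_increase_7d | scr_ge_4 | rrt
    baseline_scr: float
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.stage not in (0, 1, 2, 3):
            raise ValueError("stage must be in 0..3")
        if self.aki != (self.stage >= 1):
            raise ValueError("aki flag must match stage >= 1")
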