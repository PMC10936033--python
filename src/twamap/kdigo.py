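"""KDIGO creatinine-criteria AKI adjudication (all stages) over a 7-day
postoperative horizon, plus the postoperative CRRT secondary outcome.

Urine-output criteria are excluded by construction. The 48-hour absolute-rise
criterion is evaluated against every anchor measurement (the baseline value,
anchored at t = 0, and every postoperative value), not only the baseline.
Stage-3 via SCr >= 4.0 mg/dL additionally requires a qualifying AKI entry
criterion, guarding against chronically elevated creatinine.
"""
from __future__ import annotations

import numpy as np

from .types import (
    SECONDS_PER_DAY,
    SECONDS_PER_HOUR,
    AkiResult,
    LabSeries,
    NoBaselineError,
)

__all__ = ["baseline_creatinine", "kdigo_stage", "crrt_outcome", "BASELINE_POLICIES"]

BASELINE_POLICIES = ("most_recent_7d", "min_7d", "most_recent_30d")

ABS_RISE_MG_DL = 0.3
ABS_RISE_WINDOW_S = 48.0 * SECONDS_PER_HOUR
RATIO_STAGE1 = 1.5
RATIO_STAGE2 = 2.0
RATIO_STAGE3 = 3.0
SCR_STAGE3_ABS = 4.0


def baseline_creatinine(
    labs: LabSeries,
    surgery_start: float = 0.0,
    policy: str = "most_recent_7d",
) -> float:
    """Baseline serum creatinine (mg/dL) under a stated preoperative policy.

    Policies: ``most_recent_7d`` (default), ``min_7d``, ``most_recent_30d``.
    Raises :class:`NoBaselineError` when no qualifying preoperative value exists.
    """
    if policy not in BASELINE_POLICIES:
        raise ValueError(f"unknown baseline policy {policy!r}")
    lookback_days = 30.0 if policy == "most_recent_30d" else 7.0
    rel = labs.t - surgery_start
    mask = (rel < 0) & (rel >= -lookback_days * SECONDS_PER_DAY)
    if not np.any(mask):
        raise NoBaselineError("no_baseline")
    vals = labs.value[mask]
    if policy == "min_7d":
        return float(np.min(vals))
    return float(vals[-1])  # labs sorted by time -> last is most recent


def kdigo_stage(
    labs: LabSeries,
    baseline_scr: float,
    surgery_start: float = 0.0,
    rrt: bool = False,
    rrt_time: float | None = None,
    horizon_days: float = 7.0,
) -> AkiResult:
    """Adjudicate KDIGO creatinine-criteria AKI within ``horizon_days`` of
    surgery.

    Entry criteria: (a) absolute rise >= 0.3 mg/dL within a rolling 48-h window
    anchored at any prior measurement (baseline at t = 0 or any postoperative
    value); (b) any value >= 1.5x baseline within the horizon. Staging: 1 for
    1.5–1.9x or the +0.3 rise; 2 for 2.0–2.9x; 3 for >= 3.0x, or SCr >= 4.0
    mg/dL with a qualifying entry criterion, or RRT initiated within the
    horizon. The stage is the maximum attained; ``onset_t`` is the first time
    any criterion holds.
    """
    if baseline_scr <= 0:
        raise ValueError("baseline_scr must be > 0")
    horizon_s = horizon_days * SECONDS_PER_DAY
    rel = labs.t - surgery_start
    post_mask = (rel >= 0) & (rel <= horizon_s)
    tp = rel[post_mask]
    vp = labs.value[post_mask]
    flags: list[str] = []

    if tp.size == 0 and not rrt:
        flags.append("no_postop_labs")
        return AkiResult(False, 0, None, None, baseline_scr, tuple(flags))

    # anchors: baseline at t=0 plus every postoperative measurement
    anchor_t = np.concatenate(([0.0], tp))
    anchor_v = np.concatenate(([baseline_scr], vp))

    onset_abs: float | None = None
    for j in range(tp.size):
        dt = tp[j] - anchor_t
        window = (dt >= 0) & (dt <= ABS_RISE_WINDOW_S)
        window[j + 1] = False  # a measurement is not its own anchor
        if np.any(vp[j] - anchor_v[window] >= ABS_RISE_MG_DL):
            onset_abs = float(tp[j])
            break

    ratios = vp / baseline_scr
    onset_ratio: float | None = None
    hit = np.nonzero(ratios >= RATIO_STAGE1)[0]
    if hit.size:
        onset_ratio = float(tp[hit[0]])

    entry = onset_abs is not None or onset_ratio is not None

    max_ratio = float(np.max(ratios)) if tp.size else 0.0
    onset_scr4: float | None = None
    if entry:
        hit4 = np.nonzero(vp >= SCR_STAGE3_ABS)[0]
        if hit4.size:
            onset_scr4 = float(tp[hit4[0]])

    stage = 0
    criterion = None
    onset: float | None = None
    if entry:
        stage = 1
        candidates = [
            (onset_abs, "abs_increase_48h"),
            (onset_ratio, "relative_increase_7d"),
        ]
        if max_ratio >= RATIO_STAGE3:
            stage = 3
        elif onset_scr4 is not None:
            stage = 3
            candidates.append((onset_scr4, "scr_ge_4"))
        elif max_ratio >= RATIO_STAGE2:
            stage = 2
        valid = [(t, c) for t, c in candidates if t is not None]
        onset, criterion = min(valid, key=lambda x: x[0])
    if rrt:
        stage = 3
        if not entry:
            criterion = "rrt"
            onset = rrt_time
        elif rrt_time is not None and (onset is None or rrt_time < onset):
            criterion = "rrt"
            onset = rrt_time
    return AkiResult(stage >= 1, stage, onset, criterion, baseline_scr, tuple(flags))


def crrt_outcome(crrt_postop: bool | None) -> tuple[bool, list[str]]:
    """Postoperative-hospital-stay CRRT indicator passthrough (no 7-day
    horizon). A missing indicator is treated as False with a QC note."""
    if crrt_postop is None:
        return False, ["crrt_indicator_missing"]
    return bool(crrt_postop), []
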