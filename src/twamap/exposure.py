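"""Threshold-based hypotension exposure metrics.

The exposure of interest is the area between a threshold line T and the
piecewise-linear MAP curve where MAP < T, integrated by the composite
trapezoidal rule over a stated analysis window, and its time-weighted average
(area divided by window duration).

Two integration variants are provided:

* ``interpolate_crossings=True`` (default) — threshold-crossing points are
  inserted before integrating the clipped deficit ``d(t) = max(0, T - MAP(t))``,
  which is exact for the piecewise-linear curve.
* ``interpolate_crossings=False`` — the trapezoid rule is applied to clipped
  deficits at the sample points only (documented alternative reading).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import (
    SECONDS_PER_MINUTE,
    AnalysisWindow,
    ExposureSummary,
    InsufficientSamplesError,
    MapSeries,
    WindowOutsideRangeError,
)

__all__ = ["deficit_auc", "twa_below", "resolution_check", "ResolutionResult"]


def _window_nodes(series: MapSeries, window: AnalysisWindow) -> tuple[np.ndarray, np.ndarray]:
    """Return (t, v) nodes clipped to the window, with MAP linearly
    interpolated onto t_start / t_stop when samples straddle them.

    Samples outside the window contribute only through boundary interpolation.
    """
    t, v = series.t, series.v
    if t.size < 2:
        raise InsufficientSamplesError(f"insufficient_samples: n={t.size}")
    if window.t_start < t[0] or window.t_stop > t[-1]:
        raise WindowOutsideRangeError(
            f"window [{window.t_start}, {window.t_stop}] outside sampled range "
            f"[{t[0]}, {t[-1]}]"
        )
    inside = (t > window.t_start) & (t < window.t_stop)
    ti = t[inside]
    vi = v[inside]
    v_start = float(np.interp(window.t_start, t, v))
    v_stop = float(np.interp(window.t_stop, t, v))
    tw = np.concatenate(([window.t_start], ti, [window.t_stop]))
    vw = np.concatenate(([v_start], vi, [v_stop]))
    return tw, vw


def _insert_crossings(t: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Insert zero-crossing nodes of the piecewise-linear deficit d(t)."""
    sign_change = d[:-1] * d[1:] < 0
    if not np.any(sign_change):
        return t, d
    idx = np.nonzero(sign_change)[0]
    tc = t[idx] + (t[idx + 1] - t[idx]) * d[idx] / (d[idx] - d[idx + 1])
    t_all = np.concatenate([t, tc])
    d_all = np.concatenate([d, np.zeros_like(tc)])
    order = np.argsort(t_all, kind="stable")
    return t_all[order], d_all[order]


def deficit_auc(
    series: MapSeries,
    window: AnalysisWindow,
    threshold: float = 65.0,
    interpolate_crossings: bool = True,
) -> float:
    """Area (mmHg·min) between ``threshold`` and the MAP curve where
    MAP < threshold, within ``window``."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    tw, vw = _window_nodes(series, window)
    if tw.size < 2:
        raise InsufficientSamplesError("insufficient_samples")
    d = threshold - vw
    if interpolate_crossings:
        tr, dr = _insert_crossings(tw, d)
        dr = np.clip(dr, 0.0, None)
    else:
        tr, dr = tw, np.clip(d, 0.0, None)
    area_mmhg_s = float(np.trapezoid(dr, tr))
    return area_mmhg_s / SECONDS_PER_MINUTE


def twa_below(
    series: MapSeries,
    window: AnalysisWindow,
    threshold: float = 65.0,
    interpolate_crossings: bool = True,
) -> ExposureSummary:
    """Time-weighted average depth of MAP below ``threshold`` over ``window``:
    deficit AUC divided by the window duration. Also reports total minutes with
    interpolated MAP below threshold, sample count and the largest time gap."""
    auc = deficit_auc(series, window, threshold, interpolate_crossings)
    tw, vw = _window_nodes(series, window)
    d = threshold - vw
    tr, dr = _insert_crossings(tw, d)
    # with crossings inserted each interval is one-signed; count positive ones
    pos = (dr[:-1] > 0) | (dr[1:] > 0)
    minutes_below = float(np.sum(np.diff(tr)[pos])) / SECONDS_PER_MINUTE
    duration = window.duration_min
    inside = (series.t >= window.t_start) & (series.t <= window.t_stop)
    gaps = np.diff(tw) / SECONDS_PER_MINUTE
    return ExposureSummary(
        threshold=float(threshold),
        auc_below=auc,
        twa_below=auc / duration,
        minutes_below=minutes_below,
        window_duration=duration,
        n_samples=int(np.count_nonzero(inside)),
        max_gap=float(np.max(gaps)) if gaps.size else float("inf"),
    )


@dataclass(frozen=True)
class ResolutionResult:
    ok: bool
    max_gap: float  # minutes; inf when the window holds no samples
    reason: Optional[str] = None


def resolution_check(
    series: MapSeries,
    window: AnalysisWindow,
    max_allowed_gap: float = 5.0,
) -> ResolutionResult:
    """True iff every inter-sample gap within the window — including the edge
    gaps from t_start to the first sample and from the last sample to t_stop —
    is at most ``max_allowed_gap`` minutes (boundary inclusive)."""
    t = series.t
    inside = t[(t >= window.t_start) & (t <= window.t_stop)]
    if inside.size == 0:
        return ResolutionResult(False, float("inf"), reason="empty_window")
    edges = np.concatenate(([window.t_start], inside, [window.t_stop]))
    max_gap = float(np.max(np.diff(edges))) / SECONDS_PER_MINUTE
    return ResolutionResult(max_gap <= max_allowed_gap, max_gap)
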