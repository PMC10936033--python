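"""Synthetic INSPIRE-dialect cohorts with known ground truth.

Two levels of fidelity:

* :func:`simulate_analysis_table` draws the analysis-ready table directly
  (exposure, covariates, outcomes from exact logistic models) — cheap enough
  for hundreds of replicates in recovery/coverage studies.
* :func:`simulate_cohort` additionally constructs the raw relational tables:
  MAP trajectories whose realized TWA matches the drawn exposure (bisection on
  the CPB-regime mean, tolerance 0.1 mmHg), creatinine trajectories that
  adjudicate to the assigned KDIGO stage by construction, and operation /
  patient tables readable by :mod:`twamap.io` unchanged.

Outcome generation keeps both marginal models exactly logistic while making
CRRT a subset of AKI (the adjudicator forces stage 3 whenever RRT is given):
CRRT ~ Bernoulli(p_c(x)); AKI = CRRT or Bernoulli((p_a - p_c) / (1 - p_c)).
Intercepts are calibrated by root-finding so the mean simulated probability
hits the configured marginal incidence for the realized covariate draw.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import ckd_epi_2009, egfr_stratum
from .config import DEFAULT_VASOPRESSOR_WEIGHTS
from .exposure import twa_below
from .types import SECONDS_PER_DAY, SECONDS_PER_HOUR, SECONDS_PER_MINUTE, AnalysisWindow, MapSeries

__all__ = ["SimConfig", "simulate_analysis_table", "simulate_map_series", "simulate_cohort", "SimulatedCohort"]


class MapModel(BaseModel):
    """Mean-reverting Gaussian MAP process sampled at irregular intervals."""

    pre_mean: float = 75.0
    post_mean: float = 75.0
    sd: float = 8.0
    reversion_tau_s: float = 300.0  # AR(1) correlation time
    interval_mean_s: float = 60.0
    interval_sd_s: float = 30.0
    interval_min_s: float = 10.0
    interval_max_s: float = 240.0  # < 5-min resolution limit
    clip_low: float = 15.0
    clip_high: float = 190.0


class OutcomeModel(BaseModel):
    aki_or_per_mmhg: float = 1.07
    crrt_or_per_mmhg: float = 1.05
    aki_marginal: float = 0.34
    crrt_marginal: float = 0.10
    confounding: float = 1.0      # scales all non-exposure effects
    crrt_effect_scale: float = 0.5


class ExposureModel(BaseModel):
    twa_median: float = 2.5       # lognormal median, mmHg
    twa_sigma: float = 0.8


class CreatinineModel(BaseModel):
    baseline_median: float = 0.9
    baseline_sigma: float = 0.25
    stage_mix: tuple[float, float, float] = (0.75, 0.20, 0.05)  # stages 1/2/3 among non-CRRT AKI


class SimConfig(BaseModel):
    n_patients: int = 200
    seed: int = 0
    map_model: MapModel = Field(default_factory=MapModel)
    outcome: OutcomeModel = Field(default_factory=OutcomeModel)
    exposure: ExposureModel = Field(default_factory=ExposureModel)
    creatinine: CreatinineModel = Field(default_factory=CreatinineModel)
    cpb_median_min: float = 120.0
    cpb_sigma: float = 0.30
    # engineered ineligible/unadjudicable extras appended after the clean cohort
    n_no_cpb: int = 0
    n_invalid_cpb: int = 0
    n_low_resolution: int = 0
    n_no_baseline: int = 0
    n_reoperation: int = 0
    missing_weight_rate: float = 0.0  # fraction of clean patients with weight nulled


def _draw_covariates(cfg: SimConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    cm = cfg.creatinine
    df = pd.DataFrame(
        {
            "age": np.clip(rng.normal(62, 12, n), 20, 90),
            "sex": np.where(rng.random(n) < 0.65, "M", "F"),
            "weight": np.clip(rng.normal(70, 14, n), 40, 130),
            "surgery_type": rng.choice(
                ["CABG", "valve", "aortic", "other"], size=n, p=[0.45, 0.40, 0.10, 0.05]
            ),
            "emergency": (rng.random(n) < 0.08).astype(int),
            "asa_status": rng.choice(["2", "3", "4"], size=n, p=[0.20, 0.60, 0.20]),
            "euroscore2": np.clip(rng.lognormal(math.log(2.0), 0.6, n), 0.3, 30.0),
            "diabetes": (rng.random(n) < 0.30).astype(int),
            "heart_failure": (rng.random(n) < 0.25).astype(int),
            "hypertension": (rng.random(n) < 0.60).astype(int),
            "copd": (rng.random(n) < 0.10).astype(int),
            "peripheral_vascular_disease": (rng.random(n) < 0.08).astype(int),
            "betablocker": (rng.random(n) < 0.50).astype(int),
            "raas_blockade": (rng.random(n) < 0.45).astype(int),
            "calcium_antagonist": (rng.random(n) < 0.25).astype(int),
            "fluid_balance": rng.normal(1500, 800, n),
            "prbc_units": rng.poisson(0.8, n),
            "baseline_scr": np.clip(
                rng.lognormal(math.log(cm.baseline_median), cm.baseline_sigma, n), 0.5, 2.5
            ),
        }
    )
    df["dose_norepinephrine"] = rng.lognormal(math.log(4.0), 0.7, n)
    df["dose_epinephrine"] = np.where(rng.random(n) < 0.30, rng.lognormal(0.0, 0.6, n), 0.0)
    df["dose_dobutamine"] = np.where(rng.random(n) < 0.20, rng.lognormal(math.log(200), 0.5, n), 0.0)
    df["dose_vasopressin"] = np.where(rng.random(n) < 0.10, rng.lognormal(math.log(2.0), 0.5, n), 0.0)
    dose_cols = [c for c in df.columns if c.startswith("dose_")]
    # vectorised norepinephrine-equivalent total (same arithmetic as
    # cohort.vasopressor_dose_total, which the pipeline applies to these columns)
    df["vasopressor_dose"] = sum(
        DEFAULT_VASOPRESSOR_WEIGHTS[c[5:]] * df[c].to_numpy() for c in dose_cols
    )
    df["cpb_time"] = np.clip(
        rng.lognormal(math.log(cfg.cpb_median_min), cfg.cpb_sigma, n), 40.0, 360.0
    )
    egfr = np.array(
        [
            ckd_epi_2009(s, a, sx == "F")
            for s, a, sx in zip(df["baseline_scr"], df["age"], df["sex"])
        ]
    )
    df["egfr_stratum"] = [egfr_stratum(e) for e in egfr]
    return df


def _confounder_lp(df: pd.DataFrame, scale: float) -> np.ndarray:
    """Non-exposure linear predictor shared (up to scale) by both outcomes."""
    return scale * (
        0.02 * (df["age"].to_numpy() - 62)
        + 0.10 * (df["sex"].to_numpy() == "M")
        - 0.005 * (df["weight"].to_numpy() - 70)
        + 0.40 * df["diabetes"].to_numpy()
        + 0.50 * df["heart_failure"].to_numpy()
        + 0.20 * df["hypertension"].to_numpy()
        + 0.15 * df["copd"].to_numpy()
        + 0.20 * df["peripheral_vascular_disease"].to_numpy()
        + 0.08 * (df["euroscore2"].to_numpy() - 2.0)
        + 0.30 * df["emergency"].to_numpy()
        + 0.004 * (df["cpb_time"].to_numpy() - 120.0)
        + 0.05 * (df["vasopressor_dose"].to_numpy() - 5.0)
        + 0.0002 * (df["fluid_balance"].to_numpy() - 1500.0)
        + 0.10 * df["prbc_units"].to_numpy()
        + 0.03 * df["twa65_postcpb"].to_numpy()
    )


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    def gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + eta))) - target

    return float(brentq(gap, -30.0, 30.0, xtol=1e-10))


def simulate_analysis_table(
    config: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw one analysis-ready cohort table plus its ground truth.

    Exposure is lognormal (configured median/sigma) with mild confounding by
    heart failure, EuroSCORE II and CPB time when ``outcome.confounding`` > 0.
    """
    cfg = config or SimConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    df = _draw_covariates(cfg, rng, n)

    conf = cfg.outcome.confounding
    shift = conf * (
        0.15 * df["heart_failure"].to_numpy()
        + 0.04 * (df["euroscore2"].to_numpy() - 2.0)
        + 0.002 * (df["cpb_time"].to_numpy() - 120.0)
    )
    twa = np.exp(
        math.log(cfg.exposure.twa_median) + shift + rng.normal(0, cfg.exposure.twa_sigma, n)
    )
    df["twa65_cpb"] = np.clip(twa, 0.0, 30.0)
    post = np.exp(
        -0.4 + 0.4 * np.log(df["twa65_cpb"].to_numpy() + 0.5) + rng.normal(0, 0.6, n)
    )
    df["twa65_postcpb"] = np.clip(post, 0.0, 30.0)

    eta = _confounder_lp(df, conf)
    beta_a = math.log(cfg.outcome.aki_or_per_mmhg)
    beta_c = math.log(cfg.outcome.crrt_or_per_mmhg)
    eta_a = beta_a * df["twa65_cpb"].to_numpy() + eta
    eta_c = beta_c * df["twa65_cpb"].to_numpy() + cfg.outcome.crrt_effect_scale * eta
    alpha_a = _calibrate_intercept(eta_a, cfg.outcome.aki_marginal)
    alpha_c = _calibrate_intercept(eta_c, cfg.outcome.crrt_marginal)
    p_a = expit(alpha_a + eta_a)
    p_c = expit(alpha_c + eta_c)
    n_clip = int(np.sum(p_c > p_a))
    p_c_eff = np.minimum(p_c, p_a)
    crrt = rng.random(n) < p_c_eff
    q = np.clip((p_a - p_c_eff) / (1.0 - p_c_eff), 0.0, 1.0)
    aki = crrt | (rng.random(n) < q)

    stage = np.zeros(n, dtype=int)
    stage[crrt] = 3
    plain = aki & ~crrt
    stage[plain] = rng.choice([1, 2, 3], size=int(plain.sum()), p=list(cfg.creatinine.stage_mix))
    df["aki"] = aki.astype(int)
    df["crrt"] = crrt.astype(int)
    df["aki_stage"] = stage
    df["patient_id"] = [f"p{i:05d}" for i in range(n)]

    truth = {
        "alpha_aki": alpha_a,
        "beta_twa_aki": beta_a,
        "alpha_crrt": alpha_c,
        "beta_twa_crrt": beta_c,
        "p_aki": p_a,
        "p_crrt": p_c_eff,
        "n_prob_clips": n_clip,
    }
    return df, truth


# ---------------------------------------------------------------------------
# MAP trajectory construction
# ---------------------------------------------------------------------------


def _ar1_path(rng: np.random.Generator, dts: np.ndarray, tau: float) -> np.ndarray:
    """Standardised stationary AR(1) (OU at irregular steps)."""
    z = np.empty(dts.size + 1)
    z[0] = rng.standard_normal()
    phi = np.exp(-dts / tau)
    innov = rng.standard_normal(dts.size) * np.sqrt(1.0 - phi**2)
    for i in range(dts.size):
        z[i + 1] = phi[i] * z[i] + innov[i]
    return z


def _sample_times(rng, t0: float, t1: float, mm: MapModel, interval_scale: float = 1.0) -> np.ndarray:
    times = [t0]
    t = t0
    while True:
        dt = float(
            np.clip(
                rng.normal(mm.interval_mean_s * interval_scale, mm.interval_sd_s * interval_scale),
                mm.interval_min_s,
                mm.interval_max_s * interval_scale,
            )
        )
        t += dt
        if t >= t1:
            break
        times.append(t)
    times.append(t1)
    return np.asarray(times)


def _solve_regime_mean(build, window, target, threshold, tol, lo=15.0, hi=140.0):
    """Bisection on a regime mean so the realized TWA below threshold over
    ``window`` matches ``target`` within ``tol`` (realized TWA is monotone
    decreasing in the mean)."""

    def realized(mu: float) -> float:
        return twa_below(build(mu), window, threshold).twa_below

    if target > realized(lo):
        raise ValueError(f"unattainable target_twa {target} (max {realized(lo):.2f})")
    mid = 0.5 * (lo + hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f_mid = realized(mid)
        if abs(f_mid - target) <= 0.5 * tol:
            break
        if f_mid > target:
            lo = mid
        else:
            hi = mid
    return mid


def simulate_map_series(
    rng: np.random.Generator,
    map_model: MapModel,
    cpb_window: AnalysisWindow,
    surgery_end_s: float,
    target_twa: Optional[float] = None,
    target_twa_post: Optional[float] = None,
    threshold: float = 65.0,
    tol: float = 0.1,
    op_id: object = "sim",
    interval_scale: float = 1.0,
) -> MapSeries:
    """MAP trajectory over [0, surgery_end] with pre/CPB/post regimes and
    samples pinned at the CPB boundaries.

    When ``target_twa`` (``target_twa_post``) is given, the CPB (post-CPB)
    regime mean is solved by bisection so the realized TWA below ``threshold``
    over that window is within ``tol`` mmHg of the target. Targets outside
    [0, threshold) are rejected as unattainable.
    """
    for tgt in (target_twa, target_twa_post):
        if tgt is not None and not (0.0 <= tgt < threshold):
            raise ValueError(f"unattainable target_twa {tgt}")
    mm = map_model
    t = _sample_times(rng, 0.0, surgery_end_s, mm, interval_scale)
    t = np.unique(np.concatenate([t, [cpb_window.t_start, cpb_window.t_stop]]))
    z = _ar1_path(rng, np.diff(t), mm.reversion_tau_s)
    in_cpb = (t >= cpb_window.t_start) & (t <= cpb_window.t_stop)
    in_post = t > cpb_window.t_stop
    base_mean = np.full(t.size, mm.pre_mean)
    base_mean[in_post] = mm.post_mean

    def series_for(mu_cpb: float, mu_post: float) -> MapSeries:
        mean = base_mean.copy()
        mean[in_post] = mu_post
        mean[in_cpb] = mu_cpb
        v = np.clip(mean + mm.sd * z, mm.clip_low, mm.clip_high)
        return MapSeries(op_id, t, v)

    mu_cpb = mm.pre_mean
    mu_post = mm.post_mean
    if target_twa is not None:
        # boundary samples are pinned, so the CPB-window TWA is independent
        # of the post-regime mean
        mu_cpb = _solve_regime_mean(
            lambda mu: series_for(mu, mu_post), cpb_window, target_twa, threshold, tol,
            lo=mm.clip_low,
        )
    if target_twa_post is not None and cpb_window.t_stop < surgery_end_s:
        post_window = AnalysisWindow("post_cpb", cpb_window.t_stop, surgery_end_s)
        mu_post = _solve_regime_mean(
            lambda mu: series_for(mu_cpb, mu), post_window, target_twa_post, threshold, tol,
            lo=mm.clip_low,
        )
    return series_for(mu_cpb, mu_post)


# ---------------------------------------------------------------------------
# creatinine trajectory construction
# ---------------------------------------------------------------------------

_POST_TIMES_H = np.array([12.0, 24.0, 48.0, 72.0, 120.0, 168.0])
_RISE_FRACTIONS = np.array([0.25, 0.55, 1.00, 0.70, 0.40, 0.20])  # peak at 48 h


def _creatinine_trajectory(
    rng: np.random.Generator, baseline: float, stage: int
) -> tuple[np.ndarray, np.ndarray]:
    """(times_s, values) with preop anchors at day -3/-1; the most recent
    preop value equals ``baseline`` so adjudication sees the assigned
    baseline. Postop values are engineered to reach exactly the assigned
    stage (0–3) under the creatinine criteria."""
    t_pre = np.array([-3.0, -1.0]) * SECONDS_PER_DAY
    v_pre = np.array([baseline * rng.uniform(0.95, 1.05), baseline])
    t_post = _POST_TIMES_H * SECONDS_PER_HOUR
    if stage == 0:
        v_post = baseline * rng.uniform(0.97, 1.06, t_post.size)
    else:
        if stage == 1:
            if rng.random() < 0.3:  # absolute-rise-only stage 1
                peak = baseline + rng.uniform(0.32, 0.45)
            else:
                peak = baseline * rng.uniform(1.55, 1.85)
        elif stage == 2:
            peak = baseline * rng.uniform(2.1, 2.8)
        else:
            peak = baseline * rng.uniform(3.2, 4.5)
        v_post = baseline + (peak - baseline) * _RISE_FRACTIONS
    return np.concatenate([t_pre, t_post]), np.concatenate([v_pre, v_post])


# ---------------------------------------------------------------------------
# full relational simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    vitals: pd.DataFrame
    operations: pd.DataFrame
    labs: pd.DataFrame
    patients: pd.DataFrame
    analysis_table: pd.DataFrame
    truth: dict

    def write_csv(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.vitals.to_csv(out / "vitals.csv", index=False)
        self.operations.to_csv(out / "operations.csv", index=False)
        self.labs.to_csv(out / "labs.csv", index=False)
        self.patients.to_csv(out / "patients.csv", index=False)
        from .io import write_json

        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in self.truth.items()
        }
        write_json(truth, out / "truth.json")


_PATIENT_COLUMNS = [
    "patient_id", "age", "sex", "weight", "asa_status", "euroscore2",
    "diabetes", "heart_failure", "hypertension", "copd", "peripheral_vascular_disease",
    "betablocker", "raas_blockade", "calcium_antagonist",
    "dose_norepinephrine", "dose_epinephrine", "dose_dobutamine", "dose_vasopressin",
    "fluid_balance", "prbc_units", "crrt_postop",
]


def simulate_cohort(config: Optional[SimConfig] = None) -> SimulatedCohort:
    """Generate the four relational CSV tables (vitals, operations, labs,
    patients) plus the analysis-level ground truth. Engineered ineligible
    operations (no CPB, invalid CPB window, low-resolution MAP, missing
    baseline creatinine, reoperations) are appended per configuration so
    attrition accounting is testable by construction."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    table, truth = simulate_analysis_table(cfg, rng)
    n = cfg.n_patients
    mm = cfg.map_model

    vit_op, vit_t, vit_v = [], [], []
    ops_rows, labs_rows = [], []

    def emit_vitals(op_id, start_abs, series: MapSeries):
        vit_op.append(np.full(series.n, op_id, dtype=object))
        vit_t.append(series.t + start_abs)
        vit_v.append(series.v)

    def emit_labs(pid, start_abs, t_rel, values):
        for tt, vv in zip(t_rel, values):
            labs_rows.append((pid, start_abs + tt, "creatinine", vv))

    realized_twa = np.empty(n)
    for i in range(n):
        row = table.iloc[i]
        pid = row["patient_id"]
        op_id = f"op{i:05d}"
        start_abs = float(rng.integers(0, 10_000_000))
        pre_s = float(np.clip(rng.normal(45, 10), 25, 90)) * SECONDS_PER_MINUTE
        cpb_s = float(row["cpb_time"]) * SECONDS_PER_MINUTE
        post_s = float(np.clip(rng.normal(75, 15), 40, 150)) * SECONDS_PER_MINUTE
        end_rel = pre_s + cpb_s + post_s
        window = AnalysisWindow("cpb", pre_s, pre_s + cpb_s)
        series = simulate_map_series(
            rng, mm, window, end_rel,
            target_twa=float(row["twa65_cpb"]),
            target_twa_post=float(row["twa65_postcpb"]),
            op_id=op_id,
        )
        realized_twa[i] = twa_below(series, window).twa_below
        emit_vitals(op_id, start_abs, series)
        ops_rows.append(
            (op_id, pid, row["surgery_type"], int(row["emergency"]),
             start_abs, start_abs + end_rel, start_abs + pre_s, start_abs + pre_s + cpb_s)
        )
        t_lab, v_lab = _creatinine_trajectory(rng, float(row["baseline_scr"]), int(row["aki_stage"]))
        emit_labs(pid, start_abs, t_lab, v_lab)

    patients = table.copy()
    patients["crrt_postop"] = patients["crrt"]
    patients = patients[_PATIENT_COLUMNS]

    # --- engineered extras ------------------------------------------------
    extra_pat_rows = []
    k = 0

    def extra_patient(pid):
        extra = _draw_covariates(cfg, np.random.default_rng(cfg.seed + 7919 + len(extra_pat_rows)), 1)
        erow = extra.iloc[0].to_dict()
        erow["patient_id"] = pid
        erow["crrt_postop"] = 0
        extra_pat_rows.append({c: erow.get(c) for c in _PATIENT_COLUMNS})
        return erow

    def standard_op(pid, op_id, with_cpb=True, invalid=False, interval_scale=1.0):
        start_abs = float(rng.integers(0, 10_000_000))
        pre_s = 40 * SECONDS_PER_MINUTE
        cpb_s = 100 * SECONDS_PER_MINUTE
        post_s = 60 * SECONDS_PER_MINUTE
        end_rel = pre_s + cpb_s + post_s
        window = AnalysisWindow("cpb", pre_s, pre_s + cpb_s)
        series = simulate_map_series(
            rng, mm, window, end_rel, target_twa=2.0, op_id=op_id, interval_scale=interval_scale
        )
        emit_vitals(op_id, start_abs, series)
        if invalid:
            cpb_cols = (start_abs + pre_s + cpb_s, start_abs + pre_s)  # stop before start
        elif with_cpb:
            cpb_cols = (start_abs + pre_s, start_abs + pre_s + cpb_s)
        else:
            cpb_cols = (math.nan, math.nan)
        ops_rows.append((op_id, pid, "CABG", 0, start_abs, start_abs + end_rel, *cpb_cols))
        return start_abs

    for _ in range(cfg.n_no_cpb):
        pid = f"xnc{k:03d}"; k += 1
        erow = extra_patient(pid)
        start = standard_op(pid, f"opx{k:03d}", with_cpb=False)
        t_lab, v_lab = _creatinine_trajectory(rng, float(erow["baseline_scr"]), 0)
        emit_labs(pid, start, t_lab, v_lab)
    for _ in range(cfg.n_invalid_cpb):
        pid = f"xiv{k:03d}"; k += 1
        erow = extra_patient(pid)
        start = standard_op(pid, f"opx{k:03d}", invalid=True)
        t_lab, v_lab = _creatinine_trajectory(rng, float(erow["baseline_scr"]), 0)
        emit_labs(pid, start, t_lab, v_lab)
    for _ in range(cfg.n_low_resolution):
        pid = f"xlr{k:03d}"; k += 1
        erow = extra_patient(pid)
        start = standard_op(pid, f"opx{k:03d}", interval_scale=10.0)
        t_lab, v_lab = _creatinine_trajectory(rng, float(erow["baseline_scr"]), 0)
        emit_labs(pid, start, t_lab, v_lab)
    for _ in range(cfg.n_no_baseline):
        pid = f"xnb{k:03d}"; k += 1
        erow = extra_patient(pid)
        start = standard_op(pid, f"opx{k:03d}")
        t_lab, v_lab = _creatinine_trajectory(rng, float(erow["baseline_scr"]), 0)
        post_only = t_lab >= 0
        emit_labs(pid, start, t_lab[post_only], v_lab[post_only])
    for j in range(cfg.n_reoperation):
        pid = table.iloc[j]["patient_id"]  # second op for an existing patient
        k += 1
        base_start = ops_rows[j][4]
        start_abs = base_start + 30 * SECONDS_PER_DAY
        pre_s, cpb_s, post_s = (40 * 60.0, 100 * 60.0, 60 * 60.0)
        end_rel = pre_s + cpb_s + post_s
        window = AnalysisWindow("cpb", pre_s, pre_s + cpb_s)
        op_id = f"opx{k:03d}"
        series = simulate_map_series(rng, mm, window, end_rel, target_twa=2.0, op_id=op_id)
        emit_vitals(op_id, start_abs, series)
        ops_rows.append(
            (op_id, pid, "CABG", 0, start_abs, start_abs + end_rel,
             start_abs + pre_s, start_abs + pre_s + cpb_s)
        )

    if extra_pat_rows:
        patients = pd.concat([patients, pd.DataFrame(extra_pat_rows)], ignore_index=True)
    if cfg.missing_weight_rate > 0:
        mask = rng.random(len(patients)) < cfg.missing_weight_rate
        patients.loc[mask, "weight"] = np.nan

    vitals = pd.DataFrame(
        {
            "op_id": np.concatenate(vit_op),
            "time": np.concatenate(vit_t),
            "parameter": "map",
            "value": np.round(np.concatenate(vit_v), 2),
        }
    )
    operations = pd.DataFrame(
        ops_rows,
        columns=["op_id", "patient_id", "surgery_type", "emergency",
                 "surgery_start", "surgery_end", "cpb_start", "cpb_stop"],
    )
    labs = pd.DataFrame(labs_rows, columns=["patient_id", "time", "analyte", "value"])
    labs["value"] = labs["value"].round(3)

    truth = dict(truth)
    truth["twa65_cpb_drawn"] = table["twa65_cpb"].to_numpy()
    truth["twa65_cpb_realized"] = realized_twa
    truth["aki"] = table["aki"].to_numpy()
    truth["crrt"] = table["crrt"].to_numpy()
    truth["aki_stage"] = table["aki_stage"].to_numpy()
    truth["patient_id"] = table["patient_id"].tolist()
    return SimulatedCohort(vitals, operations, labs, patients, table, truth)
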