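"""Association models: rank-sum group comparisons, crude and multivariable
logistic regressions (ORs with 95% Wald CIs), predicted-probability curves
with delta-method bands, and the sensitivity/subgroup analysis suite.

Maximum-likelihood logistic fits are delegated to ``statsmodels`` behind this
module's contract: degenerate outcomes and rank-deficient designs raise named
errors, separation and non-convergence yield *flagged* fits (never silent
results), and all reporting (OR = exp(beta), CI = exp(beta +/- 1.96*SE), Wald
p-values) is computed here.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
from scipy.special import expit

from .config import DEFAULT_REFERENCE_LEVELS, PipelineConfig
from .types import DegenerateOutcomeError, RankDeficiencyError

__all__ = [
    "ModelSpec",
    "ModelFit",
    "rank_sum_test",
    "fit_logistic",
    "predicted_probability_curve",
    "run_analysis_suite",
    "AnalysisBundle",
]

WALD_Z = 1.96  # reporting convention: exp(beta +/- 1.96*SE)


@dataclass(frozen=True)
class ModelSpec:
    """One logistic model: outcome, exposure term, adjustment covariates and
    an optional subgroup restriction (column, value)."""

    outcome: str
    exposure: Optional[str] = "twa65_cpb"
    covariates: tuple[str, ...] = ()
    subgroup: Optional[tuple[str, object]] = None
    label: str = ""

    def __post_init__(self):
        if self.exposure is not None and self.exposure in self.covariates:
            raise ValueError("exposure must not be duplicated in covariates")

    @property
    def terms(self) -> tuple[str, ...]:
        head = (self.exposure,) if self.exposure is not None else ()
        return head + tuple(self.covariates)


@dataclass
class ModelFit:
    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    table: pd.DataFrame  # term, beta, se, or, ci_low, ci_high, p
    n: int
    n_events: int
    converged: bool
    message: str = ""
    design_means: pd.Series = field(default_factory=pd.Series)
    dummy_cols: frozenset = frozenset()
    exposure_range: tuple[float, float] = (math.nan, math.nan)

    def to_dict(self) -> dict:
        return {
            "label": self.spec.label,
            "outcome": self.spec.outcome,
            "exposure": self.spec.exposure,
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
            "message": self.message,
            "params": self.params.to_dict(),
            "cov": {c: self.cov[c].to_dict() for c in self.cov.columns},
            "table": self.table.to_dict(orient="records"),
        }


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    pvalue: float
    method: str


def rank_sum_test(a, b) -> RankSumResult:
    """Two-sided Wilcoxon–Mann–Whitney test. Exact enumeration when both
    groups have n <= 10 and there are no cross-group ties; otherwise the
    normal approximation with tie and continuity corrections."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and not ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue), method)


def _merge_sparse_levels(svals: pd.Series, min_count: int) -> pd.Series:
    """Collapse levels with < min_count observations into an adjacent level
    (levels taken in sorted order, which is the severity order for graded
    scales such as eGFR strata or ASA status)."""
    if min_count <= 1:
        return svals
    counts = svals.value_counts().to_dict()
    levels = sorted(counts)
    mapping: dict[str, str] = {}
    run: list[str] = []
    run_n = 0
    last_assigned: Optional[str] = None
    for lev in levels:
        run.append(lev)
        run_n += counts[lev]
        if run_n >= min_count:
            target = run[0] if counts[run[0]] >= min_count else run[-1]
            for l in run:
                mapping[l] = target
            last_assigned = target
            run = []
            run_n = 0
    for l in run:  # trailing sparse run: merge into the last assigned level
        mapping[l] = last_assigned if last_assigned is not None else l
    return svals.map(mapping)


def build_design(
    cohort: pd.DataFrame,
    terms: Sequence[str],
    reference_levels: Optional[dict[str, str]] = None,
    min_level_count: int = 10,
) -> tuple[pd.DataFrame, frozenset]:
    """Design matrix with intercept; reference-cell dummy coding for
    categorical terms (columns named in ``reference_levels`` or non-numeric),
    with sparse levels merged into an adjacent level to avoid quasi-separation
    from near-empty cells. Returns (X, dummy_column_names)."""
    refs = DEFAULT_REFERENCE_LEVELS if reference_levels is None else reference_levels
    X = pd.DataFrame(index=cohort.index)
    X["const"] = 1.0
    dummies: set[str] = set()
    for col in terms:
        s = cohort[col]
        categorical = col in refs or not pd.api.types.is_numeric_dtype(s)
        if categorical:
            svals = _merge_sparse_levels(s.astype(str), min_level_count)
            levels = sorted(svals.unique())
            ref = str(refs.get(col, levels[0]))
            if ref not in levels:
                ref = levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{col}[{lev}]"
                X[name] = (svals == lev).astype(float)
                dummies.add(name)
        else:
            if s.nunique(dropna=False) <= 1:
                continue  # constant column: aliased with the intercept
            X[col] = s.astype(float)
    return X, frozenset(dummies)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [X.columns[i] for i in piv[rank:]]
        raise RankDeficiencyError(bad)


def fit_logistic(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    reference_levels: Optional[dict[str, str]] = None,
    min_level_count: int = 10,
) -> ModelFit:
    """Maximum-likelihood logistic regression for one :class:`ModelSpec`.

    Raises :class:`DegenerateOutcomeError` when the outcome has one class and
    :class:`RankDeficiencyError` naming collinear columns. Separation or
    non-convergence returns a fit flagged ``converged=False`` with a
    diagnostic message.
    """
    data = cohort
    if spec.subgroup is not None:
        col, val = spec.subgroup
        data = cohort[cohort[col] == val]
    missing = [c for c in spec.terms if c not in data.columns]
    if missing:
        raise KeyError(f"cohort is missing model columns {missing}")
    y = data[spec.outcome].astype(float)
    if y.nunique() < 2:
        raise DegenerateOutcomeError("degenerate_outcome")
    X, dummies = build_design(data, spec.terms, reference_levels, min_level_count)
    _check_rank(X)

    converged = True
    message = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
        params = res.params
        cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
        converged = bool(res.mle_retvals.get("converged", False))
        if not converged:
            message = "mle_did_not_converge"
        if np.any(~np.isfinite(params)) or np.any(~np.isfinite(np.diag(cov))):
            converged = False
            message = message or "non_finite_estimates"
        elif np.max(np.abs(params.to_numpy())) > 20:
            converged = False
            message = "possible_separation"
    except Exception as exc:  # separation / singular Hessian inside optimiser
        params = pd.Series(np.nan, index=X.columns)
        cov = pd.DataFrame(np.nan, index=X.columns, columns=X.columns)
        converged = False
        message = f"fit_failed: {type(exc).__name__}"

    se = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
    beta = params
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        z = beta / se
        pvals = 2.0 * scipy.stats.norm.sf(np.abs(z))
        table = pd.DataFrame(
            {
                "term": X.columns,
                "beta": beta.to_numpy(),
                "se": se.to_numpy(),
                "or": np.exp(beta.to_numpy()),
                "ci_low": np.exp(beta.to_numpy() - WALD_Z * se.to_numpy()),
                "ci_high": np.exp(beta.to_numpy() + WALD_Z * se.to_numpy()),
                "p": pvals,
            }
        )
    exp_range = (math.nan, math.nan)
    if spec.exposure is not None:
        ex = data[spec.exposure].astype(float)
        exp_range = (float(ex.min()), float(ex.max()))
    return ModelFit(
        spec=spec,
        params=params,
        cov=cov,
        table=table,
        n=int(len(y)),
        n_events=int(y.sum()),
        converged=converged,
        message=message,
        design_means=X.mean(),
        dummy_cols=dummies,
        exposure_range=exp_range,
    )


@dataclass(frozen=True)
class ProbabilityCurve:
    grid: np.ndarray
    p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def predicted_probability_curve(
    fit: ModelFit,
    grid,
    profile: Optional[dict[str, float]] = None,
) -> ProbabilityCurve:
    """Predicted outcome probability over an exposure grid with a 95%
    delta-method band (computed on the linear predictor, then transformed, so
    the band always lies within [0, 1]).

    Covariate profile: continuous design columns at their fitted means,
    dummy columns at 0 (reference levels); override via ``profile``.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    if fit.spec.exposure is None:
        raise ValueError("fit has no exposure term")
    grid = np.asarray(grid, dtype=float)
    lo, hi = fit.exposure_range
    if np.isfinite(lo) and (grid.min() < lo or grid.max() > hi):
        warnings.warn("exposure grid extends outside the observed range", stacklevel=2)
    cols = list(fit.params.index)
    Xg = pd.DataFrame(index=np.arange(grid.size), columns=cols, dtype=float)
    for c in cols:
        if c == fit.spec.exposure:
            Xg[c] = grid
        elif c == "const":
            Xg[c] = 1.0
        elif c in fit.dummy_cols:
            Xg[c] = 0.0
        else:
            Xg[c] = fit.design_means[c]
    if profile:
        for k, v in profile.items():
            Xg[k] = v
    arr = Xg.to_numpy()
    lp = arr @ fit.params.to_numpy()
    var = np.einsum("ij,jk,ik->i", arr, fit.cov.to_numpy(), arr)
    se = np.sqrt(np.clip(var, 0.0, None))
    return ProbabilityCurve(grid, expit(lp), expit(lp - WALD_Z * se), expit(lp + WALD_Z * se))


# ---------------------------------------------------------------------------
# analysis suite
# ---------------------------------------------------------------------------


@dataclass
class AnalysisBundle:
    descriptives: pd.DataFrame
    effects: pd.DataFrame          # crude + adjusted ORs, primary threshold
    sensitivity_75: pd.DataFrame   # 75-mmHg exposure variant
    subgroups: pd.DataFrame        # hypertension yes/no
    fits: dict[str, ModelFit]
    curve: Optional[ProbabilityCurve]
    figures: dict[str, object] = field(default_factory=dict)

    def all_converged(self) -> bool:
        return all(f.converged for f in self.fits.values())

    def save(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.descriptives.to_csv(out / "table_descriptives.csv", index=False)
        self.effects.to_csv(out / "table_effects.csv", index=False)
        self.sensitivity_75.to_csv(out / "table_sensitivity_75.csv", index=False)
        self.subgroups.to_csv(out / "table_subgroups_hypertension.csv", index=False)
        from .io import write_json

        write_json({k: f.to_dict() for k, f in self.fits.items()}, out / "models.json")
        if self.curve is not None:
            pd.DataFrame(
                {
                    "exposure": self.curve.grid,
                    "p": self.curve.p,
                    "ci_low": self.curve.ci_low,
                    "ci_high": self.curve.ci_high,
                }
            ).to_csv(out / "predicted_probabilities.csv", index=False)
        for name, fig in self.figures.items():
            fig.savefig(out / f"{name}.png", dpi=150)
            fig.savefig(out / f"{name}.svg")


def _or_row(fit: ModelFit, term: str) -> dict:
    row = fit.table.loc[fit.table["term"] == term]
    if row.empty:
        return {"or": math.nan, "ci_low": math.nan, "ci_high": math.nan, "p": math.nan}
    r = row.iloc[0]
    return {"or": r["or"], "ci_low": r["ci_low"], "ci_high": r["ci_high"], "p": r["p"]}


def descriptive_table(
    cohort: pd.DataFrame,
    by: str,
    variables: Sequence[str],
    reference_levels: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Median (IQR) for numeric variables and count (%) per level for
    categoricals, split by a binary column, with rank-sum p-values for
    numeric/binary rows (the caption convention; multi-level categoricals get
    no p-value)."""
    refs = DEFAULT_REFERENCE_LEVELS if reference_levels is None else reference_levels
    g1 = cohort[cohort[by] == 1]
    g0 = cohort[cohort[by] == 0]
    rows = []
    for var in variables:
        s = cohort[var]
        if pd.api.types.is_numeric_dtype(s) and var not in refs:
            a, b = g1[var].dropna(), g0[var].dropna()
            p = rank_sum_test(a, b).pvalue if len(a) and len(b) else math.nan
            if set(s.dropna().unique()) <= {0, 1}:
                rows.append(
                    {
                        "variable": var,
                        "level": "",
                        "group1": f"{int(a.sum())} ({100 * a.mean():.1f}%)",
                        "group0": f"{int(b.sum())} ({100 * b.mean():.1f}%)",
                        "p": p,
                    }
                )
            else:
                rows.append(
                    {
                        "variable": var,
                        "level": "",
                        "group1": f"{a.median():.2f} ({a.quantile(0.25):.2f}-{a.quantile(0.75):.2f})",
                        "group0": f"{b.median():.2f} ({b.quantile(0.25):.2f}-{b.quantile(0.75):.2f})",
                        "p": p,
                    }
                )
        else:
            svals = s.astype(str)
            for lev in sorted(svals.unique()):
                n1 = int((g1[var].astype(str) == lev).sum())
                n0 = int((g0[var].astype(str) == lev).sum())
                rows.append(
                    {
                        "variable": var,
                        "level": lev,
                        "group1": f"{n1} ({100 * n1 / max(len(g1), 1):.1f}%)",
                        "group0": f"{n0} ({100 * n0 / max(len(g0), 1):.1f}%)",
                        "p": math.nan,
                    }
                )
    return pd.DataFrame(rows)


def run_analysis_suite(
    cohort: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
    example_series=None,
    example_window=None,
    curve_points: int = 100,
) -> AnalysisBundle:
    """Produce the full report bundle: descriptive comparison with rank-sum
    p-values; crude and adjusted ORs for both outcomes; the 75-mmHg exposure
    sensitivity variant; the hypertension subgroup fits (covariates minus
    hypertension); and the exposure / predicted-probability figures."""
    cfg = config or PipelineConfig()
    refs = cfg.reference_levels
    covariates = tuple(cfg.covariates)
    exposure = cfg.exposure
    fits: dict[str, ModelFit] = {}

    def _fit(spec: ModelSpec) -> ModelFit:
        return fit_logistic(cohort, spec, refs, cfg.min_level_count)

    desc_vars = [exposure, *covariates, "aki_stage"]
    descriptives = descriptive_table(cohort, "aki", desc_vars, refs)

    # crude + adjusted, both outcomes, primary threshold
    effect_rows = []
    for outcome in ("aki", "crrt"):
        adj = _fit(ModelSpec(outcome, exposure, covariates, label=f"adjusted_{outcome}"))
        fits[f"adjusted_{outcome}"] = adj
        crude_exp = _fit(ModelSpec(outcome, exposure, (), label=f"crude_{outcome}"))
        fits[f"crude_{outcome}"] = crude_exp
        effect_rows.append(
            {"outcome": outcome, "term": exposure,
             **{f"crude_{k}": v for k, v in _or_row(crude_exp, exposure).items()},
             **{f"adj_{k}": v for k, v in _or_row(adj, exposure).items()}}
        )
        for cov_name in covariates:
            crude = _fit(ModelSpec(outcome, None, (cov_name,), label=f"crude_{outcome}_{cov_name}"))
            for term in crude.table["term"]:
                if term == "const":
                    continue
                effect_rows.append(
                    {"outcome": outcome, "term": term,
                     **{f"crude_{k}": v for k, v in _or_row(crude, term).items()},
                     **{f"adj_{k}": v for k, v in _or_row(adj, term).items()}}
                )
    effects = pd.DataFrame(effect_rows)

    # 75-mmHg sensitivity: exposures recomputed at 75, same covariate roles
    cov75 = tuple("twa75_postcpb" if c == "twa65_postcpb" else c for c in covariates)
    sens_rows = []
    for outcome in ("aki", "crrt"):
        f75 = _fit(ModelSpec(outcome, "twa75_cpb", cov75, label=f"adjusted75_{outcome}"))
        fits[f"adjusted75_{outcome}"] = f75
        sens_rows.append({"outcome": outcome, "term": "twa75_cpb", **_or_row(f75, "twa75_cpb")})
    sensitivity_75 = pd.DataFrame(sens_rows)

    # hypertension subgroups: covariate set minus hypertension, AKI outcome
    cov_nohtn = tuple(c for c in covariates if c != "hypertension")
    sub_rows = []
    for val, name in ((1, "hypertension"), (0, "no_hypertension")):
        fsub = _fit(
            ModelSpec("aki", exposure, cov_nohtn, subgroup=("hypertension", val), label=f"subgroup_{name}")
        )
        fits[f"subgroup_{name}"] = fsub
        sub_rows.append({"subgroup": name, "n": fsub.n, "n_events": fsub.n_events,
                         "term": exposure, **_or_row(fsub, exposure)})
    subgroups = pd.DataFrame(sub_rows)

    curve = None
    figures: dict[str, object] = {}
    adj_aki = fits["adjusted_aki"]
    if adj_aki.converged:
        lo, hi = adj_aki.exposure_range
        grid = np.linspace(lo, hi, curve_points)
        curve = predicted_probability_curve(adj_aki, grid)
        figures["fig_probability"] = plot_probability_curve(curve, exposure)
    if example_series is not None and example_window is not None:
        figures["fig_exposure"] = plot_exposure_trace(
            example_series, example_window, threshold=cfg.thresholds[0]
        )

    return AnalysisBundle(descriptives, effects, sensitivity_75, subgroups, fits, curve, figures)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------


def plot_exposure_trace(series, window, threshold: float = 65.0):
    """MAP trace with the below-threshold area inside the analysis window
    shaded and the window bounds marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .types import SECONDS_PER_MINUTE

    fig, ax = plt.subplots(figsize=(8, 4))
    t_min = series.t / SECONDS_PER_MINUTE
    ax.plot(t_min, series.v, lw=0.8, color="steelblue")
    ax.axhline(threshold, color="red", ls="--", lw=1)
    for x in (window.t_start, window.t_stop):
        ax.axvline(x / SECONDS_PER_MINUTE, color="black", ls="--", lw=1)
    in_win = (series.t >= window.t_start) & (series.t <= window.t_stop)
    ax.fill_between(
        t_min[in_win],
        np.minimum(series.v[in_win], threshold),
        threshold,
        where=series.v[in_win] < threshold,
        color="red",
        alpha=0.3,
        interpolate=True,
    )
    ax.set_xlabel("surgery time (min)")
    ax.set_ylabel("MAP (mmHg)")
    fig.tight_layout()
    return fig


def plot_probability_curve(curve: ProbabilityCurve, exposure_name: str):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.grid, curve.p, color="black", lw=1.5)
    ax.fill_between(curve.grid, curve.ci_low, curve.ci_high, color="red", alpha=0.3)
    ax.set_xlabel(f"{exposure_name} (mmHg)")
    ax.set_ylabel("predicted probability")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    return fig
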