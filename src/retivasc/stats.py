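"""Reliability and association analysis of the cohort table.

Mirrors the study's statistical stage: retinal metrics are first averaged
over both eyes within an examination and then over examinations (reducing
biological and technical variation respectively); test-retest reliability is
summarised with a one-way random-effects intraclass correlation; and each
metric's association with a behavioural or cognitive outcome is estimated by
ordinary least squares adjusted for an a priori covariate list (sex, age,
BMI category, mean arterial pressure, maternal occupation, passive smoking),
with effects reported per interquartile-range increment of the metric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synth import METRICS

__all__ = [
    "AnalysisSpec",
    "EffectEstimate",
    "ICCResult",
    "average_metrics",
    "icc_oneway",
    "fit_effect",
    "run_analysis_matrix",
    "DEFAULT_COVARIATES",
    "SDQ_OUTCOMES",
    "COGNITIVE_OUTCOMES",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "age", "bmi_category", "map_mmhg",
                      "low_maternal_occupation", "passive_smoking")

SDQ_OUTCOMES = ("sdq_total", "sdq_emotional", "sdq_conduct",
                "sdq_hyperactivity", "sdq_peer")
COGNITIVE_OUTCOMES = ("stroop_ms", "cp_ms", "digit_symbol_s", "pattern_comparison_s")

_BMI_DUMMIES = ("underweight", "overweight", "obese")  # reference: normal weight


@dataclass(frozen=True)
class AnalysisSpec:
    """One outcome-by-metric model: adjusted OLS with per-IQR scaling.

    ``iqr_value`` overrides the sample interquartile range (Q3 - Q1, linear
    interpolation) with a fixed value, e.g. the published IQRs 0.04 / 0.06 /
    0.02 for fractal dimension / lacunarity / tortuosity. The age quadratic
    term is available but off by default (it was tested and dropped as
    non-significant in the source analysis).
    """

    outcome: str
    metric: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    iqr_scale: bool = True
    iqr_value: float | None = None
    age_quadratic: bool = False


@dataclass
class EffectEstimate:
    outcome: str
    metric: str
    beta_per_iqr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    metric_iqr: float
    covariate_betas: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta_per_iqr <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")


@dataclass
class ICCResult:
    icc: float
    n_subjects: int
    n_observations: int
    mean_group_size: float
    clipped: bool = False


def average_metrics(
    cohort: pd.DataFrame,
    metrics: Sequence[str] = METRICS,
) -> pd.DataFrame:
    """Per-child table: eye-averaged then examination-averaged metrics.

    If per-eye columns (``<metric>_left`` / ``<metric>_right``) are present
    the within-examination eye average is recomputed from them; otherwise the
    stored examination value is used. Covariates are taken from the child's
    records (age averaged over examinations); outcomes are averaged over
    examinations. Children with no non-missing value for any metric are
    excluded and logged.
    """
    df = cohort.copy()
    present = [m for m in metrics if m in df.columns or f"{m}_left" in df.columns]
    for m in present:
        if f"{m}_left" in df.columns and f"{m}_right" in df.columns:
            df[m] = df[[f"{m}_left", f"{m}_right"]].mean(axis=1)

    id_cols = ["child_id"]
    static = [c for c in ("sex", "bmi_category", "passive_smoking",
                          "low_maternal_occupation") if c in df.columns]
    numeric = [c for c in df.columns
               if c not in id_cols + static + ["exam"]
               and pd.api.types.is_numeric_dtype(df[c])]

    grouped = df.groupby("child_id", sort=True)
    out = grouped[numeric].mean()
    for c in static:
        out[c] = grouped[c].first()
    out = out.reset_index()

    all_missing = out[list(present)].isna().all(axis=1)
    if all_missing.any():
        excluded = out.loc[all_missing, "child_id"].tolist()
        logger.info("excluding %d children with no metric data: %s",
                    len(excluded), excluded)
        out = out[~all_missing].reset_index(drop=True)
    return out


def icc_oneway(values: pd.DataFrame, value_col: str = "value",
               subject_col: str = "child_id") -> ICCResult:
    """One-way random-effects intraclass correlation, ICC(1,1).

    From the one-way ANOVA mean squares: ``(MSB - MSW) / (MSB + (k0 - 1)
    MSW)`` with ``k0 = (N - sum(k_i^2) / N) / (n - 1)`` the unbalanced-design
    group-size adjustment. Negative estimates are clipped to 0 and flagged.
    """
    df = values[[subject_col, value_col]].dropna()
    groups = df.groupby(subject_col)[value_col]
    sizes = groups.size().to_numpy(dtype=float)
    n = len(sizes)
    N = int(sizes.sum())
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if N - n <= 0:
        raise ValueError("no repeated examinations: within-subject MS undefined")
    if (sizes >= 2).sum() < 2:
        raise ValueError("need at least 2 subjects with >= 2 examinations")

    grand = df[value_col].mean()
    means = groups.mean().to_numpy()
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(((df[value_col] - groups.transform("mean")) ** 2).sum())
    msb = ssb / (n - 1)
    msw = ssw / (N - n)
    k0 = (N - np.sum(sizes ** 2) / N) / (n - 1)
    denom = msb + (k0 - 1.0) * msw
    icc = (msb - msw) / denom if denom > 0 else 0.0
    clipped = icc < 0
    if clipped:
        warnings.warn("negative ICC estimate clipped to 0")
        icc = 0.0
    return ICCResult(float(icc), n, N, float(N / n), clipped)


def _design_matrix(df: pd.DataFrame, spec: AnalysisSpec,
                   metric_scaled: np.ndarray) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, spec.metric: metric_scaled}, index=df.index)
    for cov in spec.covariates:
        if cov == "sex":
            # reference level: girls, so the coefficient is boys-vs-girls
            X["boy"] = (df["sex"] == "boy").astype(float)
        elif cov == "bmi_category":
            for lvl in _BMI_DUMMIES:  # reference: normal weight
                dummy = (df["bmi_category"] == lvl).astype(float)
                if dummy.any():  # skip levels absent from the analysis sample
                    X[f"bmi_{lvl}"] = dummy
        elif cov == "age":
            X["age"] = df["age"].astype(float)
            if spec.age_quadratic:
                X["age_sq"] = df["age"].astype(float) ** 2
        else:
            X[cov] = df[cov].astype(float)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns via pivoted QR
        _, _, piv = _qr_pivot(arr)
        bad = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _qr_pivot(arr: np.ndarray):
    from scipy.linalg import qr
    return qr(arr, mode="economic", pivoting=True)


def fit_effect(table: pd.DataFrame, spec: AnalysisSpec) -> EffectEstimate:
    """Covariate-adjusted OLS effect of one metric on one outcome.

    Complete-case (listwise-deletion) ordinary least squares of the outcome
    on the IQR-scaled metric plus the covariate design; the metric
    coefficient is the change in outcome per IQR increment, with a 95%
    t-based confidence interval on residual degrees of freedom. The IQR is
    computed on the analysis sample unless a fixed override is given.
    """
    needed = [spec.outcome, spec.metric] + [c for c in spec.covariates if c in table.columns]
    missing_cols = [c for c in [spec.outcome, spec.metric] + list(spec.covariates)
                    if c not in table.columns]
    if missing_cols:
        raise KeyError(f"columns absent from table: {missing_cols}")
    df = table[needed].dropna()
    n_used = len(df)
    if n_used < len(spec.covariates) + 5:
        raise ValueError(f"too few complete cases ({n_used})")
    if n_used < len(table):
        logger.info("listwise deletion: %d of %d records used", n_used, len(table))

    x = df[spec.metric].to_numpy(dtype=float)
    if spec.iqr_scale:
        iqr = spec.iqr_value if spec.iqr_value is not None else float(
            np.quantile(x, 0.75) - np.quantile(x, 0.25))
        if iqr <= 0:
            raise ValueError("non-positive metric IQR")
        x_scaled = x / iqr
    else:
        iqr = 1.0
        x_scaled = x

    X = _design_matrix(df, spec, x_scaled)
    _check_rank(X)
    model = sm.OLS(df[spec.outcome].to_numpy(dtype=float), X)
    res = model.fit()
    ci = res.conf_int(alpha=0.05)
    return EffectEstimate(
        outcome=spec.outcome,
        metric=spec.metric,
        beta_per_iqr=float(res.params[spec.metric]),
        ci_low=float(ci.loc[spec.metric, 0]),
        ci_high=float(ci.loc[spec.metric, 1]),
        p_value=float(res.pvalues[spec.metric]),
        n_used=n_used,
        metric_iqr=float(iqr),
        covariate_betas={c: float(res.params[c]) for c in X.columns
                         if c not in ("const", spec.metric)},
    )


def run_analysis_matrix(
    table: pd.DataFrame,
    outcomes: Sequence[str] = SDQ_OUTCOMES + COGNITIVE_OUTCOMES,
    metrics: Sequence[str] = METRICS,
    **spec_kwargs,
) -> pd.DataFrame:
    """Tidy grid of adjusted per-IQR effects, one row per outcome x metric.

    Cells whose fit fails are reported as missing rather than aborting the
    grid.
    """
    rows = []
    for outcome in outcomes:
        for metric in metrics:
            try:
                est = fit_effect(table, AnalysisSpec(outcome, metric, **spec_kwargs))
                rows.append({
                    "outcome": outcome, "metric": metric,
                    "beta_per_iqr": est.beta_per_iqr,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "p_value": est.p_value, "n": est.n_used,
                    "metric_iqr": est.metric_iqr,
                })
            except (ValueError, KeyError) as exc:
                logger.warning("fit failed for %s ~ %s: %s", outcome, metric, exc)
                rows.append({
                    "outcome": outcome, "metric": metric,
                    "beta_per_iqr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p_value": np.nan, "n": 0, "metric_iqr": np.nan,
                })
    return pd.DataFrame(rows)


def format_report(effects: pd.DataFrame) -> str:
    """Markdown report mirroring the outcome x metric estimate tables."""
    lines = ["| Outcome | Metric | Change per IQR (95% CI) | P |",
             "|---|---|---|---|"]
    for _, r in effects.iterrows():
        if np.isnan(r["beta_per_iqr"]):
            lines.append(f"| {r['outcome']} | {r['metric']} | (not estimable) | - |")
        else:
            lines.append(
                f"| {r['outcome']} | {r['metric']} | "
                f"{r['beta_per_iqr']:.2f} ({r['ci_low']:.2f} to {r['ci_high']:.2f}) | "
                f"{r['p_value']:.3g} |"
            )
    return "\n".join(lines)
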