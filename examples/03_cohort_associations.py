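"""Simulate a cohort and estimate covariate-adjusted per-IQR effects.

Fast path: a cohort of 190 children with repeated examinations is drawn from
the configured population (metric means/SDs, visit mix, covariates, effect
structure); metrics are averaged over eyes and examinations and each
metric-outcome association is estimated by OLS adjusted for sex, age, BMI
category, mean arterial pressure, maternal occupation and passive smoking,
reported per interquartile-range increment of the metric.
"""

import retivasc as rv
from retivasc.stats import AnalysisSpec, fit_effect

cohort = rv.simulate_cohort(rv.CohortParams(seed=1))
per_child = rv.average_metrics(cohort)
print(f"cohort: {per_child.shape[0]} children, {len(cohort)} examinations")
print(f"median SDQ total problem score: {per_child.sdq_total.median():.0f}")
print(f"mean CP reaction time: {per_child.cp_ms.mean():.0f} ms")

# published IQRs for exact comparability across runs
for outcome, metric, iqr, truth in [
    ("sdq_total", "df", 0.04, 1.12),
    ("sdq_total", "lac", 0.06, -1.38),
    ("cp_ms", "df", 0.04, 11.0),
    ("cp_ms", "tort", 0.02, -13.4),
]:
    est = fit_effect(per_child, AnalysisSpec(outcome, metric, iqr_value=iqr))
    print(f"{outcome} ~ {metric}: {est.beta_per_iqr:+.2f} per IQR "
          f"(95% CI {est.ci_low:+.2f} to {est.ci_high:+.2f}, p={est.p_value:.3g}; "
          f"configured truth {truth:+.2f})")

# the full outcome x metric grid, as a markdown report
effects = rv.run_analysis_matrix(per_child)
sig = effects[effects.p_value < 0.05]
print(f"\ngrid: {len(effects)} models, {len(sig)} with p < 0.05 "
      "(geometry metrics drive SDQ and sustained attention; "
      "caliber effects are configured null)")
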