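"""Covariate-adjusted group comparison of the measured ALPS index.

Simulates the default 70-subject cohort through the full imaging pipeline
at 1% Rician noise, then fits the GLM of bilateral ALPS on group dummies
plus the seven clinical covariates, reporting the three pairwise
contrasts with Bonferroni (FWE) correction and Cohen's d from the raw
group summaries.  The population ordering is NGM > Pre-DM > T2DM; how
large the sample effects come out (and whether they reach significance
at n = 70) varies with the sampled cohort.
"""

from dtialps import (AcquisitionScheme, CohortConfig, PhantomGeometry,
                     all_group_contrasts, compute_vif, COVARIATE_COLUMNS,
                     generate_cohort)
from dtialps.pipeline import measure_cohort

cfg = CohortConfig(master_seed=3, noise_sigma=0.01)
cohort, truth = generate_cohort(cfg)
measured = measure_cohort(truth, PhantomGeometry.default((48, 20, 20)),
                          AcquisitionScheme.default(), noise_sigma=0.01)
merged = cohort.merge(measured, on="subject_id")

print("measured ALPS by group (mean ± SD):")
for g, v in merged.groupby("group")["alps_bilateral"]:
    print(f"  {g}: {v.mean():.2f} ± {v.std(ddof=1):.2f} (n={len(v)})")

print("\nVIF screen (all should be < 5):")
print(compute_vif(merged.loc[:, list(COVARIATE_COLUMNS)]).round(2).to_dict())

print("\npairwise GLM contrasts (7 covariates, Bonferroni m=3):")
for c in all_group_contrasts(merged["alps_bilateral"].to_numpy(), merged):
    print(f"  {c.pair[0]:>6} vs {c.pair[1]:<6} adj.diff={c.adjusted_difference:+.3f} "
          f"t={c.t:+.2f}  p_fwe={c.p_fwe:.4f}  d={c.cohens_d:+.2f} "
          f"({c.effect_category})")
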