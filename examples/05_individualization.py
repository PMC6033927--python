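"""Leave-one-out prediction of mature anatomy and individualization timing.

Builds a cohort whose subject-specific anatomy switches on at day 7 in
males and day 17 in females, predicts each subject's day-36 structure
volumes from progressively later accessed timepoints, and tests the sex
difference in when prediction error starts to fall (permutation test).
"""

from dimorphmap import individualization as ind
from dimorphmap import simulate

cfg = simulate.CohortConfig(n_per_sex=10, seed=8, sigma_noise=0.02,
                            dropout_rate=0.0)
table = simulate.generate_individualization_cohort(
    cfg, n_structures=8, onset_male=7, onset_female=17, sigma_identity=0.12)

preds = ind.predict_all_subjects(table, target_time=36, accessed_bound=29)
spec = ind.specificity_analysis(preds)
print(f"specificity: D+ = {spec.d_plus:.3f}, p = {spec.pvalue:.1e}, "
      f"{100 * spec.specificity_probability:.0f}% of subjects matched "
      "their own prediction best")
# each subject's predicted anatomy is closer to its own observation than
# to any other subject's: post-development anatomy is individualized

curves = ind.accuracy_curve(table, target_time=36)
print("\nmean RMSD by accessed timepoint (males vs females):")
print(curves.groupby(["accessed", "sex"])["rmsd"].mean().unstack().round(4))

timing = ind.individualization_timing(curves, n_perm=10000, seed=1)
print(f"\nindividualization window: p{timing.window[0]:g}-p{timing.window[1]:g}; "
      f"mean Z-RMSD female-male = {timing.observed_diff:+.2f}; "
      f"permutation p = {timing.perm_pvalue:.4f}")
print("p < 0.05: male prediction error falls earlier -> males individualize first")
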