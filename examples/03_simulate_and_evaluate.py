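"""Simulate a study-sized cohort and run the full validation analysis.

Generates 178 children with latent dehydration severity, scores the three
scales, derives the stable-weight criterion standard, and prints the
accuracy table (AUC, best cut-point, test characteristics) plus the
exclusion accounting from the run manifest.
"""

from dehydrakit import CohortConfig, generate_cohort, run_full_analysis

cohort, truth = generate_cohort(CohortConfig(n=178, seed=7))
bundle = run_full_analysis(cohort)

cols = ["scale", "cutpoint", "auc", "auc_ci_lower", "auc_ci_upper",
        "sensitivity_pct", "specificity_pct", "lr_pos", "lr_neg"]
print(bundle.accuracy_table[cols].round(2).to_string(index=False))
print()
print("weight-status counts:", bundle.manifest["weight_status_counts"])
print("determinate outcome n:", bundle.manifest["n_determinate"],
      "of", bundle.manifest["n_enrolled"],
      f"({bundle.manifest['n_outcome_positive']} outcome-positive)")
print()
strat = bundle.stratified_auc
print(strat[strat["scale"] == "CDS"][
    ["stratum", "n", "auc", "ci_lower", "ci_upper", "significant"]
].round(3).to_string(index=False))

# The AUCs land in the 0.6-0.8 range typical of bedside dehydration scales;
# children who kept gaining or losing weight (mostly the severely
# malnourished) or left within a day are excluded from accuracy analyses,
# and the stratified table shows how CDS accuracy shifts between nurse- and
# physician-examined children and across the 12-month age boundary.
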