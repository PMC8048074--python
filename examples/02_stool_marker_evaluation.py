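"""Evaluate stool qMSP markers and OR-panels on a simulated screening study.

Each marker is summarized by its ROC AUC (DeLong 95% CI) and by the
positivity cutoff that maximizes the positive likelihood ratio
LR+ = sensitivity / (1 - specificity). All marker subsets, with and
without the quantitative FIT (positive at >= 50 ng Hb/ml), are then
enumerated as any-positive panels.
"""

from methmark import (
    SimulationConfig,
    enumerate_panels,
    max_lr_cutoff,
    roc_auc,
    simulate_stool_study,
)

config = SimulationConfig(seed=7, stool_n_controls=50, stool_n_cases=43)
markers = ["GDNF_like", "SNAP91_like", "SORCS1_like"]
study = simulate_stool_study(config, markers)

print(f"subjects: {len(study.subjects)} "
      f"({(study.labels == 0).sum()} controls, {(study.labels == 1).sum()} cases)\n")

cutoffs = {}
for m in markers:
    values, labels = study.marker_values(m), study.labels
    roc = roc_auc(values, labels)
    cut = max_lr_cutoff(values, labels, marker=m)
    cutoffs[m] = cut
    print(f"{m}: AUC {roc.auc:.3f} [{roc.auc_ci[0]:.3f}-{roc.auc_ci[1]:.3f}], "
          f"cutoff {cut.cutoff:.1f} copies/ul -> sens {cut.sensitivity:.1%} "
          f"at spec {cut.specificity:.1%} (LR+ {cut.lr_positive:.1f})")

panels = enumerate_panels(study, cutoffs, fit_threshold=50.0)
print(f"\n{len(panels)} panels evaluated; top 5 by specificity then sensitivity:")
cols = ["panel", "sensitivity", "specificity", "auc"]
print(panels[cols].head(5).to_string(index=False))
# A marker is positive above its LR+-optimal cutoff; a panel is positive
# when any member (or FIT, if included) is positive, so adding markers
# trades specificity for sensitivity.
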