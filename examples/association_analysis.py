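"""Uptake/texture vs UPDRS-III associations on a synthetic cohort.

Simulates the full 85 PD + 56 HC study, then contrasts the two headline
analyses: conventional putamen mean uptake is strongly anti-correlated
with motor severity only when controls are included, while within PD
the more-affected caudate carries the signal in its texture (FDR-
corrected across the 14-metric family), not in its mean uptake.
Runtime is about half a minute.
"""

from striatex import (
    PhantomParams,
    analyze_measure,
    clinical_frame,
    extract_features,
    simulate_cohort,
)

params = PhantomParams(seed=1)
cohort = simulate_cohort(params, n_pd=85, n_hc=56)
features = extract_features(
    cohort.volumes, cohort.masks, [r.subject_id for r in cohort.records]
)
clinical = clinical_frame(cohort.records)

put = analyze_measure(features, clinical, "updrs3", region="putamen",
                      side="more", subset="PD+HC").table.set_index("metric")
print("putamen (more affected), PD+HC, conventional uptake vs UPDRS-III:")
print(f"  r = {put.loc['mean_normalized', 'r']:+.3f}, "
      f"p = {put.loc['mean_normalized', 'p']:.2g}")

rep = analyze_measure(features, clinical, "updrs3", region="caudate",
                      side="more", subset="PD")
caud = rep.table.set_index("metric")
print("\ncaudate (more affected), PD only, vs UPDRS-III:")
for metric in ("mean_normalized", "entropy", "contrast", "dissimilarity",
               "homogeneity"):
    row = caud.loc[metric]
    flag = "*" if row["fdr_significant"] else " "
    print(f"  {metric:<16} r = {row['r']:+.3f}  p = {row['p']:.2g} {flag}")
print("  (* = significant after Benjamini-Hochberg FDR at alpha = 0.05)")
print(f"\nstepwise-selected multivariate predictors: {rep.model.selected}")
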