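"""Predict acceptance with the regression forest and rank features.

Fits the 30-tree MSE-impurity forest on a synthetic cohort, evaluates it
by ten-fold cross-validated MAE on the five benchmark feature subsets
(all features / emotions only / sensors only / GSR only / pulse only),
and prints the impurity-based feature-importance ranking.
"""

from sensefuse import (CohortConfig, RandomForest, feature_names, fuse_cohort,
                       simulate_cohort, subset_experiment)

cohort = simulate_cohort(CohortConfig(seed=5))
df = fuse_cohort(cohort.records, on_empty="skip")
taste = df[df.modality == "taste"]
print(f"taste panel: {len(taste)} trials")

table = subset_experiment(taste, seed=5)
print("\nten-fold CV mean MAE per feature subset (hedonic-scale units):")
print(table["taste"].round(3).to_string())
print(f"\nbest subset: {table['taste'].idxmin()!r} — on this GSR-dominant cohort the "
      "skin-conductance channel alone predicts acceptance best.")

names = feature_names()
model = RandomForest(seed=5).fit(taste[list(names)].to_numpy(),
                                 taste["acceptance"].to_numpy(), feature_names=names)
print("\ntop-5 features by impurity-reduction importance (shares sum to 1):")
for name, fi in model.feature_importance().top(5):
    print(f"  {name:12s} {fi:.3f}")
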