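"""Descriptive statistics of a cohort: the results-section views.

Hedonic histograms per sample, per-emotion distributions of per-consumer
means, the absolute-Pearson correlation of features with acceptance, and
cross-participant GSR curves for liked vs disliked samples.
"""

from sensefuse import CohortConfig, fuse_cohort, fusion, simulate_cohort
from sensefuse.report import (abs_pearson_matrix, emotion_summary, group_signal_curves,
                              hedonic_histogram)

cohort = simulate_cohort(CohortConfig(n_participants=30, seed=9))
df = fuse_cohort(cohort.records)
taste = [r for r in cohort.records if r.modality == "taste"]

print("hedonic histogram, taste sample 5_gouda_cheese (counts per level -3..+3):")
gouda = df[(df.modality == "taste") & (df.sample_id == "5_gouda_cheese")]
print(" ", hedonic_histogram(gouda["acceptance"]).to_dict())

_, stats = emotion_summary(cohort.records)
print("\nmedian per-consumer mean probability by expression (sadness dominates):")
print(stats["median"].sort_values(ascending=False).round(3).to_string())

cols = [*fusion.feature_names(), "acceptance"]
corr = abs_pearson_matrix(df[cols])
with_acc = corr.as_frame()["acceptance"].drop("acceptance")
print("\n|r| with acceptance, top 5 features:")
print(with_acc.sort_values(ascending=False).head(5).round(3).to_string())

print("\ncross-participant GSR mean range per taste sample (liked flags):")
for curve in group_signal_curves(taste, "gsr"):
    rng_ = curve.mean.max() - curve.mean.min()
    tag = "liked" if curve.liked else "disliked"
    print(f"  {curve.sample_id:16s} {tag:9s} range {rng_:5.2f}")
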