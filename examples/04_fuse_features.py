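"""Fuse a cohort's three data streams into the 44-feature matrix.

Each trial's emotion trace (nine expressions), GSR and pulse are reduced
to {average, std, min, max} per stream: (9 + 2) x 4 = 44 features, the
representation the acceptance predictor consumes.
"""

from sensefuse import CohortConfig, feature_names, fuse_cohort, fuse_experiment, simulate_cohort

cohort = simulate_cohort(CohortConfig(n_participants=10, seed=3))
fv = fuse_experiment(cohort.records[0])
print(f"one trial -> {fv.values.size} features, e.g.:")
for name in ("sad_avr", "happy_avr", "gsr_avr", "gsr_std", "pulse_std"):
    print(f"  {name:10s} = {fv.as_dict()[name]:8.3f}")

df = fuse_cohort(cohort.records)
print(f"\ncohort matrix: {df.shape[0]} trials x {df.shape[1]} columns "
      f"(3 ids + {len(feature_names())} features + acceptance)")
print("\nGSR std by sample (disliked samples drift/jitter more by design):")
print(df.groupby("sample_id")["gsr_std"].mean().round(2).to_string())
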