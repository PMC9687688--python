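"""Balance an imbalanced cohort with SMOTE and scale features to [0, 1].

Uses the study-sized cohort (162 Parkinson / 55 healthy subjects):
synthetic healthy rows are interpolated between real minority neighbours
until both classes count 162, giving 324 rows in total.
"""

from wavetap import SmoteConfig, default_scenario, extract_matrix, minmax_scale, simulate_cohort, smote_oversample

cfg = default_scenario()
cfg.events_per_subject = 60  # keep the demo quick
logs = simulate_cohort(cfg)
matrix = extract_matrix(logs)
print(f"before: {matrix.n_subjects} rows, class counts {matrix.class_counts()}")

balanced = smote_oversample(matrix, SmoteConfig(k_neighbors=5, seed=42))
n_synth = int((balanced.provenance == "synthetic").sum())
print(f"after : {balanced.n_subjects} rows, class counts {balanced.class_counts()}")
print(f"        {n_synth} synthetic rows flagged via the provenance column")

scaled, col_min, col_max = minmax_scale(balanced)
print(f"scaled value range: [{scaled.values.min():.1f}, {scaled.values.max():.1f}]")
print("the (min, max) per column are returned so the transform can be reused on new data")
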