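"""Extract the 76-feature summary table and rank features by class signal.

Generates a two-condition dataset with a planted effect, extracts one
76-feature vector per trial, and shows the top ANOVA-ranked features.
"""

import gazeits as g
from gazeits.features import extract_feature_table, rank_features, \
    zscore_fit_apply, FEATURE_NAMES

cfg = g.GeneratorConfig(sampling_rate_hz=120, trial_length_s=5,
                        n_participants=4, trials_per_participant=20,
                        effect_size=1.5, seed=7)
ds = g.generate_dataset(cfg)
table = extract_feature_table(ds.trials)
print(f"feature table: {table.shape[0]} trials x "
      f"{len(FEATURE_NAMES)} features")

X = table[list(FEATURE_NAMES)]
Xz, _, _ = zscore_fit_apply(X)
names, scores = rank_features(Xz, table["condition"], "anova")
print("\ntop 8 features by ANOVA F (condition separability):")
for n, s in list(zip(names, scores))[:8]:
    print(f"  {n:20s} F = {s:8.1f}")
print("\nHigh-F features reflect the planted effect: scanpath disorder, "
      "longer fixations and vergence variability in condition B.")
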