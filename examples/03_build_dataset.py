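"""Assemble the labeled modeling dataset from a simulated cohort.

Pipeline: extract one feature row per activity, drop rows with fewer than
3 movements (no meaningful exercise), attach each patient's clinician
severity class, split 80/20 with stratification, and fit z-score
normalization on the training partition only.
"""

import rehabkit as rk

config = rk.SimulationConfig(n_patients=12, sessions_per_patient_range=(4, 6), seed=5)
features, assessments = rk.generate_labeled_features(config)
print(f"extracted {len(features)} activity rows from {config.n_patients} patients")

kept = rk.filter_low_activity(features, min_movements=3)
print(f"movement filter (N_mov >= 3) kept {len(kept)} rows")

labeled = rk.attach_labels(kept, assessments)
print("class counts (0=no, 1=low, 2=high):", labeled["Class"].value_counts().to_dict())

split = rk.split_dataset(labeled, train_fraction=0.8, seed=5, stratified=True)
print(f"train {len(split.train)} / test {len(split.test)} rows")

train_z = split.train_normalized[rk.MODEL_FEATURES]
test_z = split.test_normalized[rk.MODEL_FEATURES]
print(
    "train z-scores: |mean| max = %.2e, SD range = [%.6f, %.6f]"
    % (train_z.mean().abs().max(), train_z.std(ddof=0).min(), train_z.std(ddof=0).max())
)
print(
    "test z-scores use TRAIN statistics, so their mean need not be 0: "
    "|mean| max = %.3f" % test_z.mean().abs().max()
)
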