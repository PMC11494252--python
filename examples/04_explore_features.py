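"""Feature-redundancy and dimensionality diagnostics on the training set.

The correlation rule drops one of any feature pair with |r| > 0.9, except
pairs kept by an explicit override (the flexion/extension force pair is
retained by default: both directions of strength recovery are clinically
informative even when strongly anti-correlated).
"""

import rehabkit as rk

features, assessments = rk.generate_labeled_features(
    rk.SimulationConfig(n_patients=20, sessions_per_patient_range=(5, 8), seed=2)
)
labeled = rk.attach_labels(rk.filter_low_activity(features), assessments)
split = rk.split_dataset(labeled, 0.8, seed=2)
train_z = split.train_normalized

report = rk.correlation_matrix(train_z)
dropped = rk.redundancy_filter(report)

print("strongest feature correlations (|r| > 0.5):")
for i, a in enumerate(report.features):
    for b in report.features[i + 1 :]:
        r = report.matrix.loc[a, b]
        if abs(r) > 0.5:
            print(f"  r({a}, {b}) = {r:+.2f}")
print("pairs flagged above |r| = 0.9:", [(a, b, round(r, 3)) for a, b, r in report.flagged_pairs])
print("dropped features:", dropped or "none")
print("kept despite flag:", [(a, b) for a, b, _, _ in report.kept_overrides] or "none")

ratios = rk.pca_explained_variance(train_z)
print("\nPCA explained-variance ratios:")
print("  " + ", ".join(f"{r:.3f}" for r in ratios))
print(f"  sum = {ratios.sum():.6f} (all components together explain everything)")
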