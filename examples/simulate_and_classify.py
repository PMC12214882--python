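"""Train the six-feature HRD classifier on a synthetic cohort and score a
held-out cohort.

Generates channel catalogs for 100 HRD + 100 HRP whole-genome-like samples,
derives the six features, fits the calibrated linear SVM, and evaluates it
on an independent 50 + 50 cohort. Prints the chosen regularization
strength, the per-feature weights (sign = which class the feature marks),
and held-out performance.
"""

from hrdsense import classify, evaluate, fit, predict_proba
from hrdsense.features import derive_features
from hrdsense.synthetic import SimulationConfig, simulate_channel_counts

train_cats, train_labels = simulate_channel_counts(SimulationConfig(seed=7))
test_cats, test_labels = simulate_channel_counts(
    SimulationConfig(n_hrd=50, n_hrp=50, seed=1007, sample_prefix="T")
)

train_vectors = [derive_features(c, "WGS") for c in train_cats]
model = fit(train_vectors, train_labels, seed=7)

print(f"selected C = {model.regularization_c}, CV AUC = {model.cv_mean_auc:.3f}")
print("mean 10-fold CV feature weights (positive -> HRD-predictive):")
for name, weight in zip(model.feature_order, model.cv_mean_weights):
    print(f"  {name:>14s}  {weight:+.3f}")

test_vectors = [derive_features(c, "WGS") for c in test_cats]
probabilities = predict_proba(model, test_vectors)
calls = classify(probabilities, model.threshold)
truth = [test_labels[v.sample_id] for v in test_vectors]
report = evaluate(calls, probabilities, truth)
print(
    f"held-out (n=100): AUC={report.auc:.3f} sensitivity={report.sensitivity:.3f} "
    f"precision={report.precision:.3f} F1={report.f1:.3f}"
)
# An AUC near 1 means the six features rank every HR-deficient sample above
# every HR-proficient one on this cohort; a 0.50 probability cut then turns
# the ranking into HRD/HRP calls.
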