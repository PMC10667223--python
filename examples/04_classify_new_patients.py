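"""Train the nested-CV ensemble and risk-stratify new patients.

A 5x5 nested cross-validation tunes each model family by balanced accuracy
and leaves one fitted classifier per outer fold; the 5-member ensemble
averages class probabilities to label patients it has never seen.
"""

import numpy as np
from sklearn.linear_model import LogisticRegression

from phenomapper import (
    CoverConfig,
    NestedCVConfig,
    SimulationConfig,
    build_mapper,
    encode_features,
    generate_cohort,
    nested_cv_train,
    phenogroup_pipeline,
    predict_ensemble,
    preprocess,
)

cohort = generate_cohort(SimulationConfig(n_patients=800, seed=1))
features = preprocess(cohort.cohort_table)
events = cohort.cohort_table["event"].to_numpy(float)
graph = build_mapper(features.values, CoverConfig(), events=events)
part = phenogroup_pipeline(graph, events, seed=1)

retained = sorted(part.patient_to_group)
labels = np.array([part.patient_to_group[i] for i in retained])
X = encode_features(cohort.cohort_table).values[retained]

cfg = NestedCVConfig(seed=1, models={
    "logistic": (LogisticRegression(max_iter=2000), {"model__C": [0.1, 1.0, 10.0]}),
})
ensemble, report = nested_cv_train(X, labels, cfg)

mean, lo, hi = report.aggregate["balanced_accuracy"]
print(f"balanced accuracy: {mean:.3f} (95% CI {lo:.3f}-{hi:.3f})")
mean, lo, hi = report.aggregate["auc_micro"]
print(f"micro-averaged AUC: {mean:.3f} (95% CI {lo:.3f}-{hi:.3f})")

# classify three previously unseen patients
new = generate_cohort(SimulationConfig(n_patients=3, seed=99)).cohort_table
proba, pred = predict_ensemble(ensemble, encode_features(new).values)
for i, (p, lab) in enumerate(zip(proba, pred)):
    print(f"patient {i}: {lab:12s} p(low/int/high) = {np.round(p, 2)}")
# The predicted phenogroup tells a clinician which risk stratum a new CRT
# upgrade candidate resembles; high-risk membership is where the planted
# (and published) defibrillator benefit is concentrated.
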