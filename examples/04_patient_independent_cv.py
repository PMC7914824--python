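"""Patient-independent nested cross-validation on a synthetic cohort.

Simulates 30 patients, extracts cycle features, averages them per patient
(the best-performing aggregation) and runs the honest Setting-1 protocol:
patient-independent outer evaluation folds, and for each outer training
set a 10-model ensemble early-stopped on patient-independent inner folds.
"""

from neopcg import (
    AggregationSpec,
    SimulationParams,
    extract_cohort_features,
    run_setting,
    simulate_cohort,
)

cohort = simulate_cohort(n_healthy=18, n_pda=12, n_chd=0,
                         params=SimulationParams(), seed=42)
frame = extract_cohort_features(cohort)
print(f"feature table: {frame.shape[0]} cycles x {frame.shape[1] - 4} features")

report = run_setting(frame, setting=1, spec=AggregationSpec(mode="mean_of_features"),
                     seed=0, task="pda_vs_healthy")

print(f"validation AUC (early-stopping folds): "
      f"{report.validation_auc_mean:.3f} +/- {report.validation_auc_sd:.3f}")
print(f"patient-level test AUC (pooled out-of-fold): {report.test_auc:.3f}")
print(f"top features by gain: {[f for f, _ in report.importance[:5]]}")
print()
print("With the default murmur gain the cohort is cleanly separable, so the")
print("honest patient-independent protocol already reaches a high AUC; the")
print("top features are systolic/diastolic energy measures as expected.")
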