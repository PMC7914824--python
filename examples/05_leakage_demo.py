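"""Quantify patient-identity leakage in cross-validation.

Plants a fixed random offset per patient into every feature (a stand-in
for stethoscope placement, skin contact and other patient-specific
nuisances), weakens the murmur, then compares the honest patient-
independent protocol (Setting 1) with fully random cycle-level splits
(Setting 3). Setting 3 lets the model recognise patients instead of
pathology and reports an inflated AUC.
"""

from neopcg import (
    AggregationSpec,
    BoostingParams,
    SimulationParams,
    extract_cohort_features,
    inject_patient_offsets,
    run_setting,
    simulate_cohort,
)

cohort = simulate_cohort(12, 12, 0,
                         SimulationParams(murmur_gain=0.8, cycles_per_point=3),
                         seed=77)
frame = inject_patient_offsets(extract_cohort_features(cohort), scale=1.0, seed=1)

spec = AggregationSpec(mode="cycle_level_baseline")
params = BoostingParams(n_rounds=60)
honest = run_setting(frame, 1, spec, seed=1, params=params)
leaked = run_setting(frame, 3, spec, seed=1, params=params)

print(f"Setting 1 (patient-independent) test AUC: {honest.test_auc:.3f}")
print(f"Setting 3 (cycle-level random)  test AUC: {leaked.test_auc:.3f}")
print(f"leakage inflation: +{leaked.test_auc - honest.test_auc:.3f}")
print()
print("The weak murmur is barely detectable under the honest protocol, yet")
print("random splits look near-perfect: the model memorises each patient's")
print("offset fingerprint. Published AUCs are only meaningful when every")
print("patient's cycles stay on one side of each split.")
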