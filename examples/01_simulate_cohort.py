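"""Simulate a labelled neonatal heart-sound cohort and inspect one patient.

Builds three patients (healthy, PDA, CHD), writes them to disk as WAV +
segmentation CSV trees, and prints the in-band (200-400 Hz) energy of the
systolic and diastolic silent intervals — the acoustic fingerprint that
separates the diagnosis groups.
"""

import numpy as np

from neopcg import SimulationParams, simulate_patient, write_cohort
from neopcg.features import bandpass_filter

params = SimulationParams()  # 143 bpm, murmur band 200-400 Hz, gain 3

patients = [simulate_patient(f"P{i}", label, params, seed=i)
            for i, label in enumerate(["healthy", "PDA", "CHD"])]
write_cohort(patients, "scratch/example_cohort")

print("per-cycle 200-400 Hz energy in the silent intervals (first point 2 cycle):")
for patient in patients:
    rec = patient.recordings[2]  # pulmonic point, where PDA is loudest
    cycle = patient.segmentations[2].cycles[0]
    for interval in ("m1", "m2"):
        seg = rec.samples[cycle.interval_slices()[interval]]
        energy = np.sum(bandpass_filter(seg, rec.rate, 200, 400) ** 2)
        print(f"  {patient.label:8s} {interval}: {energy:.5f}")

print()
print("A healthy patient shows only noise-level energy in both intervals;")
print("CHD adds a systolic murmur (m1 only); PDA's continuous murmur raises")
print("both m1 and m2 — loudest here at the pulmonic auscultation point.")
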