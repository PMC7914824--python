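"""Extract the 200-feature vector from one segmented heartbeat cycle.

Simulates a PDA cycle at the 2 kHz analysis rate and prints the feature
census plus the handful of sub-band energy features that carry the murmur.
"""

import numpy as np

from neopcg import PointContext, SimulationParams, extract_cycle_features, simulate_cycle

x, cycle = simulate_cycle("PDA", SimulationParams(), np.random.default_rng(0))
context = PointContext(mean_cycle_duration=0.42,
                       mean_fc={"S1": 90.0, "m1": 50.0, "S2": 110.0, "m2": 50.0})

vector = extract_cycle_features(x, cycle, context)
print(f"features per cycle: {len(vector)}")

print("\nsystolic (m1) sub-band energies, linear scale:")
for k, band in enumerate(["25-45", "45-80", "80-200", "200-400", "400-1000"], 1):
    print(f"  m1_b{k}_en_lin  ({band:9s} Hz): {vector[f'm1_b{k}_en_lin']:.6f}")

print(f"\n  bpm = {vector['bpm']:.1f}, cycle_trel = {vector['cycle_trel']:.3f}")
print("\nThe 200-400 Hz band (b4) dominates because the simulated murmur")
print("lives exactly there; bpm and cycle_trel are the per-point globals.")
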