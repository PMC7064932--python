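"""The headline experiment: microbubble redistribution without recruitment.

Runs the paired workflow — baseline network (7% asymmetry, 12 mm Hg) versus
the simulated-hyperinsulinemia network (5.5% asymmetry, 18 mm Hg, same
topology) — with the frozen bubble-law calibration, and prints how contrast
microbubbles redistribute into more capillary paths even though every vessel
carried RBCs and plasma in both conditions.
"""

from capnet.pipeline import run_condition_pair

pair = run_condition_pair()
s = pair.summary()

print("Baseline (BN) vs simulated hyperinsulinemia (SHI):")
print(f"  total inlet flow ratio SHI/BN     : {s['inlet_blood_flow_ratio']:.2f}")
print(f"  mean terminal tube hct            : {s['mean_terminal_tube_hct_bn'] * 100:.1f}% "
      f"vs {s['mean_terminal_tube_hct_shi'] * 100:.1f}%  (unchanged)\n")

print("Terminal arterioles with ZERO microbubble flux:")
print(f"  BN : {s['zero_mb_terminal_pct_bn']:.1f}%")
print(f"  SHI: {s['zero_mb_terminal_pct_shi']:.1f}%")
print(f"  -> terminals carrying bubbles up {s['pct_increase_terminals_with_mb']:.0f}%\n")

print("Microbubbles resident in the arteriolar tree:")
print(f"  BN : {s['arteriolar_resident_bn']:.1f}   SHI: {s['arteriolar_resident_shi']:.1f}"
      "   (essentially unchanged)\n")

print("Microbubbles resident in the capillary bed (~2.2e4 capillaries):")
print(f"  BN : {s['capillary_resident_bn']:.0f}   SHI: {s['capillary_resident_shi']:.0f}"
      f"   (+{s['capillary_resident_pct_increase']:.0f}%)\n")

print("Reduced bifurcation asymmetry spreads bubbles into slower, previously")
print("bubble-free flow paths; their longer transit times raise the number of")
print("bubbles resident in capillaries — an increased contrast-ultrasound signal")
print("with no de novo capillary recruitment.")
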