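"""Simulate a paired clamp study and recover the programmed effects.

Generates a synthetic intravital dataset shaped like a euglycemic
hyperinsulinemic clamp experiment (8 animals x 10 fields x 3 capillaries,
measured at baseline and during the clamp), pushes it through the full
derivation pipeline, and runs the study-level statistics.
"""

from capnet.ivvm import derive_velocities_and_flows, derived_to_frame, group_stats
from capnet.synth import StudyConfig, generate_study

cfg = StudyConfig(rng_seed=7)
ds = generate_study(cfg)
print(f"Generated {len(ds.baseline)} capillaries x 2 conditions "
      f"({cfg.n_animals} animals x {cfg.fields_per_animal} fields)")
print(f"Programmed effects: velocity x{cfg.velocity_multiplier_mean}, "
      f"RBC flow x{cfg.rbc_flow_multiplier_mean} with negative flow dependence\n")

perfused = set(ds.ground_truth.loc[ds.ground_truth.flow_class != "stopped", "capillary_id"])
derived = derived_to_frame([derive_velocities_and_flows(r)
                            for r in ds.baseline + ds.clamp
                            if r.capillary_id in perfused])
stats = group_stats(derived)

for var, label in (("mean_velocity_mm_s", "RBC velocity"),
                   ("q_rbc_pl_s", "RBC flow"),
                   ("q_plasma_pl_s", "plasma flow"),
                   ("tube_hct", "tube hematocrit")):
    r = stats["paired_t"][var]
    print(f"{label:16s}: {r['mean_baseline']:.3f} -> {r['mean_clamp']:.3f}  "
          f"(x{r['mean_clamp'] / r['mean_baseline']:.2f}, paired t = {r['t']:.1f}, "
          f"p = {r['p']:.1e})")

reg = stats["rbc_flow_pct_change_regression"]
print(f"\n%change in RBC flow vs baseline flow: slope = {reg['slope']:.0f} %/(pL/s), "
      f"p = {reg['slope_p']:.1e}, r^2 = {reg['r2']:.2f}")
reg_p = stats["plasma_flow_pct_change_regression"]
print(f"%change in plasma flow vs baseline  : slope = {reg_p['slope']:.0f} %/(pL/s), "
      f"r^2 = {reg_p['r2']:.2f} (no dependence programmed; an order of magnitude "
      "weaker than the RBC-flow slope)")
print("\nLow-flow capillaries gain the most RBC flow (negative slope): the")
print("programmed redistribution is recovered by the derivation + statistics chain.")
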