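"""From intravital measurements to capillary hemodynamics.

Takes one capillary's directly measurable quantities — frame-wise RBC
velocity and lineal density, diameter — and derives everything else:
hematocrits, blood and plasma velocities, and volumetric flows.
"""

import numpy as np

from capnet.ivvm import CapillaryRecord, derive_velocities_and_flows

rng = np.random.default_rng(0)
n_frames = 630                                     # 30 s at 21 frames/s
rec = CapillaryRecord(
    capillary_id="demo", animal_id="rat1", condition="baseline",
    velocity_mm_s=0.15 * (1 + 0.05 * rng.standard_normal(n_frames)),
    lineal_density_per_mm=40.0 * (1 + 0.05 * rng.standard_normal(n_frames)),
    diameter_um=5.0, segment_length_um=150.0,
    motion_trace_mm_s=np.full(n_frames, 0.15),
)
d = derive_velocities_and_flows(rec)

print("Measured (frame-averaged):")
print(f"  RBC velocity     : {d.mean_velocity_mm_s:.3f} mm/s")
print(f"  RBC supply rate  : {d.supply_rate_rbc_s:.2f} RBC/s")
print(f"  diameter         : {rec.diameter_um:.1f} um\n")
print("Derived:")
print(f"  tube hematocrit     : {100 * d.tube_hct:.1f}%   (lineal density x 65 um^3 / lumen)")
print(f"  discharge hematocrit: {100 * d.discharge_hct:.1f}%   (Fahraeus inversion)")
print(f"  blood velocity      : {d.blood_velocity_mm_s:.3f} mm/s")
print(f"  plasma velocity     : {d.plasma_velocity_mm_s:.3f} mm/s")
print(f"  Q_RBC / Q_plasma / Q_blood: "
      f"{d.q_rbc_pl_s:.2f} / {d.q_plasma_pl_s:.2f} / {d.q_blood_pl_s:.2f} pL/s")
print(f"  flow class          : {d.flow_class}\n")
print("RBCs travel faster than plasma (Fahraeus), so despite a capillary")
print(f"hematocrit of only {100 * d.tube_hct:.0f}%, plasma flow is "
      f"{d.q_plasma_pl_s / d.q_rbc_pl_s:.1f}x the RBC flow.")
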