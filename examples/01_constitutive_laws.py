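"""Empirical microvascular rheology: viscosity, Fahraeus effect, phase separation.

Evaluates the three constitutive laws at physiological operating points and
prints what each number means for flow in a small arteriole.
"""

from capnet.rheology import discharge_hct, rbc_split, relative_viscosity, tube_hct

D_root, D_term, HD = 75.0, 11.0, 0.42

print("In vivo relative viscosity (plasma = 1):")
for D in (D_root, 30.0, D_term):
    print(f"  D = {D:5.1f} um, HD = {HD}: eta_rel = {relative_viscosity(D, HD):.3f}")
print("Smaller vessels see markedly lower apparent viscosity (Fahraeus-Lindqvist).\n")

ht_root, ht_term = tube_hct(D_root, HD), tube_hct(D_term, HD)
print(f"Fahraeus effect at inlet discharge hematocrit {HD}:")
print(f"  tube hct in the {D_root:.0f} um inlet arteriole : {100 * ht_root:.1f}%")
print(f"  tube hct in an {D_term:.0f} um terminal arteriole: {100 * ht_term:.1f}%")
print("RBCs travel faster than bulk blood, so the hematocrit you would see in")
print("the vessel is below the hematocrit of the blood it delivers.\n")

hd_back = discharge_hct(D_term, ht_term)
print(f"Inverting the relation: tube hct {100 * ht_term:.1f}% at {D_term:.0f} um "
      f"-> discharge hct {100 * hd_back:.1f}% (round trip).\n")

print("RBC phase separation at a diverging 20 um bifurcation (equal daughters):")
for fqb in (0.30, 0.45, 0.50, 0.55, 0.70):
    fqe = rbc_split(fqb, 20.0, 15.0, 15.0, HD)
    print(f"  daughter takes {100 * fqb:4.0f}% of blood -> {100 * fqe:5.1f}% of RBCs")
print("The branch with more flow is over-supplied with RBCs (plasma skimming).")
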