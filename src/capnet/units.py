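"""Unit conversions used across the flow model.

Internal solver units: pressure Pa, length m, viscosity Pa*s, flow m^3/s.
Reported units: pressure mm Hg, diameter/length um, flow nL/s (arterioles)
or pL/s (capillaries), velocity mm/s.
"""

MMHG_TO_PA = 133.322387415
UM_TO_M = 1e-6
M3_S_TO_NL_S = 1e12          # 1 m^3/s = 1e12 nL/s
M3_S_TO_PL_S = 1e15
M_S_TO_MM_S = 1e3
NL_S_TO_PL_S = 1e3
RBC_VOLUME_UM3 = 65.0        # mean rat RBC volume
UM3_TO_PL = 1e-3             # 1 pL = 1000 um^3
UM3_TO_NL = 1e-6
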