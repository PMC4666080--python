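"""Sedimentation coefficient of 5S rRNA from the Svedberg relation.

s / D_t = M (1 - v_bar rho) / (R T): with the predicted translational
diffusion coefficient, a molecular weight of 40 kDa, partial specific
volume 0.53 cm^3/g and water density, the 5S rRNA sediments at ~5 S —
the "5S" in its name.
"""

import rnabd as rb

D_t = 6.2e-7      # cm^2/s, BD prediction for 5S rRNA
M = 40_000.0      # Da
v_bar = 0.53      # cm^3/g
rho = 1.0         # g/cm^3
s = rb.svedberg(D_t, M, v_bar, rho, T=293.0)
print(f"D_t = {D_t * 1e7:.1f} x 1e-7 cm^2/s, M = {M:.0f} Da, "
      f"v_bar = {v_bar} cm^3/g")
print(f"s = {s:.2f} S  (rounds to {round(s)} S)")
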