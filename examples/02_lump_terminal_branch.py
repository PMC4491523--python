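"""Lump a terminal 1D vessel into an equivalent two-element windkessel.

Computes the profile integrals K1, K2, K3 of a tapered vessel, its lumped
resistance R_v and compliance C_v, and collapses vessel + R1-C-R2 outlet
into a single C-R model that preserves the branch's net resistance and
effective compliance.  Also prints the transit-time diagnostic that tells
you whether the lumping assumption (transit time << cardiac period) holds.
"""

import pulsereduce as pr
from pulsereduce.network import ArterialSegment, GlobalParams, Windkessel3

g = GlobalParams()
seg = ArterialSegment.from_pwv("radial", length=0.22, radius_in=1.8e-3,
                               radius_out=1.6e-3, pwv_in=7.5, pwv_out=8.5,
                               rho=g.rho)
wk = Windkessel3(R1=float(seg.char_impedance(seg.length, g.rho)),
                 R2=3e9, C=2e-10, p_out=0.0)

ints = pr.vessel_integrals(seg, g.rho)
rc = pr.vessel_rc(seg, g)
print(f"K1 = {ints.K1:.4e} m s^2   K2 = {ints.K2:.4e} 1/m   "
      f"K3 = {ints.K3:.4e} 1/m^3")
print(f"vessel resistance R_v = {rc.R_v:.4e} Pa s/m^3, "
      f"compliance C_v = {rc.C_v:.4e} m^3/Pa")

lump = pr.lump_terminal(seg, wk, g)
print(f"lumped branch: R_new = {lump.R:.4e} Pa s/m^3 "
      f"(= R2 + R1 + R_v), C_new = {lump.C:.4e} m^3/Pa")

diag = pr.reduction_validity(seg, wk, period=1.0, g=g)
print(f"transit-time ratio {diag.transit_ratio:.4f} "
      f"({'flagged' if diag.flagged else 'within the lumping regime'})")
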