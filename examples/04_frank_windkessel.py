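"""Frank's two-element windkessel of the whole arterial system.

Reduces a branched tree to a single C-R windkessel whose resistance and
compliance equal the net peripheral resistance and total compliance, then
integrates it against a half-sinusoid ejection.  The printed time constant
R C governs the exponential pressure decay in diastole — the feature this
classical model captures well (it cannot reproduce systolic wave shapes,
which require wave propagation).
"""

import numpy as np

import pulsereduce as pr

MMHG = 133.322

net = pr.make_tree(pr.FixtureSpec(kind="symmetric-tree", generations=3, seed=7,
                                  jitter=0.05))
inflow = pr.make_inflow(period=1.0, stroke_volume=70e-6, systolic_fraction=0.3)

wk = pr.reduce_to_windkessel(net)
print(f"whole-system windkessel: R = {wk.R:.4e} Pa s/m^3, "
      f"C = {wk.C:.4e} m^3/Pa, tau = R C = {wk.R * wk.C:.2f} s")

resp = pr.frank_whole_system(net, inflow, n_cycles=12)
p = resp.pressure / MMHG
print(f"aortic-root pressure (0D): systolic {p.max():.1f} mmHg, "
      f"diastolic {p.min():.1f} mmHg")

# verify the diastolic decay constant from the waveform itself
mask = (resp.time > 0.4) & (resp.time < 0.95)
slope = np.polyfit(resp.time[mask], np.log(resp.pressure[mask]), 1)[0]
print(f"fitted diastolic time constant {-1.0 / slope:.2f} s "
      f"(expected {wk.R * wk.C:.2f} s)")
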