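"""Compare complete and reduced 1D models at the waveform level.

Runs a three-generation tree to a periodic state, lumps its deepest
generation into windkessels, re-simulates, and prints the six relative
error metrics at the root: average/systolic/diastolic errors in pressure
and flow.  Small pressure errors (< 2%) show that peripheral branches
with short transit times can be lumped without distorting central
waveforms.
"""

import pulsereduce as pr
from pulsereduce.solver import Probe, SolverSettings, simulate

net = pr.make_tree(pr.FixtureSpec(kind="symmetric-tree", generations=3, seed=7,
                                  jitter=0.05))
reduced = pr.trim_generation(net)
print(f"complete model: {len(net.segments)} segments "
      f"({pr.count_parameters(net)} parameters)")
print(f"reduced model:  {len(reduced.segments)} segments "
      f"({pr.count_parameters(reduced)} parameters)")

inflow = pr.make_inflow(period=1.0, stroke_volume=70e-6, systolic_fraction=0.3)
settings = SolverSettings(max_cycles=20, periodicity_tol=3e-4,
                          initial_pressure=pr.reduce_to_windkessel(net).R
                          * inflow.mean_flow())
probes = [Probe(net.root, 0.0, "root")]

complete = simulate(net, inflow, settings, probes)
trimmed = simulate(reduced, inflow, settings, probes)

report = pr.error_report(complete, trimmed, "root")
print("root-site errors (reduced vs complete):")
print(" ", report)
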