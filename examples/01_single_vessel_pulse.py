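"""Simulate one heartbeat in a single compliant vessel.

Builds a 10 cm aorta-like vessel terminated by a three-element windkessel,
drives it with a 70 mL half-sinusoid ejection at 60 bpm, runs the 1D
solver to a periodic state and prints the systolic / diastolic / mean
pressure at the inlet.  The mean pressure is set by the net resistance
times the mean inflow; the pulse pressure reflects the compliance and the
outlet reflection.
"""

import pulsereduce as pr
from pulsereduce.solver import Probe, SolverSettings, simulate

MMHG = 133.322

net = pr.make_tree(pr.FixtureSpec(kind="single-vessel"))
inflow = pr.make_inflow(period=1.0, stroke_volume=70e-6, systolic_fraction=0.3)

wk = pr.reduce_to_windkessel(net)
settings = SolverSettings(max_cycles=16, periodicity_tol=5e-4,
                          initial_pressure=wk.R * inflow.mean_flow())
waves = simulate(net, inflow, settings,
                 probes=[Probe("vessel", 0.0, "inlet")])

P = waves.sites["inlet"]["P"] / MMHG
print(f"converged after {waves.cycles_run} cycles "
      f"(residual {waves.periodicity_residual:.1e})")
print(f"inlet pressure: systolic {P.max():.1f} mmHg, "
      f"diastolic {P.min():.1f} mmHg, mean {P.mean():.1f} mmHg")
print(f"net resistance {wk.R:.3e} Pa s/m^3 x mean inflow "
      f"{inflow.mean_flow() * 1e6:.1f} mL/s = "
      f"{wk.R * inflow.mean_flow() / MMHG:.1f} mmHg expected mean")
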