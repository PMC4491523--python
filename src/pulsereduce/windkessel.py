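"""Stand-alone 0D windkessel dynamics.

The two-element (C-R) windkessel relates inlet pressure and flow through

    q_in = (p_in - p_out) / R + C dp_in/dt,

Frank's classical model of the whole arterial system.  The three-element
variant adds a proximal resistance R1 in series with the C-R2 pair; its
state is the capacitor pressure p_c with

    p = p_c + R1 q,        C dp_c/dt = q - (p_c - p_out) / R2,

which is algebraically equivalent to the usual single-ODE form and keeps
the instantaneous resistive jump ``R1 dq`` exact for discontinuous flows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .network import ArterialNetwork, InflowWaveform, Windkessel3

__all__ = ["LumpedResponse", "wk2_response", "wk3_response", "frank_whole_system"]


@dataclass
class LumpedResponse:
    """Time series produced by a lumped model."""

    time: np.ndarray
    pressure: np.ndarray   # pressure at the model inlet (Pa)
    flow_out: np.ndarray   # flow leaving through the distal resistance (m^3/s)


def _as_flow_callable(q) -> Callable[[float], float]:
    if isinstance(q, InflowWaveform):
        return lambda t: float(q(t))
    if callable(q):
        return lambda t: float(q(t))
    raise TypeError("flow must be an InflowWaveform or a callable q(t)")


def _integrate(rhs, p0: float, t_end: float, n_out: int):
    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(rhs, (0.0, t_end), [p0], method="RK45",
                    rtol=1e-10, atol=1e-10, t_eval=t_eval, max_step=t_end / 50)
    if not sol.success:  # pragma: no cover - mild linear ODE
        raise RuntimeError(f"windkessel integration failed: {sol.message}")
    return t_eval, sol.y[0]


def wk2_response(q_in, R: float, C: float, p_out: float = 0.0,
                 p0: Optional[float] = None, t_end: Optional[float] = None,
                 n_out: int = 1024) -> LumpedResponse:
    """Integrate the two-element windkessel driven by an inlet flow.

    Parameters
    ----------
    q_in : InflowWaveform or callable ``q(t)`` in m^3/s.
    R, C : peripheral resistance (Pa s/m^3) and compliance (m^3/Pa).
    p0 : initial inlet pressure; defaults to ``p_out + R * mean(q_in)``
        for fast periodic convergence (mean of a waveform, else q(0)).
    t_end : integration horizon; defaults to one waveform period.
    """
    if R <= 0 or C <= 0:
        raise ValueError("R and C must be positive")
    qf = _as_flow_callable(q_in)
    if t_end is None:
        if not isinstance(q_in, InflowWaveform):
            raise ValueError("t_end is required for a bare callable flow")
        t_end = q_in.period
    if p0 is None:
        qm = q_in.mean_flow() if isinstance(q_in, InflowWaveform) else qf(0.0)
        p0 = p_out + R * qm

    def rhs(t, y):
        return [(qf(t) - (y[0] - p_out) / R) / C]

    t, p = _integrate(rhs, p0, t_end, n_out)
    return LumpedResponse(time=t, pressure=p, flow_out=(p - p_out) / R)


def wk3_response(q_out, wk: Windkessel3, p0: Optional[float] = None,
                 t_end: Optional[float] = None, n_out: int = 1024) -> LumpedResponse:
    """Integrate the three-element windkessel driven by its inlet flow.

    ``q_out`` is the flow entering the windkessel (i.e. leaving the 1D
    domain).  The returned ``pressure`` is the pressure at the windkessel
    inlet, ``p = p_c + R1 q``; ``flow_out`` is the flow through R2.
    ``p0`` initialises the *capacitor* pressure (defaults analogous to
    :func:`wk2_response`).
    """
    qf = _as_flow_callable(q_out)
    if t_end is None:
        if not isinstance(q_out, InflowWaveform):
            raise ValueError("t_end is required for a bare callable flow")
        t_end = q_out.period
    if p0 is None:
        qm = q_out.mean_flow() if isinstance(q_out, InflowWaveform) else qf(0.0)
        p0 = wk.p_out + wk.R2 * qm

    def rhs(t, y):
        return [(qf(t) - (y[0] - wk.p_out) / wk.R2) / wk.C]

    t, pc = _integrate(rhs, p0, t_end, n_out)
    q = np.array([qf(tt) for tt in t])
    return LumpedResponse(time=t, pressure=pc + wk.R1 * q,
                          flow_out=(pc - wk.p_out) / wk.R2)


def frank_whole_system(network: ArterialNetwork, inflow: InflowWaveform,
                       n_cycles: int = 10, n_out: int = 1024) -> LumpedResponse:
    """Frank-model response of a whole network.

    Reduces the network to a single two-element windkessel whose resistance
    and compliance equal the net peripheral resistance and total effective
    compliance, then integrates it against the inflow for ``n_cycles``
    cardiac cycles and returns the final cycle.
    """
    from .reduction import reduce_to_windkessel

    wk = reduce_to_windkessel(network)
    t_end = n_cycles * inflow.period
    # cycle-aligned grid: the final period spans exactly n_out + 1 samples
    resp = wk2_response(inflow, wk.R, wk.C, p_out=wk.p_out,
                        t_end=t_end, n_out=n_out * n_cycles + 1)
    keep = resp.time >= (n_cycles - 1) * inflow.period - 1e-12
    return LumpedResponse(time=resp.time[keep] - (n_cycles - 1) * inflow.period,
                          pressure=resp.pressure[keep],
                          flow_out=resp.flow_out[keep])
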