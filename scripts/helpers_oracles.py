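"""Independent oracles and generators used by the acceptance script."""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from pulsereduce.network import (
    ArterialNetwork,
    ArterialSegment,
    GlobalParams,
    Windkessel3,
)
from pulsereduce.reduction import vessel_rc


def circuit_input_resistance(net: ArterialNetwork) -> float:
    """Input resistance of the network's DC resistor analogue.

    Independent of the series/parallel reduction: builds the nodal
    conductance (Laplacian) matrix of the resistor network — one node at
    the inlet and one at each segment's distal end, every terminal tied to
    ground through R1 + R2 — injects a unit current at the inlet and
    solves for the potentials.
    """
    names = sorted(net.segments)
    node = {"__inlet__": 0}
    for n in names:
        node[n] = len(node)
    N = len(node)
    G = np.zeros((N, N))

    def add_conductance(i, j, g):
        G[i, i] += g
        G[j, j] += g
        G[i, j] -= g
        G[j, i] -= g

    for n in names:
        seg = net.segments[n]
        r_v = vessel_rc(seg, net.globals).R_v
        parent = net.parents[n]
        i = node["__inlet__"] if parent is None else node[parent]
        add_conductance(i, node[n], 1.0 / r_v)
    for n, wk in net.terminals.items():
        # terminal to ground: only the diagonal entry survives
        G[node[n], node[n]] += 1.0 / (wk.R1 + wk.R2)
    rhs = np.zeros(N)
    rhs[0] = 1.0
    p = np.linalg.solve(G, rhs)
    return float(p[0])


def rc_chain_response(seg: ArterialSegment, wk: Windkessel3, qfunc, period: float,
                      g: GlobalParams, n_comp: int = 200, n_periods: int = 10,
                      n_out: int = 512):
    """Inlet pressure of a linearized distributed (RC-chain) terminal branch.

    Discretises the vessel into ``n_comp`` compartments with compliance
    ``A_d / (rho c_d^2) dx`` and series resistance from the local
    Poiseuille-type friction law, terminated by the R1-C-R2 windkessel,
    and integrates the linear ODE system to a periodic state.  This is the
    inertia-free distributed model that terminal lumping approximates.
    """
    rho, kf = g.rho, g.friction_coefficient
    dx = seg.length / n_comp
    xc = (np.arange(n_comp) + 0.5) * dx
    Ad = seg.area_d(xc)
    cd = seg.wave_speed_d(xc, rho)
    Cc = Ad / (rho * cd ** 2) * dx
    rr = kf / Ad ** 2  # resistance per unit length
    Rint = 0.5 * dx * (rr[:-1] + rr[1:])
    N = n_comp
    M = np.zeros((N + 1, N + 1))
    for i in range(N):
        if i > 0:
            M[i, i - 1] += 1 / (Rint[i - 1] * Cc[i])
            M[i, i] -= 1 / (Rint[i - 1] * Cc[i])
        if i < N - 1:
            M[i, i + 1] += 1 / (Rint[i] * Cc[i])
            M[i, i] -= 1 / (Rint[i] * Cc[i])
    r_end = 0.5 * dx * rr[-1] + wk.R1
    M[N - 1, N] += 1 / (r_end * Cc[N - 1])
    M[N - 1, N - 1] -= 1 / (r_end * Cc[N - 1])
    M[N, N - 1] += 1 / (r_end * wk.C)
    M[N, N] -= 1 / (r_end * wk.C) + 1 / (wk.R2 * wk.C)
    b = np.zeros(N + 1)
    b[N] = wk.p_out / (wk.R2 * wk.C)
    e0 = np.zeros(N + 1)
    e0[0] = 1 / Cc[0]

    def rhs(t, y):
        return M @ y + b + e0 * qfunc(t)

    q_mean = np.mean([qfunc(t) for t in np.linspace(0.0, period, 400)])
    y0 = np.full(N + 1, wk.p_out + (wk.R1 + wk.R2) * q_mean)
    t_eval = np.linspace((n_periods - 1) * period, n_periods * period, n_out)
    sol = solve_ivp(rhs, (0.0, n_periods * period), y0, method="LSODA",
                    jac=lambda t, y: M, rtol=1e-9, atol=1e-6, t_eval=t_eval)
    assert sol.success
    return sol.t - (n_periods - 1) * period, sol.y[0]


def random_tree(rng: np.random.Generator, max_generations: int = 4,
                g: GlobalParams | None = None) -> ArterialNetwork:
    """A random rooted vessel tree with random terminal windkessels."""
    g = g or GlobalParams()
    segments, parents, terminals = {}, {}, {}
    counter = [0]

    def grow(parent, depth, radius):
        name = f"s{counter[0]}"
        counter[0] += 1
        length = rng.uniform(0.02, 0.3)
        r_out = radius * rng.uniform(0.8, 0.98)
        c_in = rng.uniform(4.0, 12.0)
        seg = ArterialSegment.from_pwv(name, length, radius, r_out,
                                       c_in, c_in * rng.uniform(1.0, 1.1),
                                       rho=g.rho)
        segments[name] = seg
        parents[name] = parent
        branch = depth < max_generations and rng.random() < 0.7
        if branch:
            n_kids = 2 if rng.random() < 0.85 else 3
            for _ in range(n_kids):
                grow(name, depth + 1, r_out * rng.uniform(0.6, 0.85))
        else:
            terminals[name] = Windkessel3(
                R1=float(rng.uniform(0.0, 2e8)),
                R2=float(rng.uniform(1e8, 5e9)),
                C=float(rng.uniform(1e-10, 1e-8)),
                p_out=0.0,
            )

    grow(None, 0, rng.uniform(0.004, 0.012))
    return ArterialNetwork(segments=segments, parents=parents,
                           terminals=terminals, globals=g)
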