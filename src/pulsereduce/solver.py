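"""Time-domain solver for nonlinear 1D blood flow on a vessel network.

The governing equations per segment are conservation of mass and momentum
for an impermeable compliant tube,

    dA/dt + d(AU)/dx = 0
    dU/dt + d(U^2/2 + P/rho)/dx = f / (rho A),

closed by the elastic tube law and with wall friction
``f = -2 (xi + 2) pi mu U``.  The scheme is a second-order MUSCL finite
volume method with local Lax-Friedrichs (Rusanov) fluxes and two-stage
SSP Runge-Kutta time stepping.  Slopes are reconstructed in pressure and
velocity and converted to area with the *interface* diastolic properties,
which makes the constant-pressure rest state an exact discrete
equilibrium even on tapered vessels.

Boundaries are coupled through Riemann invariants ``W± = U ± 4 (c - c_d)``:
the inlet enforces the prescribed flow (a reflective flow-source
condition), junctions enforce conservation of mass and continuity of
total pressure ``P + rho U^2 / 2`` via a Newton solve on the adjacent
characteristic states, and each terminal couples the outgoing
characteristic to its windkessel (capacitor-pressure state advanced
alongside the 1D variables).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .network import (
    ArterialNetwork,
    InflowWaveform,
    Windkessel2,
    Windkessel3,
)

__all__ = [
    "Probe",
    "SolverSettings",
    "WaveformSet",
    "SolverError",
    "ConvergenceWarning",
    "friction_force",
    "simulate",
]


class SolverError(RuntimeError):
    """Numerical failure (CFL violation, non-finite state, Newton stall)."""


class ConvergenceWarning(UserWarning):
    """Periodicity was not reached within the cycle budget."""


def friction_force(U, mu: float, xi: int):
    """Wall frictional force per unit length, ``f = -2 (xi + 2) pi mu U``."""
    out = -2.0 * (xi + 2) * math.pi * mu * np.asarray(U, float)
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class Probe:
    """A sampling site: segment name plus fractional axial position."""

    segment: str
    position: float = 0.0  # fraction of segment length in [0, 1]
    name: Optional[str] = None

    @property
    def label(self) -> str:
        return self.name or f"{self.segment}@{self.position:g}"


@dataclass
class SolverSettings:
    """Numerical settings for :func:`simulate`.

    ``dx`` is the target cell size (m); each segment gets at least
    ``min_cells`` cells.  The time step is fixed from the diastolic wave
    speeds with safety margin and re-checked against the instantaneous
    CFL condition every step.  ``initial_pressure`` sets the uniform
    starting pressure (the classical cold start is 0); cycles are run
    until the cycle-to-cycle relative change of probe pressures drops
    below ``periodicity_tol`` or ``max_cycles`` is exhausted.
    """

    dx: float = 0.01
    min_cells: int = 4
    cfl: float = 0.5
    max_cycles: int = 20
    periodicity_tol: float = 1e-3
    n_output: int = 1024
    initial_pressure: float = 0.0
    newton_tol: float = 1e-10
    newton_max_iter: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.cfl <= 1:
            raise ValueError("CFL number must lie in (0, 1]")
        if self.max_cycles < 1 or self.periodicity_tol <= 0:
            raise ValueError("max_cycles >= 1 and periodicity_tol > 0 required")


@dataclass
class WaveformSet:
    """Final-cycle probe waveforms on a uniform time grid."""

    time: np.ndarray
    sites: Dict[str, Dict[str, np.ndarray]]
    converged: bool = True
    cycles_run: int = 0
    periodicity_residual: float = 0.0
    diagnostics: Dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# discretisation
# ---------------------------------------------------------------------------

class _Grid:
    """Flat cell/face layout for all segments of a network."""

    def __init__(self, net: ArterialNetwork, settings: SolverSettings):
        g = net.globals
        self.net = net
        self.rho = g.rho
        self.P_d = g.diastolic_pressure
        self.k_fric = g.friction_coefficient
        self.names = sorted(net.segments)
        self.seg_index = {n: i for i, n in enumerate(self.names)}

        n_cells, dx_s = [], []
        for n in self.names:
            seg = net.segments[n]
            m = max(settings.min_cells, int(round(seg.length / settings.dx)))
            n_cells.append(m)
            dx_s.append(seg.length / m)
        self.n_cells = np.array(n_cells)
        self.cell_start = np.concatenate([[0], np.cumsum(self.n_cells)])
        self.N = int(self.cell_start[-1])
        self.S = len(self.names)
        self.face_start = self.cell_start[:-1] + np.arange(self.S)

        # per-cell geometry
        dx = np.empty(self.N)
        Ad_c = np.empty(self.N)
        beta_c = np.empty(self.N)
        seg_of_cell = np.empty(self.N, dtype=int)
        for i, n in enumerate(self.names):
            seg = net.segments[n]
            s0, s1 = self.cell_start[i], self.cell_start[i + 1]
            xc = (np.arange(self.n_cells[i]) + 0.5) * dx_s[i]
            dx[s0:s1] = dx_s[i]
            Ad_c[s0:s1] = seg.area_d(xc)
            beta_c[s0:s1] = seg.beta(xc)
            seg_of_cell[s0:s1] = i
        self.dx = dx
        self.Ad_c = Ad_c
        self.beta_c = beta_c
        self.gamma_c = np.sqrt(beta_c / (2.0 * self.rho * Ad_c))
        self.cd_c = self.gamma_c * Ad_c ** 0.25
        self.lface = np.arange(self.N) + seg_of_cell  # left face of each cell

        # per-face geometry (faces are segment-contiguous, n_s + 1 each)
        NF = self.N + self.S
        Ad_f = np.empty(NF)
        beta_f = np.empty(NF)
        for i, n in enumerate(self.names):
            seg = net.segments[n]
            f0 = self.face_start[i]
            xf = np.arange(self.n_cells[i] + 1) * dx_s[i]
            Ad_f[f0:f0 + self.n_cells[i] + 1] = seg.area_d(xf)
            beta_f[f0:f0 + self.n_cells[i] + 1] = seg.beta(xf)
        self.Ad_f = Ad_f
        self.beta_f = beta_f
        self.gamma_f = np.sqrt(beta_f / (2.0 * self.rho * Ad_f))
        self.cd_f = self.gamma_f * Ad_f ** 0.25

        # interior faces and their neighbour cells
        int_faces, int_L = [], []
        for i in range(self.S):
            f0, c0, m = self.face_start[i], self.cell_start[i], self.n_cells[i]
            int_faces.append(np.arange(f0 + 1, f0 + m))
            int_L.append(np.arange(c0, c0 + m - 1))
        self.int_faces = np.concatenate(int_faces).astype(int)
        self.int_L = np.concatenate(int_L).astype(int)
        self.int_R = self.int_L + 1

        # first/last cell and inlet/outlet face of each segment
        self.first_cell = self.cell_start[:-1]
        self.last_cell = self.cell_start[1:] - 1
        self.inlet_face = self.face_start
        self.outlet_face = self.face_start + self.n_cells

        # boundary bookkeeping
        self.root = self.seg_index[net.root]
        leaves = net.leaves
        self.leaf_idx = np.array([self.seg_index[n] for n in leaves], dtype=int)
        R1, R2, C, p_out = [], [], [], []
        for n in leaves:
            wk = net.terminals[n]
            if isinstance(wk, Windkessel3):
                R1.append(wk.R1), R2.append(wk.R2), C.append(wk.C)
                p_out.append(wk.p_out)
            elif isinstance(wk, Windkessel2):
                R1.append(0.0), R2.append(wk.R), C.append(wk.C)
                p_out.append(wk.p_out)
            else:  # pragma: no cover
                raise SolverError(f"unsupported terminal model on '{n}'")
        self.wk_R1 = np.array(R1)
        self.wk_R2 = np.array(R2)
        self.wk_C = np.array(C)
        self.wk_p_out = np.array(p_out)
        # filled in by simulate() once dt is fixed
        self.wk_stiff = np.zeros(len(R1), dtype=bool)

        # junction groups by child count
        groups: Dict[int, List[Tuple[int, List[int]]]] = {}
        for n in self.names:
            kids = net.children_of(n)
            if kids:
                groups.setdefault(len(kids), []).append(
                    (self.seg_index[n], [self.seg_index[k] for k in kids]))
        self.junction_groups = {
            k: (np.array([p for p, _ in v], dtype=int),
                np.array([c for _, c in v], dtype=int))
            for k, v in groups.items()
        }

    # -- tube law on cells ---------------------------------------------
    def pressure(self, A: np.ndarray) -> np.ndarray:
        return self.P_d + self.beta_c / self.Ad_c * (np.sqrt(A) - np.sqrt(self.Ad_c))

    def area_at_faces(self, p, faces) -> np.ndarray:
        Ad, beta = self.Ad_f[faces], self.beta_f[faces]
        root = np.sqrt(Ad) + (p - self.P_d) * Ad / beta
        return root * root

    def pressure_at_faces(self, A, faces) -> np.ndarray:
        Ad, beta = self.Ad_f[faces], self.beta_f[faces]
        return self.P_d + beta / Ad * (np.sqrt(A) - np.sqrt(Ad))


def _mc_slopes(v: np.ndarray, grid: _Grid) -> np.ndarray:
    """Monotonised-central limited slopes; one-sided at segment-edge cells."""
    dL = np.zeros_like(v)
    dL[1:] = v[1:] - v[:-1]
    dR = np.zeros_like(v)
    dR[:-1] = v[1:] - v[:-1]
    # single-cell segments have no usable difference at all
    single = grid.first_cell[grid.n_cells == 1]
    dL[grid.first_cell] = dR[grid.first_cell]
    dR[grid.last_cell] = dL[grid.last_cell]
    dL[single] = 0.0
    dR[single] = 0.0
    prod = dL * dR
    mag = np.minimum(np.abs(dL + dR) * 0.5, 2.0 * np.minimum(np.abs(dL), np.abs(dR)))
    return np.where(prod > 0.0, np.sign(dL) * mag, 0.0)


# ---------------------------------------------------------------------------
# boundary solves
# ---------------------------------------------------------------------------

def _solve_inlet(grid: _Grid, q_target: float, p_face: float, u_face: float,
                 settings: SolverSettings, t: float):
    """Flow-source inlet: match the prescribed flow against the backward
    characteristic leaving the domain."""
    f = grid.inlet_face[grid.root]
    gam, cd, Ad = grid.gamma_f[f], grid.cd_f[f], grid.Ad_f[f]
    A_face = grid.area_at_faces(np.array([p_face]), np.array([f]))[0]
    W = u_face - 4.0 * (gam * A_face ** 0.25 - cd)
    A = A_face
    for _ in range(settings.newton_max_iter):
        c = gam * A ** 0.25
        U = W + 4.0 * (c - cd)
        h = A * U - q_target
        dh = U + c
        step = h / dh
        A_new = A - step
        if A_new <= 0:
            A_new = 0.5 * A
        if abs(A_new - A) < 1e-14 * Ad + 1e-30:
            A = A_new
            break
        A = A_new
    else:
        raise SolverError(f"inlet Newton failed to converge at t={t:.6f}")
    c = gam * A ** 0.25
    U = W + 4.0 * (c - cd)
    return A, U


def _solve_terminals(grid: _Grid, p_face, u_face, p_c, settings, t):
    """Couple each leaf's forward characteristic to its windkessel.

    Terminals whose capacitor time constant ``R2 C`` is too short to
    resolve with the explicit step are treated as quasi-steady (purely
    resistive ``R1 + R2``) outlets; this includes the exact ``C -> 0``
    limit.
    """
    faces = grid.outlet_face[grid.leaf_idx]
    gam, cd = grid.gamma_f[faces], grid.cd_f[faces]
    Ad, beta = grid.Ad_f[faces], grid.beta_f[faces]
    A_face = grid.area_at_faces(p_face, faces)
    W = u_face + 4.0 * (gam * A_face ** 0.25 - cd)
    stiff = grid.wk_stiff
    R1 = np.where(stiff, grid.wk_R1 + grid.wk_R2, grid.wk_R1)
    p_ref = np.where(stiff, grid.wk_p_out, p_c)
    rho = grid.rho
    A = A_face.copy()
    for _ in range(settings.newton_max_iter):
        c = gam * A ** 0.25
        U = W - 4.0 * (c - cd)
        P = grid.P_d + beta / Ad * (np.sqrt(A) - np.sqrt(Ad))
        g = P - p_ref - R1 * A * U
        dg = rho * c * c / A - R1 * (U - c)
        step = g / dg
        A_new = A - step
        bad = A_new <= 0
        if np.any(bad):
            A_new[bad] = 0.5 * A[bad]
        if np.max(np.abs(A_new - A) / Ad) < 1e-13:
            A = A_new
            break
        A = A_new
    else:
        raise SolverError(f"terminal Newton failed to converge at t={t:.6f}")
    c = gam * A ** 0.25
    U = W - 4.0 * (c - cd)
    q = A * U
    dpc = np.where(stiff, 0.0,
                   (q - (p_c - grid.wk_p_out) / grid.wk_R2) / grid.wk_C)
    return A, U, q, dpc


def _solve_junctions(grid: _Grid, n: int, parents, kids,
                     p_plus, p_minus, u_plus, u_minus, settings, t):
    """Batched Newton solve of mass conservation + total-pressure continuity
    for all junctions with ``n`` children."""
    rho = grid.rho
    pf = grid.outlet_face[parents]
    kf = grid.inlet_face[kids]  # (G, n)
    gam_p, cd_p = grid.gamma_f[pf], grid.cd_f[pf]
    Ad_p, beta_p = grid.Ad_f[pf], grid.beta_f[pf]
    gam_k, cd_k = grid.gamma_f[kf], grid.cd_f[kf]
    Ad_k, beta_k = grid.Ad_f[kf], grid.beta_f[kf]

    lc = grid.last_cell[parents]
    fc = grid.first_cell[kids]
    Ap0 = grid.area_at_faces(p_plus[lc], pf)
    Ak0 = grid.area_at_faces(p_minus[fc], kf)
    Wp = u_plus[lc] + 4.0 * (gam_p * Ap0 ** 0.25 - cd_p)
    Wk = u_minus[fc] - 4.0 * (gam_k * Ak0 ** 0.25 - cd_k)

    G = len(parents)
    Ap, Ak = Ap0.copy(), Ak0.copy()
    scale_m = Ad_p * cd_p
    scale_p = rho * cd_p ** 2
    J = np.zeros((G, n + 1, n + 1))
    for _ in range(settings.newton_max_iter):
        cp = gam_p * Ap ** 0.25
        Up = Wp - 4.0 * (cp - cd_p)
        ck = gam_k * Ak ** 0.25
        Uk = Wk + 4.0 * (ck - cd_k)
        Pp = grid.P_d + beta_p / Ad_p * (np.sqrt(Ap) - np.sqrt(Ad_p))
        Pk = grid.P_d + beta_k / Ad_k * (np.sqrt(Ak) - np.sqrt(Ad_k))
        r = np.zeros((G, n + 1))
        r[:, 0] = Ap * Up - np.sum(Ak * Uk, axis=1)
        r[:, 1:] = (Pp + 0.5 * rho * Up ** 2)[:, None] - (Pk + 0.5 * rho * Uk ** 2)
        if (np.max(np.abs(r[:, 0]) / scale_m) < settings.newton_tol
                and np.max(np.abs(r[:, 1:]) / scale_p[:, None]) < settings.newton_tol):
            break
        J[:, 0, 0] = Up - cp
        J[:, 0, 1:] = -(Uk + ck)
        J[:, 1:, 0] = (rho * cp * (cp - Up) / Ap)[:, None]
        diag = -rho * ck * (ck + Uk) / Ak
        J[:, 1:, 1:] = 0.0
        idx = np.arange(n)
        J[:, 1 + idx, 1 + idx] = diag
        dX = np.linalg.solve(J, r[:, :, None])[:, :, 0]
        Ap_new = Ap - dX[:, 0]
        Ak_new = Ak - dX[:, 1:]
        bad = Ap_new <= 0
        Ap_new[bad] = 0.5 * Ap[bad]
        badk = Ak_new <= 0
        Ak_new[badk] = 0.5 * Ak[badk]
        Ap, Ak = Ap_new, Ak_new
    else:
        raise SolverError(
            f"junction Newton ({n}-furcation) failed to converge at t={t:.6f}")
    cp = gam_p * Ap ** 0.25
    Up = Wp - 4.0 * (cp - cd_p)
    ck = gam_k * Ak ** 0.25
    Uk = Wk + 4.0 * (ck - cd_k)
    return (Ap, Up, pf), (Ak, Uk, kf)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def _rhs(grid: _Grid, settings: SolverSettings, inflow, t: float,
         A: np.ndarray, U: np.ndarray, p_c: np.ndarray):
    rho = grid.rho
    if np.any(A <= 0) or not (np.all(np.isfinite(A)) and np.all(np.isfinite(U))):
        bad = int(np.argmin(A)) if np.any(A <= 0) else int(
            np.argmax(~np.isfinite(A + U)))
        seg = grid.names[int(np.searchsorted(grid.cell_start, bad, "right") - 1)]
        raise SolverError(f"non-physical state in segment '{seg}' at t={t:.6f}")

    p = grid.pressure(A)
    sp = _mc_slopes(p, grid)
    su = _mc_slopes(U, grid)

    NF = grid.N + grid.S
    Fm = np.zeros(NF)
    Fu = np.zeros(NF)

    # interior faces
    L, R, faces = grid.int_L, grid.int_R, grid.int_faces
    pL = p[L] + 0.5 * sp[L]
    pR = p[R] - 0.5 * sp[R]
    uL = U[L] + 0.5 * su[L]
    uR = U[R] - 0.5 * su[R]
    A_L = grid.area_at_faces(pL, faces)
    A_R = grid.area_at_faces(pR, faces)
    c_L = grid.gamma_f[faces] * A_L ** 0.25
    c_R = grid.gamma_f[faces] * A_R ** 0.25
    s = np.maximum(np.abs(uL) + c_L, np.abs(uR) + c_R)
    Fm[faces] = 0.5 * (A_L * uL + A_R * uR) - 0.5 * s * (A_R - A_L)
    Fu[faces] = (0.5 * (0.5 * uL ** 2 + pL / rho + 0.5 * uR ** 2 + pR / rho)
                 - 0.5 * s * (uR - uL))

    # inlet (root) — reflective flow source
    q_t = float(inflow(t))
    ri = grid.first_cell[grid.root]
    A_in, U_in = _solve_inlet(grid, q_t, p[ri] - 0.5 * sp[ri],
                              U[ri] - 0.5 * su[ri], settings, t)
    f_in = grid.inlet_face[grid.root]
    P_in = grid.pressure_at_faces(np.array([A_in]), np.array([f_in]))[0]
    Fm[f_in] = A_in * U_in
    Fu[f_in] = 0.5 * U_in ** 2 + P_in / rho

    # junctions
    p_plus = p + 0.5 * sp
    p_minus = p - 0.5 * sp
    u_plus = U + 0.5 * su
    u_minus = U - 0.5 * su
    for n, (parents, kids) in grid.junction_groups.items():
        (Ap, Up, pf), (Ak, Uk, kf) = _solve_junctions(
            grid, n, parents, kids, p_plus, p_minus, u_plus, u_minus,
            settings, t)
        Pp = grid.pressure_at_faces(Ap, pf)
        Fm[pf] = Ap * Up
        Fu[pf] = 0.5 * Up ** 2 + Pp / rho
        Pk = grid.pressure_at_faces(Ak, kf)
        Fm[kf] = Ak * Uk
        Fu[kf] = 0.5 * Uk ** 2 + Pk / rho

    # terminals
    lc = grid.last_cell[grid.leaf_idx]
    A_t, U_t, q_t_out, dpc = _solve_terminals(grid, p_plus[lc], u_plus[lc],
                                              p_c, settings, t)
    tf = grid.outlet_face[grid.leaf_idx]
    P_t = grid.pressure_at_faces(A_t, tf)
    Fm[tf] = q_t_out
    Fu[tf] = 0.5 * U_t ** 2 + P_t / rho

    lf = grid.lface
    dA = -(Fm[lf + 1] - Fm[lf]) / grid.dx
    dU = -(Fu[lf + 1] - Fu[lf]) / grid.dx - grid.k_fric * U / (rho * A)
    return dA, dU, dpc, Fm[f_in], float(np.sum(q_t_out))


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _probe_weights(grid: _Grid, probes: Sequence[Probe]):
    """Linear interpolation weights from cell centres for each probe."""
    out = []
    for pr in probes:
        if pr.segment not in grid.seg_index:
            raise KeyError(f"probe references unknown segment '{pr.segment}'")
        i = grid.seg_index[pr.segment]
        seg = grid.net.segments[pr.segment]
        m = grid.n_cells[i]
        dx = seg.length / m
        x = np.clip(pr.position, 0.0, 1.0) * seg.length
        s = x / dx - 0.5
        if m == 1:
            j0, j1, w1 = 0, 0, 0.0
        else:
            # nearest cell pair, extrapolating linearly at the segment ends
            j0 = int(np.clip(np.floor(s), 0, m - 2))
            j1 = j0 + 1
            w1 = float(s - j0)
        out.append((grid.cell_start[i] + j0, grid.cell_start[i] + j1, 1.0 - w1, w1))
    return out


def simulate(network: ArterialNetwork, inflow: InflowWaveform,
             settings: Optional[SolverSettings] = None,
             probes: Optional[Sequence[Probe]] = None) -> WaveformSet:
    """Run the 1D network simulation to a periodic state.

    Returns the final-cycle waveforms at the probe sites, resampled to a
    uniform grid of ``settings.n_output`` points by monotone cubic
    interpolation.  The result is flagged non-converged (with a warning)
    if the periodicity tolerance is not met within the cycle budget.
    """
    settings = settings or SolverSettings()
    if probes is None:
        probes = [Probe(network.root, 0.0, name="root")]
    grid = _Grid(network, settings)
    rho = grid.rho

    # fixed time step from the diastolic state with margin for systolic
    # stiffening and advection, re-checked against the true CFL each step
    c_ref = grid.cd_c
    dt_max = settings.cfl * float(np.min(grid.dx / (1.6 * c_ref + 1.0)))
    steps = max(int(math.ceil(inflow.period / dt_max)), 16)
    dt = inflow.period / steps
    grid.wk_stiff = grid.wk_R2 * grid.wk_C < 2.5 * dt

    # initial state: uniform pressure (cell-based inversion of the tube law)
    p0 = settings.initial_pressure
    rootA = np.sqrt(grid.Ad_c) + (p0 - grid.P_d) * grid.Ad_c / grid.beta_c
    if np.any(rootA <= 0):
        raise SolverError("initial pressure below tube-law collapse limit")
    A = rootA ** 2
    U = np.zeros(grid.N)
    p_c = np.full(len(grid.leaf_idx), max(p0, 0.0))
    p_c = np.maximum(p_c, grid.wk_p_out)

    pw = _probe_weights(grid, probes)
    labels = [pr.label for pr in probes]
    n_probes = len(probes)

    prev_cycle_P: Optional[np.ndarray] = None
    residual = np.inf
    converged = False
    vol_in = vol_out = 0.0
    rec = np.empty((steps + 1, n_probes, 3))
    t_rec = np.arange(steps + 1) * dt

    def record(k, A, U, p):
        for j, (i0, i1, w0, w1) in enumerate(pw):
            a = w0 * A[i0] + w1 * A[i1]
            u = w0 * U[i0] + w1 * U[i1]
            rec[k, j, 0] = w0 * p[i0] + w1 * p[i1]
            rec[k, j, 1] = a * u
            rec[k, j, 2] = a

    cycles = 0
    for cycle in range(settings.max_cycles):
        vol_in = vol_out = 0.0
        record(0, A, U, grid.pressure(A))
        t0 = 0.0  # time within the (periodic) cycle
        for k in range(steps):
            t = t0 + k * dt
            dA1, dU1, dpc1, qi1, qo1 = _rhs(grid, settings, inflow, t, A, U, p_c)
            A1 = A + dt * dA1
            U1 = U + dt * dU1
            pc1 = p_c + dt * dpc1
            dA2, dU2, dpc2, qi2, qo2 = _rhs(grid, settings, inflow, t + dt,
                                            A1, U1, pc1)
            A = A + 0.5 * dt * (dA1 + dA2)
            U = U + 0.5 * dt * (dU1 + dU2)
            p_c = p_c + 0.5 * dt * (dpc1 + dpc2)
            vol_in += 0.5 * dt * (qi1 + qi2)
            vol_out += 0.5 * dt * (qo1 + qo2)
            # CFL re-check on the updated state
            cmax = grid.gamma_c * A ** 0.25 + np.abs(U)
            nu = dt * float(np.max(cmax / grid.dx))
            if nu > 1.0:
                i = int(np.argmax(cmax / grid.dx))
                seg = grid.names[int(np.searchsorted(grid.cell_start, i, "right") - 1)]
                raise SolverError(
                    f"CFL violation (nu={nu:.3f}) in segment '{seg}' at "
                    f"t={(cycle * steps + k + 1) * dt:.6f}")
            record(k + 1, A, U, grid.pressure(A))
        cycles = cycle + 1
        P_cycle = rec[:, :, 0].copy()
        if prev_cycle_P is not None:
            scale = float(np.max(np.abs(P_cycle)))
            residual = float(np.max(np.abs(P_cycle - prev_cycle_P))) / (scale + 1e-300)
            if residual < settings.periodicity_tol:
                converged = True
                break
        prev_cycle_P = P_cycle

    if not converged:
        warnings.warn(
            f"periodicity not reached in {settings.max_cycles} cycles "
            f"(residual {residual:.3e})", ConvergenceWarning, stacklevel=2)

    # resample the final cycle to the uniform output grid
    from scipy.interpolate import PchipInterpolator

    t_out = np.linspace(0.0, inflow.period, settings.n_output)
    sites: Dict[str, Dict[str, np.ndarray]] = {}
    for j, label in enumerate(labels):
        interp = {key: PchipInterpolator(t_rec, rec[:, j, col])(t_out)
                  for key, col in (("P", 0), ("Q", 1), ("A", 2))}
        sites[label] = interp

    q_in_total = inflow.volume_per_cycle()
    diagnostics = {
        "dt": dt,
        "steps_per_cycle": steps,
        "volume_in": vol_in,
        "volume_out": vol_out,
        "volume_balance": abs(vol_in - vol_out) / (abs(q_in_total) + 1e-300)
        if q_in_total != 0 else abs(vol_in - vol_out),
    }
    return WaveformSet(time=t_out, sites=sites, converged=converged,
                       cycles_run=cycles, periodicity_residual=residual
                       if np.isfinite(residual) else 0.0,
                       diagnostics=diagnostics)
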