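"""Arterial network data model and constitutive relations.

A network is a rooted tree of tapered elastic segments. Each segment is a
deformable cylindrical tube described by its length, a linearly tapered
diastolic radius profile and a linearly varying wall-stiffness profile
``beta(x)``.  The tube law closing the 1D mass/momentum equations is

    P(A; x) = P_d + beta(x)/A_d(x) * (sqrt(A) - sqrt(A_d(x)))

and the corresponding pulse wave velocity is

    c(A; x) = sqrt(beta(x) / (2 rho A_d(x))) * A**(1/4).

Every leaf segment carries a three-element windkessel (R1-C-R2) outflow
model; the root receives a prescribed periodic inflow.  All quantities are
SI internally (m, m^2, Pa, m^3/s); helpers for mmHg / mL conversions live
in :mod:`pulsereduce.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Union

import numpy as np
from scipy.integrate import quad

__all__ = [
    "GlobalParams",
    "ArterialSegment",
    "Windkessel3",
    "Windkessel2",
    "ArterialNetwork",
    "InflowWaveform",
    "wave_speed",
    "tube_law_pressure",
    "area_from_pressure",
    "characteristic_impedance",
    "count_parameters",
    "apply_hypertension",
    "NetworkError",
]

MMHG = 133.322  # Pa per mmHg


class NetworkError(ValueError):
    """Raised for invalid network topology or parameters."""


@dataclass(frozen=True)
class GlobalParams:
    """Blood properties and global model constants.

    Parameters
    ----------
    rho : blood density (kg/m^3).
    mu : dynamic blood viscosity (Pa s).
    xi : polynomial order of the axial velocity profile (dimensionless);
        ``xi = 9`` corresponds to near-plug flow, ``xi = 2`` to Poiseuille.
    diastolic_pressure : pressure at which segments take their diastolic
        area (Pa).
    """

    rho: float = 1050.0
    mu: float = 4.0e-3
    xi: int = 9
    diastolic_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"blood density must be positive, got {self.rho}")
        if self.mu <= 0:
            raise ValueError(f"blood viscosity must be positive, got {self.mu}")
        if self.xi < 2:
            raise ValueError(f"velocity profile order must be >= 2, got {self.xi}")

    @property
    def friction_coefficient(self) -> float:
        """Coefficient ``2 (xi + 2) pi mu`` of the wall friction law."""
        return 2.0 * (self.xi + 2) * math.pi * self.mu


def wave_speed(beta, A_d, A, rho):
    """Pulse wave velocity ``c = sqrt(beta / (2 rho A_d)) A**(1/4)``.

    All arguments must be positive; arrays broadcast elementwise.
    """
    beta, A_d, A = np.asarray(beta, float), np.asarray(A_d, float), np.asarray(A, float)
    if np.any(beta <= 0) or np.any(A_d <= 0) or np.any(A <= 0) or rho <= 0:
        raise ValueError("wave_speed requires positive beta, A_d, A and rho")
    out = np.sqrt(beta / (2.0 * rho * A_d)) * A ** 0.25
    return float(out) if out.ndim == 0 else out


def tube_law_pressure(A, A_d, beta, P_d=0.0):
    """Transmural pressure from the elastic tube law."""
    A, A_d = np.asarray(A, float), np.asarray(A_d, float)
    if np.any(A <= 0) or np.any(A_d <= 0):
        raise ValueError("tube_law_pressure requires positive areas")
    out = P_d + (beta / A_d) * (np.sqrt(A) - np.sqrt(A_d))
    return float(out) if np.ndim(out) == 0 else out


def area_from_pressure(P, A_d, beta, P_d=0.0):
    """Invert the tube law: luminal area at pressure ``P``."""
    A_d = np.asarray(A_d, float)
    root = np.sqrt(A_d) + (np.asarray(P, float) - P_d) * A_d / beta
    if np.any(root <= 0):
        raise ValueError("pressure below tube-law collapse limit")
    out = root ** 2
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class ArterialSegment:
    """One tapered elastic vessel.

    The diastolic radius varies linearly between ``radius_in`` (proximal,
    x = 0) and ``radius_out`` (distal, x = length); the stiffness ``beta``
    varies linearly between ``beta_in`` and ``beta_out``.
    """

    name: str
    length: float
    radius_in: float
    radius_out: float
    beta_in: float
    beta_out: float
    trunk: bool = False  # True for segments of the main (aortic) trunk

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"{self.name}: length must be >= 0")
        if min(self.radius_in, self.radius_out) <= 0:
            raise ValueError(f"{self.name}: radii must be positive")
        if min(self.beta_in, self.beta_out) <= 0:
            raise ValueError(f"{self.name}: beta must be positive")

    @classmethod
    def from_pwv(
        cls,
        name: str,
        length: float,
        radius_in: float,
        radius_out: float,
        pwv_in: float,
        pwv_out: float,
        rho: float = 1050.0,
        trunk: bool = False,
    ) -> "ArterialSegment":
        """Build a segment from its end diastolic pulse wave velocities.

        Uses ``beta = 2 rho c_d^2 sqrt(A_d)``, the inverse of the beta-PWV
        relation evaluated at the diastolic area.
        """
        a_in = math.pi * radius_in ** 2
        a_out = math.pi * radius_out ** 2
        return cls(
            name=name,
            length=length,
            radius_in=radius_in,
            radius_out=radius_out,
            beta_in=2.0 * rho * pwv_in ** 2 * math.sqrt(a_in),
            beta_out=2.0 * rho * pwv_out ** 2 * math.sqrt(a_out),
            trunk=trunk,
        )

    # -- axial profiles -------------------------------------------------
    def _frac(self, x):
        if self.length == 0.0:
            return np.zeros_like(np.asarray(x, float))
        return np.asarray(x, float) / self.length

    def radius_d(self, x):
        """Diastolic radius at axial position x (m)."""
        s = self._frac(x)
        return self.radius_in + (self.radius_out - self.radius_in) * s

    def area_d(self, x):
        """Diastolic cross-sectional area at x (m^2)."""
        return math.pi * self.radius_d(x) ** 2

    def beta(self, x):
        """Wall stiffness parameter at x (Pa m)."""
        s = self._frac(x)
        return self.beta_in + (self.beta_out - self.beta_in) * s

    def wave_speed_d(self, x, rho: float):
        """Diastolic pulse wave velocity at x (m/s)."""
        a = self.area_d(x)
        return wave_speed(self.beta(x), a, a, rho)

    def char_impedance(self, x, rho: float):
        """Characteristic impedance ``Z0 = rho c_d / A_d`` at x (Pa s/m^3)."""
        x_arr = np.asarray(x, float)
        if np.any(x_arr < 0) or np.any(x_arr > self.length * (1 + 1e-12)):
            raise ValueError(f"{self.name}: position outside [0, {self.length}]")
        return rho * self.wave_speed_d(x, rho) / self.area_d(x)

    def transit_time(self, rho: float) -> float:
        """Pulse transit time along the vessel, integral of dx / c_d (s)."""
        if self.length == 0.0:
            return 0.0
        val, _ = quad(lambda x: 1.0 / self.wave_speed_d(x, rho), 0.0, self.length,
                      epsrel=1e-10, limit=200)
        return val


def characteristic_impedance(segment: ArterialSegment, x: float, rho: float) -> float:
    """Characteristic impedance of a segment at axial position ``x``."""
    return float(segment.char_impedance(x, rho))


@dataclass
class Windkessel3:
    """Three-element (R1-C-R2) windkessel outflow model."""

    R1: float
    R2: float
    C: float
    p_out: float = 0.0

    def __post_init__(self) -> None:
        if self.R1 < 0:
            raise ValueError("R1 must be >= 0")
        if self.R2 <= 0:
            raise ValueError("R2 must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")

    @property
    def total_resistance(self) -> float:
        return self.R1 + self.R2


@dataclass
class Windkessel2:
    """Two-element (C-R) windkessel model."""

    R: float
    C: float
    p_out: float = 0.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")


AnyWindkessel = Union[Windkessel2, Windkessel3]


@dataclass
class InflowWaveform:
    """One period of a prescribed volumetric inflow, periodically extended.

    ``times`` must be strictly increasing and span exactly one period
    ``[0, T]``.  An optional analytic callable ``func`` (taking time within
    one period) overrides sample interpolation wherever exact evaluation is
    preferable (fixtures use it for the half-sinusoid ejection waveform).
    """

    period: float
    times: np.ndarray
    flows: np.ndarray
    func: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.flows = np.asarray(self.flows, float)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.times.ndim != 1 or self.times.shape != self.flows.shape:
            raise ValueError("times and flows must be equal-length 1D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] > self.period * (1 + 1e-12):
            raise ValueError("times must lie within one period")
        self._interp = None

    def __call__(self, t):
        tau = np.mod(t, self.period)
        if self.func is not None:
            return self.func(tau)
        if self._interp is None:
            from scipy.interpolate import PchipInterpolator
            # periodic closure of the sample set
            tt = list(self.times)
            qq = list(self.flows)
            wrap = 0.5 * (qq[0] + qq[-1])
            if tt[0] > 0.0:
                tt.insert(0, 0.0)
                qq.insert(0, wrap)
            if tt[-1] < self.period:
                tt.append(self.period)
                qq.append(wrap)
            self._interp = PchipInterpolator(np.asarray(tt), np.asarray(qq))
        return self._interp(tau)

    def mean_flow(self) -> float:
        """Time-averaged flow over one period (m^3/s)."""
        return self.volume_per_cycle() / self.period

    def volume_per_cycle(self) -> float:
        """Ejected volume per cardiac cycle (m^3).

        Integrates piecewise between the sample times so that derivative
        kinks lying on samples do not degrade the quadrature.
        """
        edges = np.unique(np.concatenate([[0.0], self.times, [self.period]]))
        total = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            val, _ = quad(lambda t: float(self(t)), a, b, epsrel=1e-12, limit=100)
            total += val
        return total


@dataclass
class ArterialNetwork:
    """Rooted tree of arterial segments with windkessel terminals.

    ``parents`` maps each segment name to its parent's name (``None`` for
    the root).  Every leaf must have an entry in ``terminals``.
    """

    segments: Dict[str, ArterialSegment]
    parents: Dict[str, Optional[str]]
    terminals: Dict[str, AnyWindkessel]
    globals: GlobalParams = field(default_factory=GlobalParams)

    def __post_init__(self) -> None:
        self.validate()

    # -- topology -------------------------------------------------------
    @property
    def root(self) -> str:
        roots = [n for n, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise NetworkError(f"network must have exactly one root, found {roots}")
        return roots[0]

    def children_of(self, name: str) -> List[str]:
        return sorted(n for n, p in self.parents.items() if p == name)

    @property
    def leaves(self) -> List[str]:
        parents_set = set(p for p in self.parents.values() if p is not None)
        return sorted(n for n in self.segments if n not in parents_set)

    def validate(self) -> None:
        if set(self.segments) != set(self.parents):
            raise NetworkError("segments and parents must list the same ids")
        root = self.root
        # connectivity / acyclicity: walk each node to the root
        for name in self.segments:
            seen = set()
            node: Optional[str] = name
            while node is not None:
                if node in seen:
                    raise NetworkError(f"cycle detected through segment '{node}'")
                seen.add(node)
                parent = self.parents.get(node, "missing")
                if parent == "missing":
                    raise NetworkError(f"segment '{node}' referenced but not defined")
                node = parent
            if root not in seen:
                raise NetworkError(f"segment '{name}' is not connected to the root")
        for leaf in self.leaves:
            if leaf not in self.terminals:
                raise NetworkError(f"leaf segment '{leaf}' has no terminal windkessel")
        for name in self.terminals:
            if name not in self.segments:
                raise NetworkError(f"terminal attached to unknown segment '{name}'")
            if self.children_of(name):
                raise NetworkError(f"terminal attached to non-leaf segment '{name}'")

    def generations(self) -> Dict[str, int]:
        """Generation-of-bifurcations index per segment.

        The trunk (aortic) chain is generation 0; every branching off a
        parent increments the generation, except that a trunk child of a
        trunk parent stays at generation 0.  With no trunk flags set, this
        reduces to tree depth.
        """
        gen: Dict[str, int] = {}
        root = self.root
        gen[root] = 0
        stack = [root]
        while stack:
            node = stack.pop()
            for child in self.children_of(node):
                seg = self.segments[child]
                if seg.trunk and self.segments[node].trunk:
                    gen[child] = gen[node]
                else:
                    gen[child] = gen[node] + 1
                stack.append(child)
        return gen

    def copy(self) -> "ArterialNetwork":
        return ArterialNetwork(
            segments={k: replace(v) for k, v in self.segments.items()},
            parents=dict(self.parents),
            terminals={k: replace(v) for k, v in self.terminals.items()},
            globals=self.globals,
        )


def count_parameters(network: ArterialNetwork) -> int:
    """Number of independent model parameters.

    Each 1D segment contributes three (length, diastolic area, diastolic
    PWV); each terminal windkessel contributes two (peripheral resistance
    and compliance; R1 is tied to the outlet characteristic impedance);
    six global items remain: blood density, viscosity, velocity-profile
    shape, diastolic pressure, the inflow waveform and the shared terminal
    outflow pressure.
    """
    return 3 * len(network.segments) + 2 * len(network.terminals) + 6


def apply_hypertension(network: ArterialNetwork, factor: float) -> ArterialNetwork:
    """Stiffen a network: scale every diastolic PWV and each terminal's
    total peripheral resistance by ``factor``.

    PWV scaling is implemented as ``beta -> factor**2 * beta`` at fixed
    diastolic area.  Each terminal's ``R1`` is reset to the new outlet
    characteristic impedance and ``R2`` absorbs the remainder of the scaled
    total resistance; compliances and outflow pressures are unchanged.
    """
    if factor <= 0:
        raise ValueError("hypertension factor must be positive")
    if factor == 1.0:
        return network.copy()
    net = network.copy()
    for seg in net.segments.values():
        seg.beta_in *= factor ** 2
        seg.beta_out *= factor ** 2
    rho = net.globals.rho
    for name, wk in net.terminals.items():
        if not isinstance(wk, Windkessel3):
            raise NetworkError(f"terminal '{name}' is not a three-element windkessel")
        seg = net.segments[name]
        r_total = factor * (wk.R1 + wk.R2)
        z0 = float(seg.char_impedance(seg.length, rho))
        r2 = r_total - z0
        if r2 <= 0:
            raise NetworkError(
                f"terminal '{name}': scaled total resistance {r_total:.3e} does not "
                f"exceed the outlet characteristic impedance {z0:.3e}"
            )
        net.terminals[name] = Windkessel3(R1=z0, R2=r2, C=wk.C, p_out=wk.p_out)
    return net
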