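"""Lumping peripheral 1D vessels into equivalent windkessel models.

A terminal 1D vessel with a three-element windkessel outlet is replaced by
a two-element windkessel that preserves the branch's net resistance and
total effective compliance:

    R_new = R2 + R1 + R_v
    C_new = (C_v R2 + C_v R1 + C R2 + R_v C_v) / (R2 + R1 + R_v)

where the vessel's own resistance and compliance follow from axial
integrals of its diastolic area and wave-speed profiles,

    R_v = 2 (xi + 2) pi mu K3,   K3 = int_0^l A_d^-2 dx,
    C_v = K1 / rho,              K1 = int_0^l A_d / c_d^2 dx.

Sibling lumps merge in parallel into a three-element windkessel on their
parent: the total resistance is the parallel combination, compliances add,
and the proximal resistance is set to the parent's outlet characteristic
impedance to minimise wave reflections.  The derivation neglects fluid
inertia (the K2 integral is reported as a diagnostic only) and assumes
vessel transit times are small relative to the cardiac period; see
:func:`reduction_validity`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

from scipy.integrate import quad

from .network import (
    ArterialNetwork,
    ArterialSegment,
    GlobalParams,
    NetworkError,
    Windkessel2,
    Windkessel3,
)

__all__ = [
    "VesselIntegrals",
    "VesselRC",
    "ValidityDiagnostics",
    "ReductionWarning",
    "vessel_integrals",
    "vessel_rc",
    "lump_terminal",
    "merge_siblings",
    "trim_generation",
    "trim_peripheral_pair",
    "reduce_to_windkessel",
    "reduction_validity",
    "ReductionSchedule",
    "apply_schedule",
]


class ReductionWarning(UserWarning):
    """Emitted when a lumping step falls outside its comfortable regime."""


@dataclass(frozen=True)
class VesselIntegrals:
    """Axial integrals of a vessel's diastolic profiles.

    K1 = int A_d / c_d^2 dx (m s^2) enters the vessel compliance;
    K2 = int 1 / A_d dx (1/m) would enter an inertance term (diagnostic
    only, deliberately unused in the lumping formulas);
    K3 = int 1 / A_d^2 dx (1/m^3) enters the vessel resistance.
    """

    K1: float
    K2: float
    K3: float


@dataclass(frozen=True)
class VesselRC:
    """Lumped resistance and compliance of one 1D vessel."""

    R_v: float
    C_v: float


def vessel_integrals(segment: ArterialSegment, rho: float = 1050.0) -> VesselIntegrals:
    """Adaptive-quadrature evaluation of the K1, K2, K3 profile integrals."""
    if segment.length == 0.0:
        return VesselIntegrals(0.0, 0.0, 0.0)

    def k1_integrand(x):
        return segment.area_d(x) / segment.wave_speed_d(x, rho) ** 2

    def k2_integrand(x):
        return 1.0 / segment.area_d(x)

    def k3_integrand(x):
        return 1.0 / segment.area_d(x) ** 2

    opts = dict(epsrel=1e-12, epsabs=0.0, limit=200)
    k1, _ = quad(k1_integrand, 0.0, segment.length, **opts)
    k2, _ = quad(k2_integrand, 0.0, segment.length, **opts)
    k3, _ = quad(k3_integrand, 0.0, segment.length, **opts)
    return VesselIntegrals(k1, k2, k3)


def vessel_rc(segment: ArterialSegment, g: GlobalParams) -> VesselRC:
    """Lumped resistance ``2 (xi+2) pi mu K3`` and compliance ``K1 / rho``."""
    ints = vessel_integrals(segment, g.rho)
    return VesselRC(R_v=g.friction_coefficient * ints.K3, C_v=ints.K1 / g.rho)


def lump_terminal(segment: ArterialSegment, wk: Windkessel3,
                  g: GlobalParams) -> Windkessel2:
    """Collapse a terminal vessel plus its R1-C-R2 outlet into a C-R model."""
    rc = vessel_rc(segment, g)
    r_new = wk.R2 + wk.R1 + rc.R_v
    c_new = (rc.C_v * wk.R2 + rc.C_v * wk.R1 + wk.C * wk.R2 + rc.R_v * rc.C_v) / r_new
    return Windkessel2(R=r_new, C=c_new, p_out=wk.p_out)


def merge_siblings(parent: ArterialSegment, lumps: List[Windkessel2],
                   g: GlobalParams, match_impedance: bool = True) -> Windkessel3:
    """Combine sibling C-R lumps into an R1-C-R2 windkessel on the parent.

    The total resistance is the parallel combination of the lump
    resistances and the compliance is their sum.  With ``match_impedance``
    (the default) the proximal resistance is set to the parent's distal
    characteristic impedance to minimise wave reflections (clamped, with a
    warning, to 99% of the total when the parent is stiffer than its
    periphery, a degenerate case the derivation does not cover); with
    ``match_impedance=False`` the proximal resistance is zero.
    """
    if not lumps:
        raise ValueError("merge_siblings needs at least one lumped child")
    p_outs = {wk.p_out for wk in lumps}
    if len(p_outs) > 1:
        raise NetworkError(
            f"mismatched outflow pressures {sorted(p_outs)} at junction of "
            f"'{parent.name}'; merged terminals must share one p_out"
        )
    r_total = 1.0 / sum(1.0 / wk.R for wk in lumps)
    c_new = sum(wk.C for wk in lumps)
    if not match_impedance:
        return Windkessel3(R1=0.0, R2=r_total, C=c_new, p_out=lumps[0].p_out)
    z0 = float(parent.char_impedance(parent.length, g.rho))
    if z0 >= r_total:
        warnings.warn(
            f"junction of '{parent.name}': outlet characteristic impedance "
            f"{z0:.3e} exceeds combined peripheral resistance {r_total:.3e}; "
            "clamping R1 to 0.99 R_total",
            ReductionWarning,
            stacklevel=2,
        )
        z0 = 0.99 * r_total
    return Windkessel3(R1=z0, R2=r_total - z0, C=c_new, p_out=lumps[0].p_out)


def _lump_and_merge(net: ArterialNetwork, parent_id: str,
                    match_impedance: bool = True) -> None:
    """In place: lump all (leaf) children of ``parent_id`` and merge them."""
    children = net.children_of(parent_id)
    lumps = []
    for child in children:
        if net.children_of(child):
            raise NetworkError(f"segment '{child}' is not a leaf")
        wk = net.terminals[child]
        if isinstance(wk, Windkessel2):
            # already lumped once; treat as a degenerate R1=0 three-element
            wk = Windkessel3(R1=0.0, R2=wk.R, C=wk.C, p_out=wk.p_out)
        lumps.append(lump_terminal(net.segments[child], wk, net.globals))
    merged = merge_siblings(net.segments[parent_id], lumps, net.globals,
                            match_impedance=match_impedance)
    for child in children:
        del net.segments[child]
        del net.parents[child]
        net.terminals.pop(child, None)
    net.terminals[parent_id] = merged


def trim_generation(network: ArterialNetwork) -> ArterialNetwork:
    """Remove the deepest generation of bifurcations.

    Every segment of the deepest generation is lumped into a C-R model and
    sibling groups are merged into three-element windkessels attached to
    their parents.  Requires at least two generations below the trunk so
    that the affected junctions contain only leaves.
    """
    gen = network.generations()
    deepest = max(gen.values())
    if deepest < 2:
        raise NetworkError(
            f"nothing to trim: network has {deepest} generation(s) of "
            "bifurcations (need >= 2)"
        )
    net = network.copy()
    parents = sorted({net.parents[s] for s, d in gen.items() if d == deepest})
    for parent_id in parents:
        assert parent_id is not None
        for child in net.children_of(parent_id):
            if gen[child] != deepest:
                raise NetworkError(
                    f"junction of '{parent_id}' mixes generations; cannot trim"
                )
        _lump_and_merge(net, parent_id)
    net.validate()
    return net


def trim_peripheral_pair(network: ArterialNetwork, junction: str) -> ArterialNetwork:
    """Lump and merge all children at the distal junction of ``junction``.

    All children must be leaves carrying windkessels; they are replaced by
    a single three-element windkessel on the parent segment.
    """
    if junction not in network.segments:
        raise NetworkError(f"unknown segment '{junction}'")
    children = network.children_of(junction)
    if not children:
        raise NetworkError(f"segment '{junction}' has no distal junction")
    for child in children:
        if network.children_of(child):
            raise NetworkError(
                f"child '{child}' of junction '{junction}' is not a leaf"
            )
    net = network.copy()
    _lump_and_merge(net, junction)
    net.validate()
    return net


def reduce_to_windkessel(network: ArterialNetwork,
                         match_impedance: bool = True) -> Windkessel2:
    """Fully reduce a network to a single two-element windkessel.

    Applies terminal lumping and sibling merging leaf-to-root (deepest
    junctions first, siblings in id order) until only the root remains,
    then lumps the root itself.  The resulting resistance equals the
    network's net (series/parallel) resistance.  ``match_impedance``
    controls whether merged windkessels carry the parent's characteristic
    impedance as their proximal resistance (see :func:`merge_siblings`).
    """
    net = network.copy()
    while True:
        leaves = set(net.leaves)
        if leaves == {net.root}:
            break
        # junctions whose children are all leaves, deepest first
        depth: Dict[str, int] = {}

        def _depth(s: str) -> int:
            if s not in depth:
                p = net.parents[s]
                depth[s] = 0 if p is None else _depth(p) + 1
            return depth[s]

        ready = [p for p in net.segments
                 if net.children_of(p) and set(net.children_of(p)) <= leaves]
        ready.sort(key=lambda s: (-_depth(s), s))
        for parent_id in ready:
            _lump_and_merge(net, parent_id, match_impedance=match_impedance)
    root = net.root
    wk = net.terminals[root]
    if isinstance(wk, Windkessel2):
        wk = Windkessel3(R1=0.0, R2=wk.R, C=wk.C, p_out=wk.p_out)
    return lump_terminal(net.segments[root], wk, net.globals)


@dataclass(frozen=True)
class ValidityDiagnostics:
    """Diagnostics for the lumping assumptions on one terminal branch.

    ``transit_ratio`` is the vessel pulse transit time over the cardiac
    period; the lumping derivation assumes it is small (flagged above
    0.1).  ``inertia_ratio`` compares the neglected inertance time scale
    ``rho K2 / R_total`` with the cardiac period.
    """

    transit_ratio: float
    inertia_ratio: float
    flagged: bool


def reduction_validity(segment: ArterialSegment, wk: Windkessel3,
                       period: float, g: GlobalParams) -> ValidityDiagnostics:
    if period <= 0:
        raise ValueError("cardiac period must be positive")
    if segment.length == 0.0:
        return ValidityDiagnostics(0.0, 0.0, False)
    transit = segment.transit_time(g.rho) / period
    ints = vessel_integrals(segment, g.rho)
    r_total = g.friction_coefficient * ints.K3 + wk.R1 + wk.R2
    inertia = (g.rho * ints.K2 / r_total) / period
    return ValidityDiagnostics(transit_ratio=transit, inertia_ratio=inertia,
                               flagged=transit > 0.1)


@dataclass
class ReductionSchedule:
    """An ordered list of reduction steps.

    Steps are strings: ``"trim-generation"`` (remove the deepest
    generation), ``"lump-pair:<segment>"`` (merge the leaves at that
    segment's distal junction), ``"lump-pair:auto"`` (merge at the deepest
    junction whose children are all leaves) or ``"full"`` (reduce whatever
    remains to Frank's two-element windkessel of the whole network).
    """

    steps: List[str]

    @classmethod
    def parse(cls, text: str) -> "ReductionSchedule":
        """Parse e.g. ``"generations:2,pairs:auto,full"``."""
        steps: List[str] = []
        for tok in text.split(","):
            tok = tok.strip()
            if not tok:
                continue
            if tok.startswith("generations:"):
                steps.extend(["trim-generation"] * int(tok.split(":", 1)[1]))
            elif tok == "pairs:auto":
                steps.append("lump-pair:auto")
            elif tok.startswith("pairs:"):
                steps.append("lump-pair:" + tok.split(":", 1)[1])
            elif tok in ("full", "trim-generation") or tok.startswith("lump-pair:"):
                steps.append(tok)
            else:
                raise ValueError(f"unknown schedule step '{tok}'")
        return cls(steps)


def _deepest_ready_junction(net: ArterialNetwork) -> Optional[str]:
    leaves = set(net.leaves)
    best, best_depth = None, -1
    for p in sorted(net.segments):
        kids = net.children_of(p)
        if kids and set(kids) <= leaves:
            d = 0
            node: Optional[str] = p
            while node is not None:
                node = net.parents[node]
                d += 1
            if d > best_depth:
                best, best_depth = p, d
    return best


def apply_schedule(network: ArterialNetwork, schedule: ReductionSchedule):
    """Yield ``(label, reduced_network_or_windkessel)`` per schedule step."""
    net = network
    for step in schedule.steps:
        if step == "trim-generation":
            net = trim_generation(net)
            yield step, net
        elif step == "full":
            yield step, reduce_to_windkessel(net)
        elif step.startswith("lump-pair:"):
            target = step.split(":", 1)[1]
            if target == "auto":
                found = _deepest_ready_junction(net)
                if found is None:
                    raise NetworkError("no junction with all-leaf children")
                target = found
            net = trim_peripheral_pair(net, target)
            yield f"lump-pair:{target}", net
        else:  # pragma: no cover - guarded by ReductionSchedule.parse
            raise ValueError(f"unknown schedule step '{step}'")
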