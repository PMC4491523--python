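"""Deterministic synthetic networks and inflows.

The named anatomical trees (``tree-55-style``, ``tree-67-style``,
``tree-21-style``, ``tree-37-style``) encode the topology of a systemic
arterial tree of the 55 larger arteries — the aortic trunk plus five
generations of bifurcations — and its extension with the superficial
palmar arches and digital arteries of the hands.  Geometric and elastic
values are *representative*: chosen from physiological ranges (radius
1-15 mm, length 2-50 cm, diastolic PWV 4-12 m/s), not taken from any
published patient-specific data set, so quantitative statements on these
fixtures concern structure, counts and property suites rather than any
particular subject's waveforms.

Terminal windkessels are assigned so that R1 equals the outlet
characteristic impedance of the attached vessel, and the peripheral
resistances and compliances are distributed (by outlet area) and scaled
so that the fully reduced network has a declared net resistance and total
effective compliance (defaults 1.4e8 Pa s/m^3 and 1e-8 m^3/Pa, giving a
physiological diastolic time constant of ~1.4 s).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .network import (
    ArterialNetwork,
    ArterialSegment,
    GlobalParams,
    InflowWaveform,
    Windkessel3,
)

__all__ = ["FixtureSpec", "make_inflow", "make_tree", "TREE_KINDS"]

TREE_KINDS = (
    "single-vessel",
    "bifurcation",
    "symmetric-tree",
    "tree-55-style",
    "tree-67-style",
    "tree-21-style",
    "tree-37-style",
)


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic network fixture."""

    kind: str = "symmetric-tree"
    generations: int = 3
    seed: int = 0
    period: float = 1.0
    net_resistance: float = 1.4e8       # Pa s/m^3, target of the full reduction
    total_compliance: float = 1.0e-8    # m^3/Pa, target effective compliance
    p_out: float = 0.0                  # Pa, shared terminal outflow pressure
    jitter: float = 0.0                 # relative geometric jitter (seeded)

    def __post_init__(self) -> None:
        if self.kind not in TREE_KINDS:
            raise ValueError(f"unknown fixture kind '{self.kind}'; "
                             f"choose from {TREE_KINDS}")
        if self.period <= 0 or self.generations < 1:
            raise ValueError("period must be > 0 and generations >= 1")


def make_inflow(period: float = 1.0, stroke_volume: float = 70e-6,
                systolic_fraction: float = 0.3, n_samples: int = 101) -> InflowWaveform:
    """Half-sinusoid systolic ejection waveform.

    Flow is ``Q_peak sin(pi t / (fs T))`` during systole (duration
    ``fs T``) and zero in diastole, with ``Q_peak = pi SV / (2 fs T)`` so
    that the ejected volume per cycle equals the stroke volume exactly.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if not 0 < systolic_fraction <= 1:
        raise ValueError("systolic fraction must lie in (0, 1]")
    t_sys = systolic_fraction * period
    q_peak = math.pi * stroke_volume / (2.0 * t_sys)

    def func(tau):
        tau = np.asarray(tau, float)
        out = np.where(tau < t_sys, q_peak * np.sin(np.pi * np.clip(tau, 0, t_sys) / t_sys), 0.0)
        return out if out.ndim else float(out)

    times = np.linspace(0.0, period, n_samples)
    return InflowWaveform(period=period, times=times, flows=np.asarray(func(times)),
                          func=func)


# ---------------------------------------------------------------------------
# Representative 55-artery-style parameter table.
# Columns: name, parent, trunk, length (m), radius_in, radius_out (m),
#          pwv_in, pwv_out (m/s).
# The aortic trunk has 10 segments; branches follow the anatomical layout of
# the larger systemic arteries (5 generations of bifurcations, the deepest
# being the right interosseous and right lower ulnar arteries).
# ---------------------------------------------------------------------------
_TREE55: List[Tuple[str, Optional[str], bool, float, float, float, float, float]] = [
    ("ascending_aorta",    None,                 True, 0.040, 0.0145, 0.0140, 4.0, 4.2),
    ("aortic_arch_i",      "ascending_aorta",    True, 0.030, 0.0130, 0.0125, 4.2, 4.3),
    ("aortic_arch_ii",     "aortic_arch_i",      True, 0.040, 0.0120, 0.0115, 4.3, 4.4),
    ("thoracic_aorta_i",   "aortic_arch_ii",     True, 0.060, 0.0110, 0.0105, 4.4, 4.6),
    ("thoracic_aorta_ii",  "thoracic_aorta_i",   True, 0.100, 0.0100, 0.0092, 4.6, 4.9),
    ("abdominal_aorta_i",  "thoracic_aorta_ii",  True, 0.060, 0.0085, 0.0080, 4.9, 5.1),
    ("abdominal_aorta_ii", "abdominal_aorta_i",  True, 0.020, 0.0078, 0.0076, 5.1, 5.2),
    ("abdominal_aorta_iii","abdominal_aorta_ii", True, 0.020, 0.0075, 0.0073, 5.2, 5.3),
    ("abdominal_aorta_iv", "abdominal_aorta_iii",True, 0.050, 0.0072, 0.0068, 5.3, 5.5),
    ("abdominal_aorta_v",  "abdominal_aorta_iv", True, 0.050, 0.0065, 0.0060, 5.5, 5.7),
    # head and right arm (via the brachiocephalic trunk)
    ("brachiocephalic",    "ascending_aorta",    False, 0.035, 0.0080, 0.0075, 4.5, 4.8),
    ("r_subclavian_i",     "brachiocephalic",    False, 0.035, 0.0050, 0.0048, 5.0, 5.3),
    ("r_common_carotid",   "brachiocephalic",    False, 0.140, 0.0045, 0.0038, 5.0, 5.6),
    ("r_vertebral",        "r_subclavian_i",     False, 0.150, 0.0020, 0.0019, 7.0, 8.0),
    ("r_subclavian_ii",    "r_subclavian_i",     False, 0.400, 0.0045, 0.0032, 5.5, 6.5),
    ("r_radial",           "r_subclavian_ii",    False, 0.220, 0.0018, 0.0016, 7.5, 8.5),
    ("r_ulnar_i",          "r_subclavian_ii",    False, 0.070, 0.0022, 0.0021, 7.0, 7.5),
    ("r_interosseous",     "r_ulnar_i",          False, 0.080, 0.0010, 0.0010, 9.0, 9.5),
    ("r_ulnar_ii",         "r_ulnar_i",          False, 0.170, 0.0020, 0.0018, 7.5, 8.5),
    ("r_internal_carotid", "r_common_carotid",   False, 0.180, 0.0028, 0.0024, 6.5, 7.5),
    ("r_external_carotid", "r_common_carotid",   False, 0.180, 0.0023, 0.0020, 6.5, 7.5),
    # head left
    ("l_common_carotid",   "aortic_arch_i",      False, 0.160, 0.0045, 0.0038, 5.0, 5.6),
    ("l_internal_carotid", "l_common_carotid",   False, 0.180, 0.0028, 0.0024, 6.5, 7.5),
    ("l_external_carotid", "l_common_carotid",   False, 0.180, 0.0023, 0.0020, 6.5, 7.5),
    # left arm
    ("l_subclavian_i",     "aortic_arch_ii",     False, 0.035, 0.0050, 0.0048, 5.0, 5.3),
    ("l_vertebral",        "l_subclavian_i",     False, 0.150, 0.0020, 0.0019, 7.0, 8.0),
    ("l_subclavian_ii",    "l_subclavian_i",     False, 0.400, 0.0045, 0.0032, 5.5, 6.5),
    ("l_radial",           "l_subclavian_ii",    False, 0.220, 0.0018, 0.0016, 7.5, 8.5),
    ("l_ulnar_i",          "l_subclavian_ii",    False, 0.070, 0.0022, 0.0021, 7.0, 7.5),
    ("l_interosseous",     "l_ulnar_i",          False, 0.080, 0.0010, 0.0010, 9.0, 9.5),
    ("l_ulnar_ii",         "l_ulnar_i",          False, 0.170, 0.0020, 0.0018, 7.5, 8.5),
    # thorax and abdomen
    ("intercostals",       "thoracic_aorta_i",   False, 0.080, 0.0030, 0.0027, 5.5, 6.0),
    ("celiac_i",           "thoracic_aorta_ii",  False, 0.020, 0.0040, 0.0038, 5.0, 5.2),
    ("celiac_ii",          "celiac_i",           False, 0.020, 0.0030, 0.0029, 5.2, 5.4),
    ("hepatic",            "celiac_i",           False, 0.070, 0.0028, 0.0025, 5.5, 6.0),
    ("gastric",            "celiac_ii",          False, 0.070, 0.0018, 0.0016, 6.0, 6.5),
    ("splenic",            "celiac_ii",          False, 0.060, 0.0022, 0.0020, 6.0, 6.5),
    ("superior_mesenteric","abdominal_aorta_i",  False, 0.060, 0.0040, 0.0036, 5.0, 5.5),
    ("l_renal",            "abdominal_aorta_ii", False, 0.030, 0.0028, 0.0026, 5.5, 6.0),
    ("r_renal",            "abdominal_aorta_iii",False, 0.030, 0.0028, 0.0026, 5.5, 6.0),
    ("inferior_mesenteric","abdominal_aorta_iv", False, 0.050, 0.0020, 0.0018, 6.0, 6.5),
    # legs
    ("r_common_iliac",     "abdominal_aorta_v",  False, 0.060, 0.0040, 0.0037, 6.0, 6.5),
    ("l_common_iliac",     "abdominal_aorta_v",  False, 0.060, 0.0040, 0.0037, 6.0, 6.5),
    ("r_external_iliac",   "r_common_iliac",     False, 0.140, 0.0035, 0.0032, 6.5, 7.0),
    ("r_internal_iliac",   "r_common_iliac",     False, 0.050, 0.0020, 0.0019, 7.0, 7.5),
    ("l_external_iliac",   "l_common_iliac",     False, 0.140, 0.0035, 0.0032, 6.5, 7.0),
    ("l_internal_iliac",   "l_common_iliac",     False, 0.050, 0.0020, 0.0019, 7.0, 7.5),
    ("r_femoral",          "r_external_iliac",   False, 0.440, 0.0030, 0.0025, 7.0, 8.5),
    ("r_deep_femoral",     "r_external_iliac",   False, 0.130, 0.0020, 0.0018, 7.5, 8.0),
    ("l_femoral",          "l_external_iliac",   False, 0.440, 0.0030, 0.0025, 7.0, 8.5),
    ("l_deep_femoral",     "l_external_iliac",   False, 0.130, 0.0020, 0.0018, 7.5, 8.0),
    ("r_posterior_tibial", "r_femoral",          False, 0.320, 0.0016, 0.0014, 9.0, 10.0),
    ("r_anterior_tibial",  "r_femoral",          False, 0.340, 0.0013, 0.0012, 9.0, 10.0),
    ("l_posterior_tibial", "l_femoral",          False, 0.320, 0.0016, 0.0014, 9.0, 10.0),
    ("l_anterior_tibial",  "l_femoral",          False, 0.340, 0.0013, 0.0012, 9.0, 10.0),
]

# Hand extension (per side): two superficial palmar-arch halves fed by the
# radial and distal ulnar arteries, each supplying two digital arteries.
def _hand_rows(side: str):
    s = side
    return [
        (f"{s}_palmar_arch_radial", f"{s}_radial",   False, 0.030, 0.00130, 0.00120, 9.0, 9.5),
        (f"{s}_palmar_arch_ulnar",  f"{s}_ulnar_ii", False, 0.030, 0.00140, 0.00130, 9.0, 9.5),
        (f"{s}_digital_1", f"{s}_palmar_arch_radial", False, 0.060, 0.00110, 0.00100, 10.0, 11.0),
        (f"{s}_digital_2", f"{s}_palmar_arch_radial", False, 0.060, 0.00105, 0.00100, 10.0, 11.0),
        (f"{s}_digital_3", f"{s}_palmar_arch_ulnar",  False, 0.060, 0.00110, 0.00100, 10.0, 11.0),
        (f"{s}_digital_4", f"{s}_palmar_arch_ulnar",  False, 0.060, 0.00105, 0.00100, 10.0, 11.0),
    ]


def _build_from_rows(rows, g: GlobalParams, rng: Optional[np.random.Generator],
                     jitter: float) -> Tuple[Dict[str, ArterialSegment], Dict[str, Optional[str]]]:
    segments: Dict[str, ArterialSegment] = {}
    parents: Dict[str, Optional[str]] = {}
    for name, parent, trunk, length, r_in, r_out, c_in, c_out in rows:
        if rng is not None and jitter > 0:
            f = 1.0 + jitter * rng.uniform(-1, 1, size=4)
            length, r_in, r_out = length * f[0], r_in * f[1], r_out * f[1]
            c_in, c_out = c_in * f[2], c_out * f[2]
        segments[name] = ArterialSegment.from_pwv(
            name, length, r_in, r_out, c_in, c_out, rho=g.rho, trunk=trunk)
        parents[name] = parent
    return segments, parents


def _symmetric_rows(spec: FixtureSpec):
    """Binary tree of ``spec.generations`` levels below a root vessel."""
    rows = []
    root_l, root_r, root_c = 0.10, 0.010, 4.5
    rows.append(("root", None, False, root_l, root_r, root_r * 0.94, root_c, root_c * 1.05))

    def recurse(parent: str, level: int):
        if level > spec.generations:
            return
        l = root_l * 0.75 ** level
        r = root_r * 0.78 ** level
        c = root_c * 1.18 ** level
        for k in (1, 2):
            name = f"{parent}.{k}"
            rows.append((name, parent, False, l, r, r * 0.94, c, c * 1.05))
            recurse(name, level + 1)

    recurse("root", 1)
    return rows


def _single_rows():
    return [("vessel", None, False, 0.100, 0.0100, 0.0095, 4.5, 4.7)]


def _bifurcation_rows():
    return [
        ("parent", None, False, 0.080, 0.0060, 0.0057, 4.5, 4.7),
        ("parent.1", "parent", False, 0.060, 0.0042, 0.0040, 5.5, 5.8),
        ("parent.2", "parent", False, 0.060, 0.0042, 0.0040, 5.5, 5.8),
    ]


def _tree37_rows():
    """Full aorta with all peripheral vessels attached as terminal leaves.

    The 17 right-side vessels of the 67-artery tree are kept as individual
    1D leaf segments at the brachiocephalic origin (an n-furcation), and
    the 10 remaining first-generation branches stay as terminal leaves:
    37 segments, 27 terminals.
    """
    by_name = {r[0]: r for r in _TREE55 + _hand_rows("r") + _hand_rows("l")}
    aorta = [r for r in _TREE55 if r[2]]
    first_gen_leaves = [
        "l_common_carotid", "l_subclavian_i", "intercostals", "celiac_i",
        "superior_mesenteric", "l_renal", "r_renal", "inferior_mesenteric",
        "r_common_iliac", "l_common_iliac",
    ]
    right_side = [
        "brachiocephalic", "r_subclavian_i", "r_common_carotid", "r_vertebral",
        "r_subclavian_ii", "r_radial", "r_ulnar_i", "r_interosseous",
        "r_ulnar_ii", "r_internal_carotid", "r_external_carotid",
        "r_palmar_arch_radial", "r_palmar_arch_ulnar",
        "r_digital_1", "r_digital_2", "r_digital_3", "r_digital_4",
    ]
    rows = list(aorta)
    for name in first_gen_leaves:
        rows.append(by_name[name])
    for name in right_side:
        r = by_name[name]
        rows.append((r[0], "ascending_aorta", False) + r[3:])
    return rows


def _assign_windkessels(segments, parents, spec: FixtureSpec,
                        g: GlobalParams) -> ArterialNetwork:
    """Attach R1=Z0 windkessels and scale R2, C to the declared targets."""
    from .reduction import ReductionWarning, reduce_to_windkessel

    parent_set = {p for p in parents.values() if p is not None}
    leaves = sorted(n for n in segments if n not in parent_set)
    areas = np.array([segments[n].area_d(segments[n].length) for n in leaves])
    weights = areas / areas.sum()
    z0 = np.array([float(segments[n].char_impedance(segments[n].length, g.rho))
                   for n in leaves])
    r_base = spec.net_resistance / weights
    c_base = spec.total_compliance * weights

    def build(m: float, k: float) -> ArterialNetwork:
        terminals = {}
        for i, n in enumerate(leaves):
            r2 = m * r_base[i] - z0[i]
            if r2 <= 0:
                raise ValueError("resistance multiplier too small")
            terminals[n] = Windkessel3(R1=z0[i], R2=r2, C=k * c_base[i],
                                       p_out=spec.p_out)
        return ArterialNetwork(segments={n: s for n, s in segments.items()},
                               parents=dict(parents), terminals=terminals,
                               globals=g)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ReductionWarning)
        m_lo = 1.02 * float(np.max(z0 / r_base))
        m_lo = max(m_lo, 1e-3)

        def f(m):
            return reduce_to_windkessel(build(m, 1.0)).R - spec.net_resistance

        m_hi = max(2.0, 2 * m_lo)
        while f(m_hi) < 0:
            m_hi *= 2
            if m_hi > 1e4:
                raise ValueError("cannot reach the requested net resistance")
        if f(m_lo) > 0:
            raise ValueError(
                "requested net resistance is below the vessels' own series "
                "resistance plus characteristic impedances")
        m_star = brentq(f, m_lo, m_hi, rtol=1e-13)

        # effective compliance is affine in the common terminal-C multiplier
        c1 = reduce_to_windkessel(build(m_star, 1.0)).C
        c2 = reduce_to_windkessel(build(m_star, 2.0)).C
        slope = c2 - c1
        k_star = 1.0 + (spec.total_compliance - c1) / slope
        if k_star <= 0:
            raise ValueError(
                "requested total compliance is below the vessels' own "
                "distributed compliance")
    return build(m_star, k_star)


def make_tree(spec: FixtureSpec) -> ArterialNetwork:
    """Build the synthetic network described by ``spec``."""
    g = GlobalParams()
    rng = np.random.default_rng(spec.seed)
    jitter = spec.jitter
    if spec.kind == "single-vessel":
        rows = _single_rows()
    elif spec.kind == "bifurcation":
        rows = _bifurcation_rows()
    elif spec.kind == "symmetric-tree":
        rows = _symmetric_rows(spec)
    elif spec.kind == "tree-55-style":
        rows = list(_TREE55)
    elif spec.kind == "tree-67-style":
        rows = _TREE55 + _hand_rows("r") + _hand_rows("l")
    elif spec.kind == "tree-37-style":
        rows = _tree37_rows()
    elif spec.kind == "tree-21-style":
        from .reduction import trim_generation
        net = make_tree(FixtureSpec(kind="tree-55-style", seed=spec.seed,
                                    period=spec.period,
                                    net_resistance=spec.net_resistance,
                                    total_compliance=spec.total_compliance,
                                    p_out=spec.p_out, jitter=spec.jitter))
        while max(net.generations().values()) > 1:
            net = trim_generation(net)
        return net
    else:  # pragma: no cover - guarded in FixtureSpec
        raise ValueError(spec.kind)
    segments, parents = _build_from_rows(rows, g, rng, jitter)
    return _assign_windkessels(segments, parents, spec, g)
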