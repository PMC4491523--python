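"""1D solver oracles: equilibrium, steady friction, wave transit,
junction coupling, outlet reflection, convergence order and conservation."""

import math
import warnings

import numpy as np
import pytest

import pulsereduce as pr
from pulsereduce.network import (
    ArterialNetwork,
    ArterialSegment,
    GlobalParams,
    InflowWaveform,
    Windkessel2,
    Windkessel3,
)
from pulsereduce.solver import (
    ConvergenceWarning,
    Probe,
    SolverSettings,
    SolverError,
    friction_force,
    simulate,
)
from helpers import gaussian_pulse_inflow


def _constant_inflow(Q0, period=0.2):
    return InflowWaveform(period=period, times=np.array([0.0, period]),
                          flows=np.array([Q0, Q0]),
                          func=lambda t: np.full_like(np.asarray(t, float), Q0))


def _single_vessel(l, r, c, g, wk):
    seg = ArterialSegment.from_pwv("v", l, r, r, c, c, rho=g.rho)
    return ArterialNetwork({"v": seg}, {"v": None}, {"v": wk}, g)


class TestFrictionForce:
    def test_zero_velocity(self):
        assert friction_force(0.0, 4e-3, 9) == 0.0

    def test_direct_evaluation(self):
        f = friction_force(0.1, 4e-3, 9)
        assert f == pytest.approx(-2 * 11 * math.pi * 4e-3 * 0.1, rel=1e-12)
        assert f == pytest.approx(-2.7646e-2, rel=1e-4)

    def test_odd_in_velocity(self):
        assert friction_force(-0.3, 4e-3, 9) == -friction_force(0.3, 4e-3, 9)


class TestEquilibrium:
    def test_rest_state_is_exact_fixed_point(self):
        """Zero inflow with all pressures at the outflow pressure stays
        constant to 1e-10 (relative), even on tapered vessels."""
        g = GlobalParams(diastolic_pressure=2000.0)
        par = ArterialSegment.from_pwv("p", 0.2, 0.005, 0.004, 5.0, 5.5, rho=g.rho)
        d1 = ArterialSegment.from_pwv("p.1", 0.15, 0.003, 0.0025, 6.0, 6.5, rho=g.rho)
        d2 = ArterialSegment.from_pwv("p.2", 0.12, 0.0028, 0.0024, 6.0, 6.6, rho=g.rho)
        wk = Windkessel3(R1=1e8, R2=1e9, C=1e-9, p_out=3000.0)
        net = ArterialNetwork({"p": par, "p.1": d1, "p.2": d2},
                              {"p": None, "p.1": "p", "p.2": "p"},
                              {"p.1": wk, "p.2": wk}, g)
        zero = _constant_inflow(0.0, period=0.1)
        s = SolverSettings(dx=0.01, max_cycles=1, initial_pressure=3000.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            w = simulate(net, zero, s,
                         probes=[Probe("p", 0.5, "m"), Probe("p.1", 0.9, "e")])
        for site in w.sites:
            drift = np.max(np.abs(w.sites[site]["P"] - 3000.0)) / 3000.0
            assert drift < 1e-10
        assert abs(w.diagnostics["volume_in"]) < 1e-16

    def test_zero_inflow_net_volume_zero(self):
        net = pr.make_tree(pr.FixtureSpec(kind="single-vessel"))
        zero = _constant_inflow(0.0, period=0.1)
        s = SolverSettings(max_cycles=1, initial_pressure=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            w = simulate(net, zero, s)
        assert abs(w.diagnostics["volume_in"]) < 1e-16


class TestSteadyState:
    def test_poiseuille_pressure_drop(self):
        """Near-rigid vessel under steady flow: the inlet-outlet drop equals
        the lumped viscous resistance R_v Q within 1% (operating close to
        the diastolic area so the friction law is evaluated there)."""
        g = GlobalParams()
        seg = ArterialSegment.from_pwv("v", 0.05, 0.005, 0.005, 20.0, 20.0,
                                       rho=g.rho)
        rc = pr.vessel_rc(seg, g)
        z0 = float(seg.char_impedance(0.05, g.rho))
        wk = Windkessel3(R1=z0, R2=2e7, C=1e-11, p_out=0.0)
        net = ArterialNetwork({"v": seg}, {"v": None}, {"v": wk}, g)
        Q0 = 2e-6
        s = SolverSettings(dx=0.005, max_cycles=30, periodicity_tol=1e-8,
                           initial_pressure=float((rc.R_v + z0 + 2e7) * Q0))
        w = simulate(net, _constant_inflow(Q0), s,
                     probes=[Probe("v", 0.0, "in"), Probe("v", 1.0, "out")])
        drop = w.sites["in"]["P"].mean() - w.sites["out"]["P"].mean()
        assert drop == pytest.approx(rc.R_v * Q0, rel=0.01)

    def test_wk2_terminal_steady_resistive_relation(self):
        """A two-element terminal at steady state satisfies
        p_out - p_hat = R q exactly (the C branch carries no flow)."""
        g = GlobalParams()
        wk = Windkessel2(R=5e8, C=1e-9, p_out=600.0)
        net = _single_vessel(0.1, 0.004, 6.0, g, wk)
        Q0 = 1e-6
        s = SolverSettings(max_cycles=30, periodicity_tol=1e-8,
                           initial_pressure=600.0 + 5e8 * Q0)
        w = simulate(net, _constant_inflow(Q0), s,
                     probes=[Probe("v", 1.0, "out")])
        p_end = w.sites["out"]["P"].mean()
        rc = pr.vessel_rc(net.segments["v"], g)
        assert p_end - 600.0 == pytest.approx(5e8 * Q0, rel=1e-3)

    def test_constant_inflow_time_average(self):
        net = pr.make_tree(pr.FixtureSpec(kind="single-vessel"))
        Q0 = 5e-6
        s = SolverSettings(max_cycles=12, periodicity_tol=1e-4,
                           initial_pressure=1.4e8 * Q0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            w = simulate(net, _constant_inflow(Q0), s,
                         probes=[Probe("vessel", 0.0, "in")])
        # the imposed boundary flux is exact; the probe is an interpolation
        assert w.diagnostics["volume_in"] == pytest.approx(Q0 * 0.2, rel=1e-9)
        mean_q = np.trapezoid(w.sites["in"]["Q"], w.time) / 0.2
        assert mean_q == pytest.approx(Q0, rel=1e-3)


class TestWaves:
    def test_foot_transit_time(self):
        """A compact pulse's foot travels at the diastolic wave speed."""
        g = GlobalParams()
        seg = ArterialSegment.from_pwv("v", 0.5, 0.004, 0.004, 5.0, 5.0, rho=g.rho)
        z0 = float(seg.char_impedance(0.25, g.rho))
        wk = Windkessel3(R1=z0, R2=1e10, C=1e-7, p_out=0.0)
        net = ArterialNetwork({"v": seg}, {"v": None}, {"v": wk}, g)
        inflow = gaussian_pulse_inflow(1.0, t0=0.05, sigma=0.01, amplitude=2e-6)
        s = SolverSettings(dx=0.005, max_cycles=1, initial_pressure=0.0,
                           n_output=4096)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            w = simulate(net, inflow, s,
                         probes=[Probe("v", 0.1, "a"), Probe("v", 0.9, "b")])

        def foot(tr, P):
            thr = P.max() * 0.02
            i = int(np.argmax(P > thr))
            return tr[i - 1] + (thr - P[i - 1]) * (tr[i] - tr[i - 1]) / (P[i] - P[i - 1])

        dt_meas = foot(w.time, w.sites["b"]["P"]) - foot(w.time, w.sites["a"]["P"])
        assert dt_meas == pytest.approx(0.8 * 0.5 / 5.0, rel=0.03)

    def test_numerical_dissipation_bounded(self):
        """Inviscid pulse with a matched outlet loses < 1% peak amplitude
        over most of one transit."""
        g = GlobalParams(mu=1e-12)
        seg = ArterialSegment.from_pwv("v", 0.5, 0.004, 0.004, 5.0, 5.0, rho=g.rho)
        z0 = float(seg.char_impedance(0.25, g.rho))
        wk = Windkessel3(R1=z0, R2=1e10, C=1e-7, p_out=0.0)
        net = ArterialNetwork({"v": seg}, {"v": None}, {"v": wk}, g)
        inflow = gaussian_pulse_inflow(0.3, t0=0.04, sigma=0.02, amplitude=2e-6)
        s = SolverSettings(dx=0.002, max_cycles=1, initial_pressure=0.0,
                           n_output=4096)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            w = simulate(net, inflow, s,
                         probes=[Probe("v", 0.15, "a"), Probe("v", 0.85, "b")])
        decay = 1.0 - w.sites["b"]["P"].max() / w.sites["a"]["P"].max()
        assert abs(decay) < 0.01

    def test_matched_bifurcation_reflection_below_1e3(self):
        """Daughters whose combined admittance equals the parent's produce
        essentially no reflected wave (linear-theory oracle: zero)."""
        g = GlobalParams(mu=1e-12)
        par = ArterialSegment.from_pwv("p", 0.4, 0.005, 0.005, 5.0, 5.0, rho=g.rho)
        rd = 0.005 / math.sqrt(2.0)
        d1 = ArterialSegment.from_pwv("p.1", 0.4, rd, rd, 5.0, 5.0, rho=g.rho)
        d2 = ArterialSegment.from_pwv("p.2", 0.4, rd, rd, 5.0, 5.0, rho=g.rho)
        z0d = float(d1.char_impedance(0.4, g.rho))
        wk = Windkessel3(R1=z0d, R2=1e10, C=1e-6, p_out=0.0)
        net = ArterialNetwork({"p": par, "p.1": d1, "p.2": d2},
                              {"p": None, "p.1": "p", "p.2": "p"},
                              {"p.1": wk, "p.2": wk}, g)
        inflow = gaussian_pulse_inflow(0.5, t0=0.04, sigma=0.012, amplitude=1e-6)
        s = SolverSettings(dx=0.002, max_cycles=1, initial_pressure=0.0,
                           n_output=4096)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            w = simulate(net, inflow, s,
                         probes=[Probe("p", 0.5, "mid"),
                                 Probe("p.1", 0.5, "d1"), Probe("p.2", 0.5, "d2")])
        P, t = w.sites["mid"]["P"], w.time
        incident = P[(t > 0.0) & (t < 0.14)].max()
        reflected = np.abs(P[(t > 0.15) & (t < 0.26)]).max()
        assert reflected / incident < 1e-3
        # perfect symmetry of the daughters
        assert np.array_equal(w.sites["d1"]["Q"], w.sites["d2"]["Q"])

    def test_windkessel_outlet_reflection_coefficient(self):
        """With the capacitor branch effectively removed the outlet is a
        resistor R_total and the reflected/incident peak ratio follows the
        linear coefficient (R_total - Z0)/(R_total + Z0) within 5%."""
        g = GlobalParams(mu=1e-12)
        seg = ArterialSegment.from_pwv("v", 1.0, 0.005, 0.005, 5.0, 5.0, rho=g.rho)
        z0 = float(seg.char_impedance(1.0, g.rho))
        inflow = gaussian_pulse_inflow(0.6, t0=0.05, sigma=0.015, amplitude=1e-6)
        for r_total, sign in [(3.0 * z0, 1.0), (0.5 * z0, -1.0)]:
            if r_total > z0:
                wk = Windkessel3(R1=z0, R2=r_total - z0, C=1e-13, p_out=0.0)
            else:
                wk = Windkessel3(R1=0.0, R2=r_total, C=1e-13, p_out=0.0)
            net = ArterialNetwork({"v": seg}, {"v": None}, {"v": wk}, g)
            s = SolverSettings(dx=0.004, max_cycles=1, initial_pressure=0.0,
                               n_output=4096)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                w = simulate(net, inflow, s, probes=[Probe("v", 0.8, "a")])
            P, t = w.sites["a"]["P"], w.time
            incident = P[(t > 0.1) & (t < 0.26)].max()
            window = P[(t > 0.27) & (t < 0.45)]
            reflected = window[np.argmax(np.abs(window))]
            predicted = (r_total - z0) / (r_total + z0)
            assert reflected / incident == pytest.approx(predicted, rel=0.05)

    def test_grid_convergence_order(self):
        """Halving the cell size reduces the smooth-pulse error at a rate
        consistent with at least order 1.5."""
        g = GlobalParams(mu=1e-12)
        seg = ArterialSegment.from_pwv("v", 1.0, 0.005, 0.005, 5.0, 5.0, rho=g.rho)
        z0 = float(seg.char_impedance(1.0, g.rho))
        wk = Windkessel3(R1=z0, R2=1e10, C=1e-6, p_out=0.0)
        net = ArterialNetwork({"v": seg}, {"v": None}, {"v": wk}, g)
        inflow = gaussian_pulse_inflow(0.4, t0=0.05, sigma=0.015, amplitude=1e-6)
        sols = {}
        for dx in (0.02, 0.01, 0.005):
            s = SolverSettings(dx=dx, max_cycles=1, initial_pressure=0.0,
                               n_output=2048)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                w = simulate(net, inflow, s, probes=[Probe("v", 0.5, "m")])
            mask = (w.time > 0.08) & (w.time < 0.22)
            sols[dx] = w.sites["m"]["P"][mask]
        e_coarse = np.sqrt(np.mean((sols[0.02] - sols[0.01]) ** 2))
        e_fine = np.sqrt(np.mean((sols[0.01] - sols[0.005]) ** 2))
        assert np.log2(e_coarse / e_fine) >= 1.5


class TestPeriodicCycle:
    def test_inlet_flow_matches_prescription_and_volume_balances(self):
        net = pr.make_tree(pr.FixtureSpec(kind="bifurcation"))
        inflow = pr.make_inflow(1.0, 70e-6, 0.3)
        wk = pr.reduce_to_windkessel(net)
        s = SolverSettings(dx=0.005, max_cycles=25, periodicity_tol=1e-5,
                           initial_pressure=wk.R * inflow.mean_flow())
        w = simulate(net, inflow, s, probes=[Probe("parent", 0.0, "in")])
        assert w.converged
        # prescribed inflow reproduced at the inlet
        q_expect = np.asarray(inflow(w.time), float)
        err = np.max(np.abs(w.sites["in"]["Q"] - q_expect)) / q_expect.max()
        assert err < 5e-3
        # global volume balance over the converged cycle
        assert w.diagnostics["volume_balance"] < 1e-3

    def test_mean_pressure_identity(self):
        """At the periodic state, mean(p_in) - p_hat = R_net mean(q_in)
        within 1% (time-average of the linearized balance)."""
        g = GlobalParams()
        seg = ArterialSegment.from_pwv("v", 0.1, 0.01, 0.0095, 4.5, 4.7, rho=g.rho)
        z0 = float(seg.char_impedance(0.1, g.rho))
        wk = Windkessel3(R1=z0, R2=1.4e8 - z0, C=2e-9, p_out=400.0)
        net = ArterialNetwork({"v": seg}, {"v": None}, {"v": wk}, g)
        inflow = pr.make_inflow(1.0, 70e-6, 0.3)
        r_net = pr.vessel_rc(seg, g).R_v + wk.R1 + wk.R2
        s = SolverSettings(max_cycles=30, periodicity_tol=1e-6,
                           initial_pressure=400.0 + r_net * inflow.mean_flow())
        w = simulate(net, inflow, s, probes=[Probe("v", 0.0, "in")])
        assert w.converged
        mean_p = np.trapezoid(w.sites["in"]["P"], w.time) / inflow.period
        assert mean_p - 400.0 == pytest.approx(r_net * inflow.mean_flow(), rel=0.01)

    def test_nonconvergence_is_flagged(self):
        net = pr.make_tree(pr.FixtureSpec(kind="single-vessel"))
        inflow = pr.make_inflow(1.0, 70e-6, 0.3)
        s = SolverSettings(max_cycles=2, periodicity_tol=1e-12,
                           initial_pressure=0.0)
        with pytest.warns(ConvergenceWarning):
            w = simulate(net, inflow, s)
        assert not w.converged
        assert w.cycles_run == 2


class TestSettingsValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(cfl=0.0), dict(cfl=1.5), dict(max_cycles=0),
        dict(periodicity_tol=0.0),
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverSettings(**kwargs)

    def test_collapse_initial_pressure_rejected(self):
        net = pr.make_tree(pr.FixtureSpec(kind="single-vessel"))
        inflow = pr.make_inflow(1.0, 70e-6, 0.3)
        s = SolverSettings(max_cycles=1, initial_pressure=-1e9)
        with pytest.raises(SolverError):
            simulate(net, inflow, s)
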