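"""Lumped-parameter network: construction, simulation, metrics, sweeps."""

import numpy as np
import pytest

from placenta_vasomech import synthetic, windkessel as wk
from placenta_vasomech.waveforms import PeriodicWaveform, PressureWaveform


def constant_inlet(value, period=0.43, n=50):
    t = period * np.arange(n) / n
    return PressureWaveform(t=t, p=np.full(n, float(value)), period=period)


class TestNetworkConstruction:
    def test_default_has_23_compartments_in_order(self, default_network):
        kinds = [c.kind for c in default_network.compartments]
        assert len(kinds) == 23
        assert kinds[0] == "umbilical_artery"
        assert kinds[1:11] == ["placental_artery"] * 10
        assert kinds[11] == "microvilli"
        assert kinds[12:22] == ["placental_vein"] * 10
        assert kinds[22] == "umbilical_vein"

    def test_explicit_rc_lists_echoed(self):
        R = list(np.linspace(0.1, 2.3, 23))
        C = list(np.linspace(1e-5, 1e-3, 23))
        net = wk.build_default_network(R=R, C=C)
        assert np.allclose(net.R, R)
        assert np.allclose(net.C, C)

    def test_arterial_resistance_exceeds_venous(self, default_network):
        comps = default_network.compartments
        art = sum(c.R for c in comps if "artery" in c.kind)
        ven = sum(c.R for c in comps if "vein" in c.kind)
        assert art > ven

    def test_microvilli_dominate_resistance(self, default_network):
        mv = next(c for c in default_network.compartments
                  if c.kind == "microvilli")
        assert mv.R >= 0.5 * default_network.total_resistance

    def test_halving_radii_scales_poiseuille_by_16(self):
        a = wk.build_default_network(wk.NetworkConfig())
        b = wk.build_default_network(wk.NetworkConfig(
            umbilical_artery_radius=1.0, first_artery_radius=0.75))
        vessel = [i for i, c in enumerate(a.compartments)
                  if c.kind != "microvilli"]
        assert np.allclose(b.R[vessel] / a.R[vessel], 16.0, rtol=1e-9)


class TestPressureScaling:
    def test_unit_shape_maps_to_target_range(self):
        shape = synthetic.gen_doppler_waveform(
            synthetic.WaveformConfig(target_RI=0.6))
        for sys_p, dia_p in ((50.0, 25.0), (80.0, 25.0)):
            p = wk.scale_pressure_waveform(shape, sys_p, dia_p)
            assert p.p.max() == pytest.approx(sys_p)
            assert p.p.min() == pytest.approx(dia_p)

    def test_constant_shape_constant_target_ok(self):
        shape = PeriodicWaveform(t=np.linspace(0, 0.9, 10, endpoint=False),
                                 v=np.ones(10), period=1.0)
        p = wk.scale_pressure_waveform(shape, 30.0, 30.0)
        assert np.all(p.p == 30.0)

    def test_constant_shape_pulsatile_target_raises(self):
        shape = PeriodicWaveform(t=np.linspace(0, 0.9, 10, endpoint=False),
                                 v=np.ones(10), period=1.0)
        with pytest.raises(ValueError, match="constant shape"):
            wk.scale_pressure_waveform(shape, 50.0, 25.0)


class TestSimulate:
    def test_equilibrium_at_venous_pressure(self, default_network):
        pv = default_network.venous_pressure
        sim = wk.simulate(default_network, constant_inlet(pv))
        assert np.allclose(sim.P, pv, atol=1e-9)
        assert np.allclose(sim.Q_R, 0.0, atol=1e-12)

    def test_ohmic_steady_state(self):
        R = [10.0 / 23.0] * 23
        C = [1e-4] * 23
        net = wk.build_default_network(R=R, C=C)
        sim = wk.simulate(net, constant_inlet(50.0))
        expected = (50.0 - 5.3) / 10.0
        assert np.allclose(sim.Q_R, expected, rtol=1e-6)

    def test_rc_relaxation_time_constant(self):
        """Step response of a near-terminal RC compartment decays with
        time constant R*C (log-linear fit within 1%)."""
        comps = [
            wk.Compartment(label="rc", generation=1,
                           kind="umbilical_artery", R=1.0, C=0.5),
            wk.Compartment(label="out", generation=2,
                           kind="umbilical_vein", R=1000.0, C=0.5),
        ]
        net = wk.WindkesselNetwork(comps, venous_pressure=0.0)
        t, P = wk.transient_response(net, lambda _: 10.0, 5.0, 5000)
        P1 = P[0]
        P_inf = 10.0 * 1000.0 / 1001.0
        mask = (t > 0.05) & (t < 2.0)
        slope = np.polyfit(t[mask], np.log(P_inf - P1[mask]), 1)[0]
        assert -1.0 / slope == pytest.approx(1.0 * 0.5, rel=0.01)

    def test_periodic_mass_balance(self, default_network, normal_inlet):
        """At the periodic steady state every capacitor's net cycle flux is
        zero, so the cycle-mean flow is identical through all resistors."""
        sim = wk.simulate(default_network, normal_inlet)
        T = normal_inlet.period
        qc_mean = np.trapezoid(sim.Q_C, sim.t, axis=1) / T
        qr_mean = np.trapezoid(sim.Q_R, sim.t, axis=1) / T
        mean_flow = qr_mean[0]
        assert np.all(np.abs(qc_mean) < 1e-6 * abs(mean_flow))
        assert np.ptp(qr_mean) < 1e-6 * abs(mean_flow)

    def test_analytic_mean_flow(self, default_network, normal_inlet):
        sim = wk.simulate(default_network, normal_inlet)
        m = wk.flow_metrics(sim.t, sim.umbilical_flow)
        pbar = normal_inlet.as_periodic().mean()
        expected = (pbar - default_network.venous_pressure) \
            / default_network.total_resistance
        assert m.mean_flow == pytest.approx(expected, rel=1e-3)

    def test_nonconvergence_raises_with_trace(self, default_network,
                                              normal_inlet):
        with pytest.raises(RuntimeError, match="convergence trace"):
            wk.simulate(default_network.scaled(4.0, 64.0), normal_inlet,
                        max_cycles=2)


class TestFlowMetrics:
    def test_constant_flow(self):
        t = np.linspace(0, 1, 100)
        m = wk.flow_metrics(t, np.full(100, 2.0))
        assert (m.RI, m.PI, m.peak_backflow) == (0.0, 0.0, 0.0)

    def test_sinusoid_closed_form(self):
        t = np.linspace(0.0, 1.0, 2001)
        q = 2.0 + np.sin(2 * np.pi * t)
        m = wk.flow_metrics(t, q)
        assert m.RI == pytest.approx(2.0 / 3.0, abs=1e-6)
        assert m.PI == pytest.approx(1.0, rel=1e-4)
        assert m.mean_flow == pytest.approx(2.0, rel=1e-4)

    def test_peak_backflow_magnitude(self):
        t = np.linspace(0.0, 1.0, 1001)
        q = 1.0 + 1.5 * np.sin(2 * np.pi * t)
        assert wk.flow_metrics(t, q).peak_backflow == pytest.approx(0.5,
                                                                    abs=1e-3)

    def test_no_forward_flow_raises(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError, match="forward"):
            wk.flow_metrics(t, -np.ones(10))

    def test_index_identity(self):
        t = np.linspace(0.0, 1.0, 1001)
        q = 2.0 + np.sin(2 * np.pi * t) ** 3
        m = wk.flow_metrics(t, q)
        assert m.PI * m.mean_flow == pytest.approx(m.RI * q.max(), rel=1e-9)


class TestFitMultipliers:
    def test_identity_recovery(self, default_network, normal_inlet):
        sim = wk.simulate(default_network, normal_inlet)
        target = PeriodicWaveform(t=sim.t[:-1], v=sim.umbilical_flow[:-1],
                                  period=normal_inlet.period)
        fit = wk.fit_multipliers(default_network, normal_inlet, target)
        assert fit.k_R == pytest.approx(1.0, rel=0.01)
        assert fit.k_C == pytest.approx(1.0, rel=0.01)

    def test_self_generated_recovery(self, default_network, normal_inlet):
        sim = wk.simulate(default_network.scaled(2.0, 3.0), normal_inlet)
        target = PeriodicWaveform(t=sim.t[:-1], v=sim.umbilical_flow[:-1],
                                  period=normal_inlet.period)
        fit = wk.fit_multipliers(default_network, normal_inlet, target)
        assert fit.k_R == pytest.approx(2.0, rel=0.02)
        assert fit.k_C == pytest.approx(3.0, rel=0.02)

    def test_period_mismatch_raises(self, default_network, normal_inlet):
        bad = PeriodicWaveform(t=np.linspace(0, 0.9, 10, endpoint=False),
                               v=np.ones(10), period=1.0)
        with pytest.raises(ValueError, match="period"):
            wk.fit_multipliers(default_network, normal_inlet, bad)


class TestSweep:
    def test_single_point_grid_equals_single_run(self, default_network,
                                                 normal_inlet):
        sw = wk.sweep(default_network, normal_inlet, np.array([1.0]),
                      np.array([1.0]))
        sim = wk.simulate(default_network, normal_inlet)
        m = wk.flow_metrics(sim.t, sim.umbilical_flow)
        assert sw.mean_flow[0, 0] == pytest.approx(m.mean_flow, rel=1e-9)
        assert sw.RI[0, 0] == pytest.approx(m.RI, rel=1e-9)

    def test_mean_flow_tracks_resistance_not_compliance(self,
                                                        default_network,
                                                        normal_inlet):
        r = np.array([0.5, 1.0, 2.0])
        c = np.array([0.5, 1.0, 2.0])
        sw = wk.sweep(default_network, normal_inlet, r, c)
        # inverse in k_R
        assert np.all(np.diff(sw.mean_flow, axis=0) < 0)
        # flat in k_C
        rel_var = np.abs(sw.mean_flow / sw.mean_flow[:, :1] - 1.0)
        assert rel_var.max() < 1e-4

    def test_grid_validation(self, default_network, normal_inlet):
        with pytest.raises(ValueError, match="positive"):
            wk.sweep(default_network, normal_inlet, np.array([-1.0]),
                     np.array([1.0]))
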