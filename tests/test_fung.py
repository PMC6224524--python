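"""Constitutive model: kinematics, stresses, equilibrium pressure, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placenta_vasomech import fung


class TestKinematics:
    def test_identity_deformation_without_residual_stress(self):
        geom = fung.StressFreeGeometry(R_i=0.5, R_o=1.0, opening_angle=0.0)
        kin = fung.kinematics(geom, r_i=0.5, lambda_z=1.0)
        R = np.linspace(0.5, 1.0, 11)
        assert np.allclose(kin.r(R), R, atol=1e-14)
        assert np.allclose(kin.lambda_theta(R), 1.0, atol=1e-14)
        assert np.allclose(kin.lambda_r(R), 1.0, atol=1e-14)

    @pytest.mark.parametrize("oa,lz,ri", [(0.0, 1.0, 0.5), (91.48, 1.1, 0.4),
                                          (180.0, 1.2, 0.7)])
    def test_incompressibility_closure(self, oa, lz, ri):
        geom = fung.StressFreeGeometry(R_i=0.5, R_o=1.0, opening_angle=oa)
        kin = fung.kinematics(geom, r_i=ri, lambda_z=lz)
        lhs = geom.k * lz * (kin.r_o ** 2 - ri ** 2)
        assert lhs == pytest.approx(geom.R_o ** 2 - geom.R_i ** 2, abs=1e-9)

    def test_residual_strain_gradient_across_wall(self, normal_geometry,
                                                  normal_params):
        """In the closed, unloaded (self-equilibrated) configuration the
        inner face is circumferentially compressed and the outer face
        stretched — the hallmark of opening-angle residual stress."""
        ri0 = fung.zero_pressure_inner_radius(normal_geometry, normal_params,
                                              1.1)
        kin = fung.kinematics(normal_geometry, r_i=ri0, lambda_z=1.1)
        lt_in = kin.lambda_theta(normal_geometry.R_i)
        lt_out = kin.lambda_theta(normal_geometry.R_o)
        assert lt_in < 1.0 < lt_out
        assert lt_in < lt_out

    def test_point_volume_conservation(self, normal_geometry):
        kin = fung.kinematics(normal_geometry, r_i=0.4, lambda_z=1.1)
        R = np.linspace(normal_geometry.R_i, normal_geometry.R_o, 7)
        J = kin.lambda_r(R) * kin.lambda_theta(R) * 1.1
        assert np.allclose(J, 1.0, atol=1e-12)


class TestStrainEnergy:
    def test_zero_strain_zero_energy(self):
        p = fung.FungParameters(c=100.0, b1=10.0)
        state = fung.StrainState(1.0, 1.0, 1.0)
        assert fung.strain_energy(p, state) == 0.0

    def test_closed_form_value(self):
        # c=2, b1=1, E_theta=1 (lambda_theta = sqrt(3)), others free to
        # satisfy incompressibility: pick lambda_z = 1/sqrt(3), lambda_r = 1
        lt, lz = math.sqrt(3.0), 1.0 / math.sqrt(3.0)
        state = fung.StrainState(1.0 / (lt * lz), lt, lz)
        p = fung.FungParameters(c=2.0, b1=1.0)
        Q = state.E_theta ** 2 + state.E_z ** 2 + state.E_r ** 2
        assert fung.strain_energy(p, state) == pytest.approx(math.expm1(Q))

    def test_overflow_guard(self):
        p = fung.FungParameters(c=1.0, b1=1e6)
        state = fung.StrainState.from_plane(1.4, 1.1)
        with pytest.raises(OverflowError):
            fung.strain_energy(p, state)

    def test_positive_away_from_reference(self):
        p = fung.FungParameters(c=50.0, b1=5.0)
        assert fung.strain_energy(p, fung.StrainState.from_plane(1.2, 1.0)) > 0


class TestStressDifference:
    def test_zero_at_reference(self):
        p = fung.FungParameters(c=100.0, b1=10.0)
        assert fung.stress_difference(p, fung.StrainState(1, 1, 1)) == 0.0

    def test_zero_for_equibiaxial_in_plane(self):
        # lambda_theta = lambda_r requires lambda_z = 1/lambda^2
        lam = 1.1
        state = fung.StrainState(lam, lam, 1.0 / lam ** 2)
        p = fung.FungParameters(c=100.0, b1=10.0)
        assert fung.stress_difference(p, state) == pytest.approx(0.0, abs=1e-12)

    @given(lt=st.floats(0.8, 1.4), lz=st.floats(0.9, 1.25),
           c=st.floats(10.0, 400.0), b1=st.floats(1.0, 30.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_finite_difference_of_energy(self, lt, lz, c, b1):
        """sigma_theta - sigma_r equals the work-conjugate combination of
        numerical dW/dE within 1e-6 relative."""
        state = fung.StrainState.from_plane(lt, lz)
        p = fung.FungParameters(c=c, b1=b1)

        def W(Et, Ez, Er):
            return c / 2.0 * math.expm1(b1 * (Et ** 2 + Ez ** 2 + Er ** 2))

        h = 1e-6
        Et, Ez, Er = state.E_theta, state.E_z, state.E_r
        dWdEt = (W(Et + h, Ez, Er) - W(Et - h, Ez, Er)) / (2 * h)
        dWdEr = (W(Et, Ez, Er + h) - W(Et, Ez, Er - h)) / (2 * h)
        oracle = state.lambda_theta ** 2 * dWdEt - state.lambda_r ** 2 * dWdEr
        got = fung.stress_difference(p, state)
        assert got == pytest.approx(oracle, rel=1e-6, abs=1e-9)


class TestLuminalPressure:
    def test_stress_free_state_zero_pressure(self):
        geom = fung.StressFreeGeometry(R_i=0.5, R_o=1.0, opening_angle=0.0)
        p = fung.FungParameters(c=100.0, b1=10.0)
        assert fung.luminal_pressure(geom, p, 0.5, 1.0) == \
            pytest.approx(0.0, abs=1e-12)

    def test_quadrature_convergence(self, normal_geometry, normal_params):
        P1 = fung.luminal_pressure(normal_geometry, normal_params, 0.45, 1.1,
                                   n_points=200)
        P2 = fung.luminal_pressure(normal_geometry, normal_params, 0.45, 1.1,
                                   n_points=400)
        assert P2 == pytest.approx(P1, rel=1e-6)

    def test_against_brute_force_trapezoid(self, normal_geometry,
                                           normal_params):
        """Gauss quadrature agrees with a 1e5-point trapezoid oracle
        integrating (sigma_theta - sigma_r)/r over the deformed wall."""
        geom, params, lz = normal_geometry, normal_params, 1.1
        ri0 = fung.zero_pressure_inner_radius(geom, params, lz)
        ro0 = fung._outer_radius(geom, ri0, lz)
        ro = 1.2 * ro0  # outer stretch 1.2
        ri = math.sqrt(ro ** 2 - (geom.R_o ** 2 - geom.R_i ** 2)
                       / (geom.k * lz))
        r = np.linspace(ri, ro, 100_001)
        R = np.sqrt(geom.R_i ** 2 + geom.k * lz * (r ** 2 - ri ** 2))
        lt = geom.k * r / R
        lr = 1.0 / (lt * lz)
        Et, Er, Ez = (lt ** 2 - 1) / 2, (lr ** 2 - 1) / 2, (lz ** 2 - 1) / 2
        Q = params.b1 * (Et ** 2 + Er ** 2 + Ez ** 2)
        sd = params.c * params.b1 * np.exp(Q) * (lt ** 2 * Et - lr ** 2 * Er)
        oracle = np.trapezoid(sd / r, r)
        got = fung.luminal_pressure(geom, params, ri, lz)
        assert got == pytest.approx(oracle, rel=1e-5)

    def test_monotone_in_inner_radius(self, normal_geometry, normal_params):
        ri = np.linspace(0.30, 0.60, 30)
        P = fung._pressures(normal_geometry, normal_params.c,
                            normal_params.b1, ri, 1.1)
        assert np.all(np.diff(P) > 0)


class TestForwardCurve:
    def test_zero_pressure_unit_stretch(self, normal_curve):
        assert normal_curve.P_grid[0] == 0.0
        assert normal_curve.lam[0] == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing_stretch(self, normal_curve):
        assert np.all(np.diff(normal_curve.lam) > 0)

    def test_small_strain_pressure_linear_in_c(self, normal_geometry):
        """Doubling c doubles the pressure at fixed stretch (<= 2% when the
        stretch is small)."""
        lz = 1.1
        p1 = fung.FungParameters(c=125.82, b1=20.63)
        p2 = fung.FungParameters(c=2 * 125.82, b1=20.63)
        ri0 = fung.zero_pressure_inner_radius(normal_geometry, p1, lz)
        ro0 = fung._outer_radius(normal_geometry, ri0, lz)
        ro = 1.01 * ro0
        ri = math.sqrt(ro ** 2 - (normal_geometry.R_o ** 2
                                  - normal_geometry.R_i ** 2)
                       / (normal_geometry.k * lz))
        P1 = fung.luminal_pressure(normal_geometry, p1, ri, lz)
        P2 = fung.luminal_pressure(normal_geometry, p2, ri, lz)
        assert P2 / P1 == pytest.approx(2.0, rel=0.02)

    def test_grid_validation(self, normal_geometry, normal_params):
        with pytest.raises(ValueError):
            fung.forward_curve(normal_geometry, normal_params, 1.1,
                               P_grid=np.array([0.0, 70.0]))


class TestFitFung:
    @pytest.mark.parametrize("c,b1", [(125.82, 20.63), (99.91, 26.83),
                                      (345.65, 8.56)])
    def test_noiseless_round_trip_recovery(self, normal_geometry, c, b1):
        """Each group's generating parameters are recovered within 1% from
        the noiseless forward curve, with near-perfect goodness of fit."""
        truth = fung.FungParameters(c=c, b1=b1)
        curve = fung.forward_curve(normal_geometry, truth, 1.1)
        fit = fung.fit_fung(curve, normal_geometry, 1.1)
        assert fit.params.c == pytest.approx(c, rel=0.01)
        assert fit.params.b1 == pytest.approx(b1, rel=0.01)
        assert fit.r_squared >= 0.988
        assert fit.converged

    def test_multistart_beats_grid_search(self, normal_geometry, normal_curve):
        """A brute-force grid over the whole start box never finds a lower
        objective than the multistart Nelder-Mead solution."""
        fit = fung.fit_fung(normal_curve, normal_geometry, 1.1)
        objective = fung._fit_objective(
            normal_geometry, 1.1, normal_curve.lam, normal_curve.P_grid, 200)
        cs = np.geomspace(10.0, 1000.0, 60)
        b1s = np.geomspace(1.0, 60.0, 60)
        grid_best = min(objective([math.log(c), math.log(b)])
                        for c in cs for b in b1s)
        assert grid_best >= fit.sse - 1e-9

    def test_rejects_short_curves(self, normal_geometry):
        from placenta_vasomech.pd_mechanics import PressureStretchCurve
        short = PressureStretchCurve(P_grid=np.arange(0.0, 8.0),
                                     lam=1.0 + 0.001 * np.arange(8.0))
        with pytest.raises(ValueError, match="30 mmHg"):
            fung.fit_fung(short, normal_geometry, 1.1)


class TestValidation:
    @pytest.mark.parametrize("kwargs", [
        {"R_i": -0.1, "R_o": 1.0}, {"R_i": 1.0, "R_o": 0.5},
        {"R_i": 0.5, "R_o": 1.0, "opening_angle": 360.0},
    ])
    def test_geometry_invariants(self, kwargs):
        with pytest.raises(ValueError):
            fung.StressFreeGeometry(**kwargs)

    def test_parameters_must_be_positive(self):
        with pytest.raises(ValueError):
            fung.FungParameters(c=-1.0, b1=10.0)

    def test_strain_state_incompressibility_enforced(self):
        with pytest.raises(ValueError, match="incompressib"):
            fung.StrainState(1.0, 1.1, 1.0)
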