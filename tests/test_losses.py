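"""Six-term loss operators, superposition and the cumulative pressure field."""

import numpy as np
import pytest

from ctffr.fluid import Fluid
from ctffr.geometry import SegmentFeatures
from ctffr.losses import (CorrectionFactors, element_pressure_drop,
                          friction_coefficient, loss_bend, loss_bifurcation,
                          loss_constriction, loss_convection, loss_diffusion,
                          loss_expansion, pressure_profile, zeta_bend,
                          zeta_constriction, zeta_expansion)
from conftest import straight_tube

FLUID = Fluid()  # rho = 1050, mu = 3.5e-3
UNIT_C = CorrectionFactors(1, 1, 1, 1, 1, 1)


def seg(l=3e-4, d1=3e-3, d2=3e-3, theta_b=0.0, R_bend=np.inf, post_bif=False):
    tc, te = (0.0, 0.0)
    if d1 != d2:
        theta = np.degrees(2 * np.arctan(abs(d1 - d2) / (2 * l)))
        tc, te = (theta, 0.0) if d2 < d1 else (0.0, theta)
    return SegmentFeatures(l=l, d_mean=(d1 + d2) / 2,
                           A1=np.pi * d1 ** 2 / 4, A2=np.pi * d2 ** 2 / 4,
                           theta_c=tc, theta_e=te, theta_b=theta_b,
                           R_bend=R_bend, is_post_bifurcation=post_bif)


class TestFrictionCoefficient:
    def test_laminar_definition(self):
        assert friction_coefficient(64.0) == 1.0
        assert friction_coefficient(160.0) == pytest.approx(0.4)

    def test_nonpositive_re_rejected(self):
        with pytest.raises(ValueError):
            friction_coefficient(0.0)


class TestDiffusion:
    def test_zero_flow_zero_loss(self):
        assert loss_diffusion(seg(), 0.0, 1.0, FLUID) == 0.0

    def test_poiseuille_closed_form(self):
        # l = 10 mm, d = 3 mm, U = 0.15 m/s -> 32*mu*l*U/d^2 = 18.67 Pa
        f = seg(l=1e-2)
        dp = loss_diffusion(f, 0.15, 1.0, FLUID)
        assert dp == pytest.approx(32 * 3.5e-3 * 1e-2 * 0.15 / 9e-6, rel=1e-12)
        assert dp == pytest.approx(18.6667, rel=1e-4)

    def test_packaged_factor_scales(self):
        f = seg(l=1e-2)
        assert loss_diffusion(f, 0.15, 0.4544, FLUID) == pytest.approx(
            0.4544 * 18.66667, rel=1e-4)


class TestConstriction:
    def test_no_area_change_no_loss(self):
        assert loss_constriction(seg(), 0.2, 0.2, 1.0, FLUID) == 0.0

    def test_table_formula_value(self):
        # theta_c = 20 deg, lambda = 0.2, A2/A1 = 0.5
        z = zeta_constriction(20.0, 0.2, 0.5)
        assert z == pytest.approx(0.2 / (8 * np.sin(np.radians(10.0))) * 0.75,
                                  rel=1e-12)
        assert z == pytest.approx(0.10797, rel=1e-4)
        dp = 1.0 * 1050.0 * z * 0.2 ** 2 / 2
        assert dp == pytest.approx(2.267, rel=1e-3)

    def test_piecewise_branch_adds_degrees_over_1000(self):
        z30 = zeta_constriction(40.0, 0.2, 0.5)
        base = 0.2 / (8 * np.sin(np.radians(20.0))) * 0.75
        assert z30 == pytest.approx(base + 0.04, rel=1e-12)

    def test_step_beyond_90_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            z = zeta_constriction(120.0, 0.2, 0.5)
        assert z == pytest.approx(zeta_constriction(89.999, 0.2, 0.5), rel=1e-3)


class TestExpansion:
    def test_equal_areas_no_loss(self):
        assert loss_expansion(seg(), 0.2, 0.3, 1.0, FLUID) == 0.0

    def test_table_formula_value(self):
        # theta_e = 30 deg, lambda = 0.3, A1/A2 = 0.5
        z = zeta_expansion(30.0, 0.3, 0.5)
        expected = 0.3 / (8 * np.sin(np.radians(15.0))) * 0.75 + 0.5 * 0.25
        assert z == pytest.approx(expected, rel=1e-12)
        assert z == pytest.approx(0.23366, rel=1e-4)

    def test_zero_velocity_zero_loss(self):
        f = seg(d1=2e-3, d2=3e-3)
        assert loss_expansion(f, 0.0, 0.3, 1.0, FLUID) == 0.0


class TestBifurcationAndBend:
    def test_bifurcation_values(self):
        assert loss_bifurcation(0.0, 0.0025, FLUID) == 0.0
        assert loss_bifurcation(0.2, 0.0025, FLUID) == pytest.approx(
            0.0025 * 1050 * 0.1 * 0.04 / 2, rel=1e-12)  # 5.25e-3 Pa

    def test_bend_straight_is_zero(self):
        assert loss_bend(seg(theta_b=0.0), 0.2, 1.0, FLUID) == 0.0

    def test_bend_no_curvature_term_at_infinite_radius(self):
        assert zeta_bend(45.0, 3e-3, np.inf) == pytest.approx(0.131 * 0.5)

    def test_bend_with_curvature(self):
        z = zeta_bend(90.0, 1.0, 2.0)  # d/R = 0.5
        assert z == pytest.approx(0.131 + 0.163 * 0.5 ** 3.5, rel=1e-12)
        assert z == pytest.approx(0.14541, rel=1e-4)


class TestConvection:
    def test_no_velocity_change(self):
        assert loss_convection(0.2, 0.2, 0.9138, FLUID) == 0.0

    def test_recovery_is_negative(self):
        dp = loss_convection(0.3, 0.1, 0.9138, FLUID)
        assert dp == pytest.approx(0.9138 * 1050 * (0.01 - 0.09) / 2, rel=1e-12)
        assert dp == pytest.approx(-38.38, rel=1e-3)

    def test_acceleration_is_positive(self):
        assert loss_convection(0.0, 0.2, 1.0, FLUID) == pytest.approx(21.0)


class TestElementSuperposition:
    def test_zero_flow_all_terms_zero(self):
        lb = element_pressure_drop(seg(d1=3e-3, d2=2.8e-3, theta_b=10.0), 0.0,
                                   UNIT_C, FLUID)
        assert lb.dP_total == 0.0

    def test_uniform_straight_is_pure_poiseuille(self):
        f = seg(l=1e-2)
        Q = 0.15 * f.A1
        lb = element_pressure_drop(f, Q, UNIT_C, FLUID)
        assert lb.dP_constriction == lb.dP_expansion == 0.0
        assert lb.dP_bend == lb.dP_bifurcation == lb.dP_convection == 0.0
        assert lb.dP_total == pytest.approx(128 * 3.5e-3 * 1e-2 * Q
                                            / (np.pi * (3e-3) ** 4), rel=1e-12)

    def test_tapering_element_breakdown_sums_to_total(self):
        f = seg(l=5e-4, d1=3e-3, d2=2.6e-3, theta_b=5.0, R_bend=2e-2)
        lb = element_pressure_drop(f, 2e-6, UNIT_C, FLUID)
        assert lb.dP_constriction > 0 and lb.dP_diffusion > 0
        assert lb.dP_convection > 0  # narrowing accelerates the flow
        parts = (lb.dP_diffusion + lb.dP_constriction + lb.dP_expansion
                 + lb.dP_bifurcation + lb.dP_bend + lb.dP_convection)
        assert lb.dP_total == parts  # exact superposition

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            element_pressure_drop(seg(), -1e-6, UNIT_C, FLUID)

    def test_minor_losses_scale_quadratically(self):
        # gentle taper keeps theta_c < 30 deg (no additive piecewise term)
        f = seg(l=5e-4, d1=3e-3, d2=2.9e-3, theta_b=5.0, R_bend=2e-2,
                post_bif=True)
        lb1 = element_pressure_drop(f, 1e-6, UNIT_C, FLUID)
        lb2 = element_pressure_drop(f, 2e-6, UNIT_C, FLUID)
        # lambda ~ 1/U makes viscous-scaled terms linear in Q
        for name in ("dP_diffusion", "dP_constriction"):
            assert getattr(lb2, name) == pytest.approx(
                2 * getattr(lb1, name), rel=1e-12)
        # constant-coefficient minor losses are quadratic in Q
        for name in ("dP_bifurcation", "dP_bend", "dP_convection"):
            assert getattr(lb2, name) == pytest.approx(
                4 * getattr(lb1, name), rel=1e-12)


class TestPressureProfile:
    def test_lossless_pressure_constant(self, y_tree):
        C0 = CorrectionFactors(0, 0, 0, 0, 0, 0)
        q = {"b0": 2e-6, "b0.0": 1e-6, "b0.1": 1e-6}
        p = pressure_profile(y_tree, q, 12000.0, C0)
        for arr in p.values():
            assert np.all(arr == 12000.0)

    def test_uniform_tube_matches_poiseuille_network(self, tube):
        Q = 1.5e-6
        C = CorrectionFactors(1, 0, 0, 0, 0, 0)
        p = pressure_profile(tube, {"b0": Q}, 12000.0, C)["b0"]
        L = tube.root.length
        drop = 128 * 3.5e-3 * L * Q / (np.pi * (3e-3) ** 4)
        assert p[-1] == pytest.approx(12000.0 - drop, rel=1e-10)
        # linear gradient along the tube
        s = tube.root.arclengths()
        assert np.allclose(p, 12000.0 - drop * s / L, rtol=1e-10)

    def test_symmetric_daughters_identical(self, y_tree):
        q = {"b0": 2e-6, "b0.0": 1e-6, "b0.1": 1e-6}
        p = pressure_profile(y_tree, q, 12000.0, UNIT_C)
        assert np.allclose(p["b0.0"], p["b0.1"], rtol=1e-12)

    def test_monotone_nonincreasing_without_convection(self):
        tree = straight_tube(d_end=2.2e-3)  # tapering: constriction active
        C = CorrectionFactors(1, 1, 1, 1, 1, 0)
        p = pressure_profile(tree, {"b0": 2e-6}, 12000.0, C)["b0"]
        assert np.all(np.diff(p) <= 0)

    def test_inconsistent_flows_rejected(self, y_tree):
        with pytest.raises(ValueError, match="mass"):
            pressure_profile(y_tree, {"b0": 2e-6, "b0.0": 1.5e-6,
                                      "b0.1": 1e-6}, 12000.0, UNIT_C)
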