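"""Branch-flow solve, boundary residuals, FFR and loss reporting."""

import numpy as np
import pytest

from ctffr.fluid import BLOOD
from ctffr.losses import CorrectionFactors, DEFAULT_FACTORS
from ctffr.solver import (NotConvergedError, SolverOptions, boundary_residual,
                          branch_flows_from_outlets, compute_ffr,
                          loss_breakdown_report, results_frame, solve_flows)
from ctffr.units import mmhg_to_pa
from conftest import resistance_bc

C0 = CorrectionFactors(0, 0, 0, 0, 0, 0)
DIFFUSION_ONLY = CorrectionFactors(1, 0, 0, 0, 0, 0)


class TestBoundaryResidual:
    def test_lossless_closed_form_zero_residual(self, y_tree):
        bc = resistance_bc(y_tree)
        q_out = {k: (bc.P_inlet_hyper - bc.P_v) / bc.R_hyper[k]
                 for k in bc.outlet_ids}
        flows = branch_flows_from_outlets(y_tree, q_out)
        r = boundary_residual(y_tree, flows, C0, BLOOD, bc)
        assert all(abs(v) < 1e-9 for v in r.values())

    def test_overflow_gives_negative_residual(self, y_tree):
        bc = resistance_bc(y_tree)
        q_out = {k: (bc.P_inlet_hyper - bc.P_v) / bc.R_hyper[k]
                 for k in bc.outlet_ids}
        q_out["b0.0"] *= 1.1
        flows = branch_flows_from_outlets(y_tree, q_out)
        r = boundary_residual(y_tree, flows, C0, BLOOD, bc)
        assert r["b0.0"] < 0

    def test_symmetric_flows_equal_residuals(self, y_tree):
        bc = resistance_bc(y_tree)
        flows = branch_flows_from_outlets(y_tree, {"b0.0": 1e-6, "b0.1": 1e-6})
        r = boundary_residual(y_tree, flows, DEFAULT_FACTORS, BLOOD, bc)
        assert r["b0.0"] == pytest.approx(r["b0.1"], rel=1e-12)


class TestSolveFlows:
    def test_lossless_tree_matches_closed_form(self, y_tree):
        bc = resistance_bc(y_tree)
        state = solve_flows(y_tree, bc, C0, opts=SolverOptions(tol_mmHg=1e-8))
        assert state.converged
        for k in bc.outlet_ids:
            expected = (bc.P_inlet_hyper - bc.P_v) / bc.R_hyper[k]
            assert state.branch_flows[k] == pytest.approx(expected, rel=1e-8)

    def test_single_tube_analytic_solution(self, tube):
        bc = resistance_bc(tube, R_hyper=2.4e9)
        L, d = tube.root.length, 3e-3
        R_tube = 128 * 3.5e-3 * L / (np.pi * d ** 4)
        expected = (bc.P_inlet_hyper - bc.P_v) / (R_tube + bc.R_hyper["b0"])
        state = solve_flows(tube, bc, DIFFUSION_ONLY,
                            opts=SolverOptions(tol_mmHg=1e-10))
        assert state.converged
        assert state.branch_flows["b0"] == pytest.approx(expected, rel=1e-8)

    def test_symmetric_bifurcation_equal_flows(self, y_tree):
        bc = resistance_bc(y_tree)
        state = solve_flows(y_tree, bc, DEFAULT_FACTORS)
        assert state.converged
        assert state.branch_flows["b0.0"] == pytest.approx(
            state.branch_flows["b0.1"], rel=1e-10)

    def test_mass_conservation_at_bifurcation(self, y_tree):
        bc = resistance_bc(y_tree)
        state = solve_flows(y_tree, bc, DEFAULT_FACTORS)
        assert state.branch_flows["b0"] == pytest.approx(
            state.branch_flows["b0.0"] + state.branch_flows["b0.1"],
            rel=1e-12)

    def test_residual_contract_on_convergence(self, y_tree):
        bc = resistance_bc(y_tree)
        opts = SolverOptions(tol_mmHg=1e-5)
        state = solve_flows(y_tree, bc, DEFAULT_FACTORS, opts=opts)
        assert state.converged
        assert state.max_residual_mmHg <= opts.tol_mmHg

    def test_deterministic_bit_identical(self, y_tree):
        bc = resistance_bc(y_tree)
        s1 = solve_flows(y_tree, bc, DEFAULT_FACTORS)
        s2 = solve_flows(y_tree, bc, DEFAULT_FACTORS)
        assert s1.branch_flows == s2.branch_flows
        for bid in y_tree.branches:
            assert np.array_equal(s1.pressures[bid], s2.pressures[bid])

    def test_nonconvergence_is_flagged(self, y_tree):
        bc = resistance_bc(y_tree)
        state = solve_flows(y_tree, bc, DEFAULT_FACTORS,
                            opts=SolverOptions(max_iter=1, tol_mmHg=1e-14))
        assert not state.converged


class TestFFR:
    def test_inlet_ffr_is_one(self, y_tree):
        bc = resistance_bc(y_tree)
        state = solve_flows(y_tree, bc, DEFAULT_FACTORS)
        ffr, _ = compute_ffr(state, bc)
        assert ffr["b0"][0] == pytest.approx(1.0, rel=1e-14)

    def test_lossless_ffr_is_one_everywhere(self, y_tree):
        bc = resistance_bc(y_tree)
        state = solve_flows(y_tree, bc, C0)
        ffr, at = compute_ffr(state, bc)
        for arr in ffr.values():
            assert np.allclose(arr, 1.0, atol=1e-12)
        assert all(v == pytest.approx(1.0) for v in at.values())

    def test_ratio_definition(self):
        assert mmhg_to_pa(67.5) / mmhg_to_pa(90.0) == pytest.approx(0.75)

    def test_ffr_bounded_without_convection(self, y_tree):
        bc = resistance_bc(y_tree)
        state = solve_flows(y_tree, bc,
                            CorrectionFactors(1, 1, 1, 1, 1, 0))
        ffr, _ = compute_ffr(state, bc)
        for arr in ffr.values():
            assert np.all(arr <= 1.0) and np.all(arr > 0.0)

    def test_unconverged_requires_force(self, y_tree):
        bc = resistance_bc(y_tree)
        state = solve_flows(y_tree, bc, DEFAULT_FACTORS,
                            opts=SolverOptions(max_iter=1, tol_mmHg=1e-14))
        with pytest.raises(NotConvergedError):
            compute_ffr(state, bc)
        ffr, _ = compute_ffr(state, bc, force=True)
        assert ffr

    def test_query_point_interpolation(self, tube):
        bc = resistance_bc(tube)
        state = solve_flows(tube, bc, DIFFUSION_ONLY)
        L = tube.root.length
        _, at = compute_ffr(state, bc, [("b0", L / 2)], tree=tube)
        ffr_full, _ = compute_ffr(state, bc)
        mid = (ffr_full["b0"][0] + ffr_full["b0"][-1]) / 2
        assert at[("b0", L / 2)] == pytest.approx(mid, rel=1e-6)


class TestLossReport:
    def test_lossless_all_zero(self, y_tree):
        bc = resistance_bc(y_tree)
        rep = loss_breakdown_report(solve_flows(y_tree, bc, C0))
        assert rep.total_mmHg == 0.0
        assert all(v == 0.0 for v in rep.totals_mmHg.values())

    def test_straight_tube_pure_diffusion(self, tube):
        bc = resistance_bc(tube)
        rep = loss_breakdown_report(solve_flows(tube, bc, DIFFUSION_ONLY))
        assert rep.fractions_percent["diffusion"] == pytest.approx(100.0)
        assert rep.stenosis_mmHg == 0.0

    def test_fractions_sum_to_100(self, y_tree):
        bc = resistance_bc(y_tree)
        rep = loss_breakdown_report(solve_flows(y_tree, bc, DEFAULT_FACTORS))
        assert sum(rep.fractions_percent.values()) == pytest.approx(100.0)

    def test_results_frame_columns(self, y_tree):
        bc = resistance_bc(y_tree)
        state = solve_flows(y_tree, bc, DEFAULT_FACTORS)
        df = results_frame(y_tree, state)
        assert len(df) == y_tree.total_points()
        for col in ("branch_id", "index", "arclength_m", "Q_m3_s", "U_m_s",
                    "P_mmHg", "FFR", "dP_diffusion_mmHg", "dP_convection_mmHg"):
            assert col in df.columns
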