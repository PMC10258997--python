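"""Iterative branch-flow solve against microvascular resistance boundaries.

Unknowns are the outlet (leaf-branch) flows only; every interior branch flow
is the sum of its descendant outlet flows, so mass conservation holds by
construction.  For a trial flow vector the per-point pressure field follows
from the six-term loss superposition, and the residual at outlet k is

    r_k = P_distal,k - (Q_k * R_hyper,k + P_v),

i.e. the mismatch between the 1D pressure delivered to the outlet and the
pressure demanded by the microvascular resistance.  A damped least-squares
(Levenberg-Marquardt) iteration drives max |r_k| below tolerance, starting
from a constant 1e-6 m^3/s per branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .boundary import BoundaryModel
from .centerline import CoronaryTree
from .fluid import BLOOD, Fluid
from .geometry import FeatureTable, tree_features
from .losses import (CorrectionFactors, DEFAULT_FACTORS, LossBreakdown,
                     TERM_NAMES, pressure_profile)
from .units import MMHG_TO_PA, pa_to_mmhg

log = logging.getLogger(__name__)


class NotConvergedError(RuntimeError):
    """Raised when a result requiring convergence is requested from a
    non-converged state."""


@dataclass
class SolverOptions:
    tol_mmHg: float = 1e-3        # convergence: max outlet residual
    max_iter: int = 200
    lm_lambda0: float = 1e-3      # initial LM damping
    lm_up: float = 10.0           # damping multiplier on rejected step
    lm_down: float = 10.0         # damping divisor on accepted step
    fd_rel_step: float = 1e-6     # forward-difference Jacobian step
    q_init: float = 1e-6          # m^3/s, constant initial branch flow
    q_floor: float = 1e-12        # m^3/s, clip for negative trial flows


@dataclass
class FlowState:
    """Converged (or diagnosed) flows, pressures and per-term losses."""

    branch_flows: dict[str, float]
    pressures: dict[str, np.ndarray]          # Pa per point
    velocities: dict[str, np.ndarray]         # m/s per point (Q / local A)
    losses: dict[str, LossBreakdown]          # per-element terms, Pa
    residuals: dict[str, float]               # Pa per outlet
    converged: bool
    iterations: int
    P_inlet: float                            # Pa

    @property
    def max_residual_mmHg(self) -> float:
        return pa_to_mmhg(max(abs(r) for r in self.residuals.values()))


def branch_flows_from_outlets(tree: CoronaryTree,
                              outlet_flows: dict[str, float]) -> dict[str, float]:
    """Interior branch flows by summation over descendant outlets."""
    flows = dict(outlet_flows)
    for bid in reversed(tree.preorder()):
        kids = tree.children(bid)
        if kids:
            flows[bid] = sum(flows[k] for k in kids)
    return flows


def boundary_residual(tree: CoronaryTree, branch_flows: dict[str, float],
                      C: CorrectionFactors, fluid: Fluid, bc: BoundaryModel,
                      features: dict[str, FeatureTable] | None = None) -> dict[str, float]:
    """Per-outlet residual P_distal - (Q R_hyper + P_v), in Pa."""
    for k in bc.outlet_ids:
        if not (branch_flows[k] > 0):
            raise ValueError(f"outlet {k!r}: flow must be positive")
    pressures = pressure_profile(tree, branch_flows, bc.P_inlet_hyper, C,
                                 fluid, features)
    return {k: float(pressures[k][-1] - (branch_flows[k] * bc.R_hyper[k] + bc.P_v))
            for k in bc.outlet_ids}


def solve_flows(tree: CoronaryTree, bc: BoundaryModel,
                C: CorrectionFactors = DEFAULT_FACTORS, fluid: Fluid = BLOOD,
                opts: SolverOptions | None = None,
                features: dict[str, FeatureTable] | None = None) -> FlowState:
    """Damped least-squares solve of the outlet flows.

    Deterministic: fixed inputs and options give bit-identical results.
    Non-convergence is flagged on the returned state, never silent.
    """
    opts = opts or SolverOptions()
    if features is None:
        features = tree_features(tree)
    outlets = bc.outlet_ids
    n = len(outlets)
    tol_pa = opts.tol_mmHg * MMHG_TO_PA

    def residual_vec(x):
        flows = branch_flows_from_outlets(tree, dict(zip(outlets, x)))
        r = boundary_residual(tree, flows, C, fluid, bc, features)
        return np.array([r[k] for k in outlets])

    x = np.full(n, opts.q_init)
    r = residual_vec(x)
    cost = 0.5 * float(r @ r)
    lam = opts.lm_lambda0
    iterations = 0
    converged = bool(np.max(np.abs(r)) <= tol_pa)

    while not converged and iterations < opts.max_iter:
        iterations += 1
        # forward-difference Jacobian
        J = np.empty((n, n))
        for j in range(n):
            h = opts.fd_rel_step * max(abs(x[j]), opts.q_init)
            xh = x.copy()
            xh[j] += h
            J[:, j] = (residual_vec(xh) - r) / h
        JtJ = J.T @ J
        g = J.T @ r
        diag = np.diag(JtJ).copy()
        diag[diag <= 0] = 1.0
        accepted = False
        while not accepted:
            try:
                dx = np.linalg.solve(JtJ + lam * np.diag(diag), -g)
            except np.linalg.LinAlgError:
                dx = None
            if dx is not None:
                xt = np.maximum(x + dx, opts.q_floor)
                if np.any(x + dx < opts.q_floor):
                    log.warning("trial flow below floor clipped to %g m^3/s",
                                opts.q_floor)
                rt = residual_vec(xt)
                cost_t = 0.5 * float(rt @ rt)
                if cost_t < cost:
                    x, r, cost = xt, rt, cost_t
                    lam = max(lam / opts.lm_down, 1e-14)
                    accepted = True
                    continue
            lam *= opts.lm_up
            if lam > 1e14:
                break
        if not accepted:
            log.warning("LM damping exhausted at iteration %d", iterations)
            break
        converged = bool(np.max(np.abs(r)) <= tol_pa)

    flows = branch_flows_from_outlets(tree, dict(zip(outlets, x)))
    pressures, losses = pressure_profile(tree, flows, bc.P_inlet_hyper, C,
                                         fluid, features, return_losses=True)
    velocities = {bid: flows[bid] / tree.branches[bid].areas
                  for bid in tree.branches}
    residuals = dict(zip(outlets, r))
    if not converged:
        log.warning("flow solve did not converge: max residual %.3e mmHg "
                    "after %d iterations", pa_to_mmhg(np.max(np.abs(r))),
                    iterations)
    return FlowState(branch_flows=flows, pressures=pressures,
                     velocities=velocities, losses=losses,
                     residuals=residuals, converged=converged,
                     iterations=iterations, P_inlet=bc.P_inlet_hyper)


def compute_ffr(state: FlowState, bc: BoundaryModel,
                query_points: list[tuple[str, float]] | None = None,
                tree: CoronaryTree | None = None,
                force: bool = False):
    """FFR field: per-point P / P_inlet_hyper.

    Returns ``(ffr_per_branch, at_queries)``; ``at_queries`` holds the FFR at
    each requested (branch_id, arclength_m) location, defaulting to the
    distal terminus of every leaf branch.
    """
    if not state.converged and not force:
        raise NotConvergedError("flow state is not converged; pass force=True "
                                "to evaluate FFR anyway")
    ffr = {bid: p / state.P_inlet for bid, p in state.pressures.items()}
    queries = {}
    if query_points:
        if tree is None:
            raise ValueError("query points require the tree for arclengths")
        for bid, s_q in query_points:
            s = tree.branches[bid].arclengths()
            queries[(bid, s_q)] = float(np.interp(s_q, s, ffr[bid]))
    else:
        for k in bc.outlet_ids:
            queries[(k, None)] = float(ffr[k][-1])
    return ffr, queries


@dataclass
class LossReport:
    """Tree-total pressure loss by term (mmHg) and fractions of total."""

    totals_mmHg: dict[str, float]
    fractions_percent: dict[str, float]
    stenosis_mmHg: float          # constriction + expansion combined
    total_mmHg: float


def loss_breakdown_report(state: FlowState) -> LossReport:
    sums = {name: 0.0 for name in TERM_NAMES}
    for lb in state.losses.values():
        mat = lb.as_matrix()
        for j, name in enumerate(TERM_NAMES):
            sums[name] += float(mat[:, j].sum())
    totals = {k: pa_to_mmhg(v) for k, v in sums.items()}
    total = sum(totals.values())
    fractions = {k: (100.0 * v / total if total != 0 else 0.0)
                 for k, v in totals.items()}
    return LossReport(totals_mmHg=totals, fractions_percent=fractions,
                      stenosis_mmHg=totals["constriction"] + totals["expansion"],
                      total_mmHg=total)


def results_frame(tree: CoronaryTree, state: FlowState):
    """Per-point results table: flows, velocity, pressure, FFR, loss terms."""
    import pandas as pd

    rows = []
    for bid in tree.preorder():
        b = tree.branches[bid]
        s = b.arclengths()
        p = state.pressures[bid]
        u = state.velocities[bid]
        mat = state.losses[bid].as_matrix()
        for i in range(b.n_points):
            row = {"branch_id": bid, "index": i, "arclength_m": s[i],
                   "Q_m3_s": state.branch_flows[bid], "U_m_s": u[i],
                   "P_mmHg": pa_to_mmhg(p[i]),
                   "FFR": p[i] / state.P_inlet}
            for j, name in enumerate(TERM_NAMES):
                # element i-1 ends at point i; the inlet point has no element
                row[f"dP_{name}_mmHg"] = (pa_to_mmhg(mat[i - 1, j])
                                          if i > 0 else 0.0)
            rows.append(row)
    return pd.DataFrame(rows)
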