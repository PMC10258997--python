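"""Correction-factor calibration against reference pressure data.

Given reference cases (a tree, its per-branch flows, and per-point reference
pressures from an external solver such as 3D CFD), the six uncorrected loss
terms evaluated at the reference flows form a per-point design basis; the
cumulative pressure drop at each point is then linear in the correction
factors C1..C6.  The factors are fit by bound-constrained (C >= 0)
least squares on the pooled per-point cumulative drops with a trust-region
reflective iteration; a factor whose basis column is identically zero across
all cases (the corresponding flow pattern never occurs) is reported as
unidentifiable rather than silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .centerline import CoronaryTree
from .fluid import BLOOD, Fluid
from .geometry import tree_features
from .losses import CorrectionFactors, check_mass_consistency, element_losses
from .units import pa_to_mmhg


@dataclass
class CalibrationCase:
    """One reference case: geometry, flows and per-point pressures (Pa)."""

    tree: CoronaryTree
    branch_flows: dict[str, float]
    pressures: dict[str, np.ndarray]
    P0: float                      # inlet reference pressure, Pa

    def __post_init__(self):
        check_mass_consistency(self.tree, self.branch_flows)
        root = self.tree.root.id
        if root not in self.pressures:
            raise ValueError("reference pressures missing for the root branch")
        if not np.isclose(self.pressures[root][0], self.P0, rtol=1e-9, atol=1e-6):
            raise ValueError(
                f"inlet reference pressure {self.pressures[root][0]:.6g} Pa "
                f"does not match stated P0 {self.P0:.6g} Pa")


def extract_design(case: CalibrationCase, fluid: Fluid = BLOOD,
                   smooth_window: int = 3):
    """(X, y): per-point six-column cumulative loss basis and target drops.

    Row j of ``X`` holds the six uncorrected (C = 1) loss terms summed along
    the path from the inlet to point j; ``y_j = P0 - P_ref,j``.  The inlet
    point and the duplicated junction points (daughter first points) are
    excluded, so the row count equals total points minus branch count.
    """
    features = tree_features(case.tree, smooth_window)
    unit = CorrectionFactors(1, 1, 1, 1, 1, 1)
    X_rows, y_rows = [], []
    cum_at_end: dict[str, np.ndarray] = {}
    for bid in case.tree.preorder():
        b = case.tree.branches[bid]
        if bid not in case.pressures:
            raise ValueError(f"reference pressures missing for branch {bid!r}")
        p_ref = np.asarray(case.pressures[bid], float)
        if p_ref.shape != (b.n_points,):
            raise ValueError(f"branch {bid!r}: expected {b.n_points} reference "
                             f"pressures, got {p_ref.shape}")
        lb = element_losses(features[bid], case.branch_flows[bid], unit, fluid)
        basis = lb.as_matrix()                       # (n_el, 6)
        start = (np.zeros(6) if b.parent_id is None
                 else cum_at_end[b.parent_id])
        cum = start + np.cumsum(basis, axis=0)       # rows for points 1..n-1
        cum_at_end[bid] = cum[-1]
        X_rows.append(cum)
        y_rows.append(case.P0 - p_ref[1:])
    return np.vstack(X_rows), np.concatenate(y_rows)


@dataclass
class CalibrationReport:
    residual_rms_mmHg: float
    per_case_rms_mmHg: list[float]
    n_cases: int
    n_points: int
    iterations: int
    unidentifiable: list[str] = field(default_factory=list)
    active_bounds: list[str] = field(default_factory=list)


_FACTOR_NAMES = ("C1", "C2", "C3", "C4", "C5", "C6")


def fit_correction_factors(cases: list[CalibrationCase], fluid: Fluid = BLOOD,
                           x0=None, ftol: float = 1e-12,
                           max_iter: int = 1000):
    """Bound-constrained least-squares fit of C1..C6 on pooled cases.

    Returns ``(CorrectionFactors, CalibrationReport)``.  Unidentifiable
    factors (zero basis column in every case) are returned as 0 and named in
    the report.
    """
    if not cases:
        raise ValueError("at least one calibration case is required")
    designs = [extract_design(c, fluid) for c in cases]
    X = np.vstack([d[0] for d in designs])
    y = np.concatenate([d[1] for d in designs])
    if len(y) < 6:
        raise ValueError(f"pooled design has only {len(y)} rows; need >= 6")

    col_scale = np.max(np.abs(X), axis=0)
    identifiable = col_scale > 0
    unident = [n for n, ok in zip(_FACTOR_NAMES, identifiable) if not ok]
    Xi = X[:, identifiable]

    x0_full = np.ones(6) if x0 is None else np.asarray(x0, float)
    res = least_squares(
        lambda c: Xi @ c - y, x0_full[identifiable],
        jac=lambda c: Xi, method="trf", bounds=(0.0, np.inf),
        ftol=ftol, xtol=ftol, gtol=ftol, max_nfev=max_iter)

    c_full = np.zeros(6)
    c_full[identifiable] = res.x
    factors = CorrectionFactors.from_array(c_full)

    resid = X @ c_full - y
    per_case, off = [], 0
    for d in designs:
        n = len(d[1])
        per_case.append(float(pa_to_mmhg(
            np.sqrt(np.mean(resid[off:off + n] ** 2)))))
        off += n
    active = [n for n, ok, v in zip(_FACTOR_NAMES, identifiable, c_full)
              if ok and v == 0.0]
    report = CalibrationReport(
        residual_rms_mmHg=float(pa_to_mmhg(np.sqrt(np.mean(resid ** 2)))),
        per_case_rms_mmHg=per_case, n_cases=len(cases), n_points=len(y),
        iterations=int(res.nfev), unidentifiable=unident,
        active_bounds=active)
    return factors, report


def normal_equations_fit(cases: list[CalibrationCase],
                         fluid: Fluid = BLOOD) -> np.ndarray:
    """Unconstrained linear least-squares solution (lstsq on the pooled
    design); reference oracle for the iterative fit when no bound is active."""
    designs = [extract_design(c, fluid) for c in cases]
    X = np.vstack([d[0] for d in designs])
    y = np.concatenate([d[1] for d in designs])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def convergence_curve(cases: list[CalibrationCase], subset_sizes,
                      seed: int = 0, fluid: Fluid = BLOOD) -> pd.DataFrame:
    """Factor estimates vs number of pooled cases, on nested random subsets.

    A fixed seed shuffles the case order once; each requested size fits on
    the first n cases of that order.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    rows = []
    for n in subset_sizes:
        if not (1 <= n <= len(cases)):
            raise ValueError(f"subset size {n} out of range 1..{len(cases)}")
        subset = [cases[i] for i in order[:n]]
        factors, report = fit_correction_factors(subset, fluid)
        rows.append({"n_cases": n, **factors.as_dict(),
                     "residual_rms_mmHg": report.residual_rms_mmHg})
    return pd.DataFrame(rows)
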