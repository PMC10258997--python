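"""Ideal (healthy) lumen reconstruction and stenosis quantification.

For every root-to-leaf path the healthy diameter profile is modeled as one
straight line per branch segment.  Stage one fits each segment's line to the
original diameters by least squares (iteratively re-fit to the upper envelope
so lesion points do not drag the line down); stage two refines all segment
lines jointly by constrained nonlinear programming, minimizing
sum_j sqrt(d_ideal,j - d_orig,j) subject to

* feasibility: d_ideal >= d_orig at every point,
* monotone non-increase of d_ideal from ostium to terminus (a daughter may
  not be wider than its parent at the junction),
* one straight line per segment (by construction of the parameterization).

Profiles from paths sharing a segment are merged by pointwise maximum.  The
per-point stenosis rate is S = 100 * (d_ideal - d_orig) / d_ideal (a
diameter-stenosis convention; an area-based variant is available); points
with S >= beta (default 5%) are flagged stenotic, and flagged daughter-branch
first points have their diameter replaced by the ideal value for Murray flow
splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .centerline import CoronaryTree, enumerate_paths, path_points

_MM = 1e3  # optimizer works in millimeters for conditioning
_EPS_MM = 1e-9  # slack regularizer under the square root


class IdealFitError(RuntimeError):
    """Raised when the ideal-profile optimization cannot be set up."""


@dataclass
class IdealProfile:
    """Ideal-lumen fit along one root-to-leaf path."""

    keys: list                 # (branch_id, index_in_branch) per point
    s: np.ndarray              # path arclength, m
    d_orig: np.ndarray         # m
    d_ideal: np.ndarray        # m
    alpha: np.ndarray          # final/initial line-fit ratio per point
    slopes: np.ndarray         # per-segment line slope (d per arclength)
    converged: bool = True


def _upper_envelope_line(s, d, n_iter: int = 4, drop_rel: float = 0.03):
    """Least-squares line through the upper envelope of (s, d).

    Repeatedly fits a line and discards points falling clearly below it
    (relative gap > ``drop_rel`` of the local diameter), so that lesion
    points do not bias the healthy-taper estimate.
    """
    if len(s) < 2:
        raise IdealFitError("segment with a single point cannot be line-fitted")
    active = np.ones(len(s), bool)
    coef = np.polyfit(s, d, 1)
    for _ in range(n_iter):
        coef = np.polyfit(s[active], d[active], 1)
        resid = d - np.polyval(coef, s)
        new_active = resid > -drop_rel * d
        if new_active.sum() < 2:
            break
        if np.array_equal(new_active, active):
            break
        active = new_active
    return coef  # (slope, intercept)


def fit_ideal_path(d_orig: np.ndarray, s: np.ndarray,
                   segment_bounds: list[tuple[int, int]],
                   keys: list | None = None,
                   maxiter: int = 500, tol: float = 1e-9) -> IdealProfile:
    """Constrained ideal-diameter fit along one path.

    ``segment_bounds`` lists half-open index ranges [a, b) of the path's
    points belonging to each branch segment; segments must be contiguous and
    cover all points.
    """
    d = np.asarray(d_orig, float) * _MM
    sv = np.asarray(s, float) * _MM
    nseg = len(segment_bounds)
    if nseg == 0:
        raise IdealFitError("path has no segments")
    for a, b in segment_bounds:
        if b - a < 2:
            raise IdealFitError(
                f"segment [{a}, {b}) has fewer than 2 points; cannot fit a line")

    # stage 1: per-segment upper-envelope line fits
    coefs = [_upper_envelope_line(sv[a:b], d[a:b]) for a, b in segment_bounds]

    # feasible start: non-positive slope, shifted up to dominate d within the
    # segment, then a proximal sweep so segments never increase across joints
    z0 = np.empty(2 * nseg)
    for k, ((a, b), (m, c)) in enumerate(zip(segment_bounds, coefs)):
        m = min(m, 0.0)
        line = m * sv[a:b] + c
        c += max(np.max(d[a:b] - line), 0.0)
        z0[2 * k], z0[2 * k + 1] = m, c
    for k in range(nseg - 1, 0, -1):
        a, b = segment_bounds[k]
        pa, pb = segment_bounds[k - 1]
        start_val = z0[2 * k] * sv[a] + z0[2 * k + 1]
        parent_end = z0[2 * (k - 1)] * sv[pb - 1] + z0[2 * (k - 1) + 1]
        if parent_end < start_val:  # raise the parent line
            z0[2 * (k - 1) + 1] += start_val - parent_end

    seg_of_point = np.empty(len(d), int)
    for k, (a, b) in enumerate(segment_bounds):
        seg_of_point[a:b] = k

    def ideal(z):
        m = z[0::2][seg_of_point]
        c = z[1::2][seg_of_point]
        return m * sv + c

    # design matrix: ideal = B @ z (linear)
    B = np.zeros((len(d), 2 * nseg))
    rows = np.arange(len(d))
    B[rows, 2 * seg_of_point] = sv
    B[rows, 2 * seg_of_point + 1] = 1.0

    def objective(z):
        slack = ideal(z) - d
        root = np.sqrt(np.maximum(slack, 0.0) + _EPS_MM)
        grad = (0.5 / root) @ B
        return float(root.sum()), grad

    D = B[:-1] - B[1:]  # monotone non-increase rows: ideal_j - ideal_{j+1} >= 0
    constraints = [
        {"type": "ineq", "fun": lambda z: B @ z - d, "jac": lambda z: B},
        {"type": "ineq", "fun": lambda z: D @ z, "jac": lambda z: D},
    ]
    res = minimize(objective, z0, jac=True, method="SLSQP",
                   constraints=constraints,
                   options={"maxiter": maxiter, "ftol": tol * _MM})
    z = res.x
    # accept the refined point only if it stayed feasible (solver tolerance)
    feas_tol = 1e-6  # mm
    if (np.min(B @ z - d) < -feas_tol) or (np.min(D @ z) < -feas_tol):
        z = z0
        converged = False
    else:
        converged = bool(res.success)
    # snap sub-tolerance feasibility violations
    d_id = np.maximum(B @ z, d)

    init = np.concatenate([np.polyval(coefs[k], sv[a:b])
                           for k, (a, b) in enumerate(segment_bounds)])
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(init > 0, d_id / init, 1.0)
    return IdealProfile(keys=keys if keys is not None else list(range(len(d))),
                        s=sv / _MM, d_orig=d / _MM, d_ideal=d_id / _MM,
                        alpha=alpha, slopes=z[0::2].copy(), converged=converged)


def merge_paths(profiles: list[IdealProfile]) -> dict:
    """Pointwise maximum of per-path ideal diameters, keyed by point."""
    merged: dict = {}
    for prof in profiles:
        for key, di in zip(prof.keys, prof.d_ideal):
            if key not in merged or di > merged[key]:
                merged[key] = float(di)
    return merged


def stenosis_rate(d_orig, d_ideal, convention: str = "diameter"):
    """Per-point stenosis rate in percent.

    ``diameter``: S = 100*(d_ideal - d_orig)/d_ideal;
    ``area``: S = 100*(1 - (d_orig/d_ideal)^2).
    """
    d_orig = np.asarray(d_orig, float)
    d_ideal = np.asarray(d_ideal, float)
    if np.any(d_ideal <= 0):
        raise ValueError("ideal diameter must be positive")
    if convention == "diameter":
        S = 100.0 * (d_ideal - d_orig) / d_ideal
    elif convention == "area":
        S = 100.0 * (1.0 - (d_orig / d_ideal) ** 2)
    else:
        raise ValueError(f"unknown stenosis convention {convention!r}")
    return np.maximum(S, 0.0)


@dataclass
class IdealTree:
    """Merged ideal-lumen reconstruction for a whole tree."""

    d_ideal: dict[str, np.ndarray] = field(default_factory=dict)
    d_orig: dict[str, np.ndarray] = field(default_factory=dict)
    S_percent: dict[str, np.ndarray] = field(default_factory=dict)
    stenotic: dict[str, np.ndarray] = field(default_factory=dict)
    profiles: list[IdealProfile] = field(default_factory=list)
    beta: float = 5.0

    def frame(self):
        """branch_id/index/d_orig_m/d_ideal_m/S_percent/stenotic_flag table."""
        import pandas as pd

        rows = []
        for bid, d_id in self.d_ideal.items():
            for i in range(len(d_id)):
                rows.append({"branch_id": bid, "index": i,
                             "d_orig_m": self.d_orig[bid][i],
                             "d_ideal_m": d_id[i],
                             "S_percent": self.S_percent[bid][i],
                             "stenotic_flag": bool(self.stenotic[bid][i])})
        return pd.DataFrame(rows)


def fit_ideal_tree(tree: CoronaryTree, beta: float = 5.0,
                   convention: str = "diameter") -> IdealTree:
    """Fit every root-to-leaf path, merge, and flag stenotic points."""
    profiles = []
    for path in enumerate_paths(tree):
        keys, s, d = path_points(tree, path)
        bounds, start = [], 0
        for bid in path:
            n = tree.branches[bid].n_points
            bounds.append((start, start + n))
            start += n
        profiles.append(fit_ideal_path(d, s, bounds, keys=keys))
    merged = merge_paths(profiles)

    out = IdealTree(beta=beta, profiles=profiles)
    for bid, b in tree.branches.items():
        d_id = np.array([merged[(bid, i)] for i in range(b.n_points)])
        d_id = np.maximum(d_id, b.diameters)
        S = stenosis_rate(b.diameters, d_id, convention)
        out.d_ideal[bid] = d_id
        out.d_orig[bid] = b.diameters.copy()
        out.S_percent[bid] = S
        out.stenotic[bid] = S >= beta
    return out


def repair_daughter_roots(tree: CoronaryTree, ideal: IdealTree,
                          beta: float | None = None) -> dict[str, float]:
    """Healthy first-point diameter per branch for Murray flow splitting.

    A daughter whose first point is flagged stenotic (S >= beta) gets the
    ideal diameter there; healthy daughters keep their original diameter.
    """
    beta = ideal.beta if beta is None else beta
    out = {}
    for bid, b in tree.branches.items():
        S0 = ideal.S_percent[bid][0]
        out[bid] = float(ideal.d_ideal[bid][0] if S0 >= beta else b.diameters[0])
    return out
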