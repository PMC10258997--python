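"""Six-term pressure-loss model and its superposition along the tree.

Per micro-flow element the pressure drop is the superposition of six terms:
viscous diffusion (Darcy-Weisbach with laminar lambda = 64/Re), constriction
and expansion minor losses (taper-angle dependent coefficients), a constant
bifurcation junction coefficient (0.1) applied to the first element of every
daughter branch, a bend loss depending on the turn angle and local curvature
radius, and the Bernoulli convective acceleration term (signed: pressure
recovers where the lumen widens).  Each term carries a dimensionless
correction factor C1..C6 calibrated against reference (3D CFD) pressure data.

Velocity convention per element: U = Q / ((A1 + A2)/2); the convection term
uses U_in = Q/A1 and U_out = Q/A2.

All functions are numpy-ufunc style: scalars in, scalar out; arrays in,
arrays out.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .centerline import CoronaryTree
from .fluid import BLOOD, Fluid
from .geometry import FeatureTable, SegmentFeatures, tree_features


@dataclass(frozen=True)
class CorrectionFactors:
    """The six dimensionless loss-correction multipliers.

    Defaults are the packaged reference calibration (fit against 20 3D-CFD
    coronary cases): C1 = 0.4544, C2 = C3 = 2.5681, C4 = 0.0025, C5 = 0.1169,
    C6 = 0.9138.
    """

    c1: float = 0.4544
    c2: float = 2.5681
    c3: float = 2.5681
    c4: float = 0.0025
    c5: float = 0.1169
    c6: float = 0.9138

    def __post_init__(self):
        for name, v in self.as_dict().items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"correction factor {name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3, self.c4, self.c5, self.c6])

    def as_dict(self) -> dict[str, float]:
        return {"C1": self.c1, "C2": self.c2, "C3": self.c3,
                "C4": self.c4, "C5": self.c5, "C6": self.c6}

    @classmethod
    def from_array(cls, a) -> "CorrectionFactors":
        a = np.asarray(a, float)
        return cls(*[float(x) for x in a])

    @classmethod
    def from_json(cls, path) -> "CorrectionFactors":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(*[float(doc[k]) for k in ("C1", "C2", "C3", "C4", "C5", "C6")])

    def to_json(self, path, **extra) -> None:
        doc = {**self.as_dict(), **extra}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


DEFAULT_FACTORS = CorrectionFactors()
ZETA_BIFURCATION = 0.1  # constant junction loss coefficient
TERM_NAMES = ("diffusion", "constriction", "expansion",
              "bifurcation", "bend", "convection")


def friction_coefficient(Re):
    """Laminar Darcy friction factor lambda = 64/Re (Re > 0)."""
    Re = np.asarray(Re, float)
    if np.any(Re <= 0):
        raise ValueError("friction_coefficient requires Re > 0")
    out = 64.0 / Re
    return float(out) if out.ndim == 0 else out


def _clamp_theta_c(theta_c):
    """Piecewise constriction coefficient is defined for theta_c < 90 deg;
    abrupt steps (resampling artifacts) are clamped to 90 with a warning."""
    theta_c = np.asarray(theta_c, float)
    if np.any(theta_c >= 90.0):
        warnings.warn("constriction angle >= 90 deg clamped to 90 deg "
                      "(abrupt lumen step)", stacklevel=3)
    return np.minimum(theta_c, 90.0)


def zeta_constriction(theta_c, lam, area_ratio):
    """Constriction loss coefficient; ``area_ratio`` = A2/A1 (<= 1).

    lambda/(8 sin(theta_c/2)) * [1 - (A2/A1)^2], plus theta_c/1000 (degrees)
    when 30 <= theta_c < 90 deg; zero at theta_c = 0.
    """
    theta = _clamp_theta_c(theta_c)
    lam = np.asarray(lam, float)
    ar = np.asarray(area_ratio, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        base = lam / (8.0 * np.sin(np.radians(theta) / 2.0)) * (1.0 - ar ** 2)
    z = np.where(theta > 0, base, 0.0)
    z = z + np.where(theta >= 30.0, theta / 1000.0, 0.0)
    return float(z) if z.ndim == 0 else z


def zeta_expansion(theta_e, lam, area_ratio):
    """Expansion loss coefficient; ``area_ratio`` = A1/A2 (<= 1).

    lambda/(8 sin(theta_e/2)) * [1 - (A1/A2)^2] + sin(theta_e) * [1 - A1/A2]^2;
    zero at theta_e = 0.
    """
    theta = np.asarray(theta_e, float)
    lam = np.asarray(lam, float)
    ar = np.asarray(area_ratio, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        base = (lam / (8.0 * np.sin(np.radians(theta) / 2.0)) * (1.0 - ar ** 2)
                + np.sin(np.radians(theta)) * (1.0 - ar) ** 2)
    z = np.where(theta > 0, base, 0.0)
    return float(z) if z.ndim == 0 else z


def zeta_bend(theta_b, d, R_bend):
    """Bend loss coefficient [0.131 + 0.163 (d/R)^3.5] * theta_b/90."""
    theta = np.asarray(theta_b, float)
    with np.errstate(divide="ignore"):
        dr = np.where(np.isinf(R_bend), 0.0, np.asarray(d, float) / np.asarray(R_bend, float))
    z = (0.131 + 0.163 * dr ** 3.5) * theta / 90.0
    return float(z) if z.ndim == 0 else z


# -- per-term pressure drops (Pa) -------------------------------------------

def loss_diffusion(f: SegmentFeatures, U, c1: float, fluid: Fluid = BLOOD):
    """Viscous (Darcy-Weisbach) loss; with lambda = 64/Re this is exactly
    C1 * 32 mu l U / d^2 (Hagen-Poiseuille), well-defined at U = 0."""
    return c1 * 32.0 * fluid.mu * f.l * np.asarray(U, float) / f.d_mean ** 2


def loss_constriction(f: SegmentFeatures, U, lam, c2: float, fluid: Fluid = BLOOD):
    if f.theta_c == 0:
        return 0.0
    z = zeta_constriction(f.theta_c, lam, f.A2 / f.A1)
    return c2 * fluid.rho * z * np.asarray(U, float) ** 2 / 2.0


def loss_expansion(f: SegmentFeatures, U, lam, c3: float, fluid: Fluid = BLOOD):
    if f.theta_e == 0:
        return 0.0
    z = zeta_expansion(f.theta_e, lam, f.A1 / f.A2)
    return c3 * fluid.rho * z * np.asarray(U, float) ** 2 / 2.0


def loss_bifurcation(U, c4: float, fluid: Fluid = BLOOD):
    """Junction loss on the first element of a daughter branch."""
    return c4 * fluid.rho * ZETA_BIFURCATION * np.asarray(U, float) ** 2 / 2.0


def loss_bend(f: SegmentFeatures, U, c5: float, fluid: Fluid = BLOOD):
    z = zeta_bend(f.theta_b, f.d_mean, f.R_bend)
    return c5 * fluid.rho * z * np.asarray(U, float) ** 2 / 2.0


def loss_convection(U_in, U_out, c6: float, fluid: Fluid = BLOOD):
    """Signed Bernoulli acceleration term; negative = pressure recovery."""
    U_in = np.asarray(U_in, float)
    U_out = np.asarray(U_out, float)
    return c6 * fluid.rho * (U_out ** 2 - U_in ** 2) / 2.0


@dataclass
class LossBreakdown:
    """Per-element (or per-branch array) pressure drops by term, in Pa."""

    dP_diffusion: np.ndarray
    dP_constriction: np.ndarray
    dP_expansion: np.ndarray
    dP_bifurcation: np.ndarray
    dP_bend: np.ndarray
    dP_convection: np.ndarray

    @property
    def dP_total(self):
        return (self.dP_diffusion + self.dP_constriction + self.dP_expansion
                + self.dP_bifurcation + self.dP_bend + self.dP_convection)

    def as_matrix(self) -> np.ndarray:
        """(n_elements, 6) matrix in TERM_NAMES order."""
        return np.column_stack([
            np.atleast_1d(self.dP_diffusion), np.atleast_1d(self.dP_constriction),
            np.atleast_1d(self.dP_expansion), np.atleast_1d(self.dP_bifurcation),
            np.atleast_1d(self.dP_bend), np.atleast_1d(self.dP_convection)])


def element_losses(ft: FeatureTable, Q: float, C: CorrectionFactors,
                   fluid: Fluid = BLOOD) -> LossBreakdown:
    """Vectorized six-term losses for every element of one branch at flow Q."""
    if Q < 0:
        raise ValueError(f"flow must be nonnegative (proximal->distal), got {Q}")
    A_mean = 0.5 * (ft.A1 + ft.A2)
    U = Q / A_mean
    U_in = Q / ft.A1
    U_out = Q / ft.A2
    dyn = fluid.rho * U ** 2 / 2.0

    diff = C.c1 * 32.0 * fluid.mu * ft.l * U / ft.d_mean ** 2

    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(U > 0, 64.0 * fluid.mu / (fluid.rho * U * ft.d_mean), 0.0)
    constr = np.where(
        (ft.theta_c > 0) & (U > 0),
        C.c2 * dyn * zeta_constriction(ft.theta_c, lam, ft.A2 / ft.A1), 0.0)
    expan = np.where(
        (ft.theta_e > 0) & (U > 0),
        C.c3 * dyn * zeta_expansion(ft.theta_e, lam, ft.A1 / ft.A2), 0.0)
    bif = np.where(ft.is_post_bifurcation, C.c4 * ZETA_BIFURCATION * dyn, 0.0)
    bend = C.c5 * dyn * zeta_bend(ft.theta_b, ft.d_mean, ft.R_bend)
    conv = C.c6 * fluid.rho * (U_out ** 2 - U_in ** 2) / 2.0
    return LossBreakdown(diff, constr, expan, bif, bend, conv)


def element_pressure_drop(f: SegmentFeatures, Q: float, C: CorrectionFactors,
                          fluid: Fluid = BLOOD) -> LossBreakdown:
    """Six-term loss breakdown of a single element at volumetric flow Q."""
    ft = FeatureTable(
        l=np.array([f.l]), d_mean=np.array([f.d_mean]),
        A1=np.array([f.A1]), A2=np.array([f.A2]),
        theta_c=np.array([f.theta_c]), theta_e=np.array([f.theta_e]),
        theta_b=np.array([f.theta_b]), R_bend=np.array([f.R_bend]),
        is_post_bifurcation=np.array([f.is_post_bifurcation]))
    lb = element_losses(ft, Q, C, fluid)
    return LossBreakdown(*(float(getattr(lb, n)[0]) for n in (
        "dP_diffusion", "dP_constriction", "dP_expansion",
        "dP_bifurcation", "dP_bend", "dP_convection")))


def check_mass_consistency(tree: CoronaryTree, branch_flows: dict[str, float],
                           rtol: float = 1e-9) -> None:
    """Raise if flows at any bifurcation violate conservation."""
    for bid in tree.branches:
        kids = tree.children(bid)
        if not kids:
            continue
        qp = branch_flows[bid]
        qk = sum(branch_flows[k] for k in kids)
        if abs(qp - qk) > rtol * max(abs(qp), 1e-300):
            raise ValueError(
                f"mass inconsistency at branch {bid!r}: parent {qp:.6e} "
                f"vs daughters {qk:.6e}")


def pressure_profile(tree: CoronaryTree, branch_flows: dict[str, float],
                     P0: float, C: CorrectionFactors, fluid: Fluid = BLOOD,
                     features: dict[str, FeatureTable] | None = None,
                     return_losses: bool = False):
    """Cumulative per-point pressures (Pa) from inlet pressure P0.

    P_j = P0 - sum of element drops along the root-to-point path.  The shared
    junction point takes the parent-side value; each daughter branch starts
    at its parent's terminal pressure.
    """
    check_mass_consistency(tree, branch_flows)
    if features is None:
        features = tree_features(tree)
    pressures: dict[str, np.ndarray] = {}
    losses: dict[str, LossBreakdown] = {}
    for bid in tree.preorder():
        b = tree.branches[bid]
        p_start = P0 if b.parent_id is None else pressures[b.parent_id][-1]
        lb = element_losses(features[bid], branch_flows[bid], C, fluid)
        pressures[bid] = np.concatenate([[p_start],
                                         p_start - np.cumsum(lb.dP_total)])
        if return_losses:
            losses[bid] = lb
    return (pressures, losses) if return_losses else pressures
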