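"""Seedable synthetic coronary trees with ground truth, plus a linear
Poiseuille-network oracle.

The generator emulates the input domain of clinical CT centerlines: rooted
bifurcating trees with calibers in the 2-4 mm range, gentle linear taper,
planar circular-arc bends, Murray-consistent daughter sizing, and optional
raised-cosine (smooth) focal lesions with known support.  Everything is
deterministic for a fixed seed.

The oracle solves the diffusion-only (resistor network) subproblem by direct
linear algebra — an independent cross-check for the iterative solver's
analytic limit, not a substitute for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boundary import BoundaryModel, PatientParams, build_boundary_model
from .centerline import Branch, CoronaryTree
from .fluid import BLOOD, Fluid
from .losses import CorrectionFactors
from .calibration import CalibrationCase


@dataclass
class LesionSpec:
    """A smooth focal stenosis: raised-cosine diameter reduction."""

    branch_id: str
    center_m: float        # arclength of lesion center along the branch
    length_m: float
    reduction_pct: float   # peak diameter reduction, in (0, 100)

    def __post_init__(self):
        if not (0 < self.reduction_pct < 100):
            raise ValueError("lesion reduction must be in (0, 100) percent")
        if not (self.length_m > 0):
            raise ValueError("lesion length must be positive")


@dataclass
class TreeSpec:
    """Parameters of one synthetic tree (SI units)."""

    depth: int = 2                       # bifurcation levels (0 = single branch)
    root_diameter: float = 3.5e-3
    taper_per_cm: float = 0.04           # fractional diameter loss per cm
    murray_daughter_ratio: float = 1.25  # d_major / d_minor at each split
    branch_length: float = 30e-3         # root length; shrinks with level
    length_decay: float = 0.8
    bend_angle_deg: float = 25.0         # total turn of each branch arc
    branching_angle_deg: float = 30.0    # daughter take-off angle
    spacing: float = 3e-4
    lesions: list[LesionSpec] = field(default_factory=list)
    jitter: float = 0.15                 # relative random variation of sizes
    seed: int = 0


@dataclass
class GroundTruth:
    """What the generator knows that the model must recover."""

    healthy_diameters: dict[str, np.ndarray]
    lesion_support: dict[str, np.ndarray]   # bool per point
    boundary: BoundaryModel | None = None


def _rotate(v, axis, angle_rad):
    """Rodrigues rotation of vector v about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    return (v * np.cos(angle_rad) + np.cross(axis, v) * np.sin(angle_rad)
            + axis * np.dot(axis, v) * (1.0 - np.cos(angle_rad)))


def _perpendicular(t, rng):
    """A random unit vector perpendicular to t."""
    while True:
        r = rng.normal(size=3)
        p = r - np.dot(r, t) * t
        n = np.linalg.norm(p)
        if n > 1e-6:
            return p / n


def _arc_points(start, tangent, length, bend_deg, normal, spacing):
    """Polyline along a planar circular arc (or a straight line)."""
    n = max(int(round(length / spacing)) + 1, 2)
    s = np.linspace(0.0, length, n)
    if abs(bend_deg) < 1e-9:
        return start + np.outer(s, tangent)
    phi = np.radians(bend_deg)
    R = length / phi
    # circle center at start + R*normal; param by arc length
    return (start[None, :] + R * np.outer(np.sin(s / R), tangent)
            + R * np.outer(1.0 - np.cos(s / R), normal))


def make_tree(spec: TreeSpec) -> tuple[CoronaryTree, GroundTruth]:
    """Deterministic synthetic tree + ground truth for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    branches: dict[str, Branch] = {}
    healthy: dict[str, np.ndarray] = {}
    support: dict[str, np.ndarray] = {}
    lesions_by_branch: dict[str, list[LesionSpec]] = {}
    for les in spec.lesions:
        lesions_by_branch.setdefault(les.branch_id, []).append(les)

    def jit(x):
        return x * (1.0 + spec.jitter * rng.uniform(-1.0, 1.0))

    def grow(bid, parent_id, start, tangent, d_start, length, level):
        bend = jit(spec.bend_angle_deg) * rng.choice([-1.0, 1.0])
        normal = _perpendicular(tangent, rng)
        pos = _arc_points(start, tangent, length, bend, normal, spec.spacing)
        s = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(pos, axis=0), axis=1))])
        d_healthy = d_start * (1.0 - spec.taper_per_cm * s / 1e-2)
        if np.any(d_healthy <= 0):
            raise ValueError(f"branch {bid!r}: taper drives diameter <= 0")
        d = d_healthy.copy()
        sup = np.zeros(len(d), bool)
        for les in lesions_by_branch.get(bid, []):
            if les.length_m > s[-1]:
                raise ValueError(f"lesion longer than branch {bid!r}")
            x = (s - les.center_m) / les.length_m
            inside = np.abs(x) <= 0.5
            profile = 0.5 * (1.0 + np.cos(2.0 * np.pi * x[inside]))
            d[inside] *= 1.0 - (les.reduction_pct / 100.0) * profile
            sup[inside] |= profile > 0
        branches[bid] = Branch(id=bid, positions=pos, diameters=d,
                               parent_id=parent_id)
        healthy[bid] = d_healthy
        support[bid] = sup
        if level >= spec.depth:
            return
        # daughters sized by a Murray-consistent asymmetric split
        end_tangent = pos[-1] - pos[-2]
        end_tangent = end_tangent / np.linalg.norm(end_tangent)
        d_end = d_healthy[-1]
        a = jit(spec.murray_daughter_ratio)
        d_minor = d_end / (1.0 + a ** 3) ** (1.0 / 3.0)
        d_major = a * d_minor
        plane = _perpendicular(end_tangent, rng)
        ang = np.radians(jit(spec.branching_angle_deg))
        next_len = length * spec.length_decay
        for i, (dd, sign) in enumerate(((d_major, 1.0), (d_minor, -1.0))):
            t_child = _rotate(end_tangent, plane, sign * ang)
            grow(f"{bid}.{i}", bid, pos[-1], t_child, dd,
                 jit(next_len), level + 1)

    grow("b0", None, np.zeros(3), np.array([1.0, 0.0, 0.0]),
         spec.root_diameter, spec.branch_length, 0)
    tree = CoronaryTree(branches=branches)
    return tree, GroundTruth(healthy_diameters=healthy, lesion_support=support)


def poiseuille_oracle(tree: CoronaryTree, bc: BoundaryModel,
                      fluid: Fluid = BLOOD):
    """Direct linear solve of the diffusion-only resistor network.

    Per-element resistance 32*mu*l/(A_mean*d_mean^2) (Hagen-Poiseuille with
    the element-mean velocity convention); branch resistances sum in series,
    outlets terminate on R_hyper to P_v, the root on P_inlet_hyper.  Returns
    ``(branch_flows, pressures)`` with per-point pressures in Pa.
    """
    order = tree.preorder()
    idx = {bid: i for i, bid in enumerate(order)}
    n = len(order)

    elem_R: dict[str, np.ndarray] = {}
    R_branch = np.empty(n)
    for bid in order:
        b = tree.branches[bid]
        l = np.linalg.norm(np.diff(b.positions, axis=0), axis=1)
        d_mean = 0.5 * (b.diameters[:-1] + b.diameters[1:])
        A_mean = 0.5 * (b.areas[:-1] + b.areas[1:])
        r = 32.0 * fluid.mu * l / (A_mean * d_mean ** 2)
        elem_R[bid] = r
        R_branch[idx[bid]] = r.sum()

    # nodal equations for the distal-node pressure of every branch
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    for bid in order:
        i = idx[bid]
        gi = 1.0 / R_branch[i]
        A[i, i] += gi
        parent = tree.branches[bid].parent_id
        if parent is None:
            rhs[i] += gi * bc.P_inlet_hyper
        else:
            A[i, idx[parent]] -= gi
            A[idx[parent], i] -= gi
            A[idx[parent], idx[parent]] += gi
        if not tree.children(bid):
            go = 1.0 / bc.R_hyper[bid]
            A[i, i] += go
            rhs[i] += go * bc.P_v
    try:
        p_dist = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"singular resistor network: {exc}") from exc

    flows, pressures = {}, {}
    for bid in order:
        i = idx[bid]
        parent = tree.branches[bid].parent_id
        p_prox = bc.P_inlet_hyper if parent is None else p_dist[idx[parent]]
        q = (p_prox - p_dist[i]) / R_branch[i]
        flows[bid] = float(q)
        pressures[bid] = p_prox - np.concatenate(
            [[0.0], np.cumsum(elem_R[bid] * q)])
    return flows, pressures


def random_tree_spec(rng: np.random.Generator, depth: int | None = None,
                     with_lesion: bool = False) -> TreeSpec:
    """A randomized TreeSpec in the clinical caliber range (2-4 mm roots)."""
    depth = int(rng.integers(1, 4)) if depth is None else depth
    spec = TreeSpec(
        depth=depth,
        root_diameter=float(rng.uniform(2.8e-3, 4.0e-3)),
        taper_per_cm=float(rng.uniform(0.02, 0.06)),
        murray_daughter_ratio=float(rng.uniform(1.05, 1.5)),
        branch_length=float(rng.uniform(25e-3, 40e-3)),
        bend_angle_deg=float(rng.uniform(10.0, 40.0)),
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )
    if with_lesion:
        spec.lesions = [LesionSpec(
            branch_id="b0",
            center_m=float(rng.uniform(0.35, 0.65)) * spec.branch_length,
            length_m=float(rng.uniform(4e-3, 8e-3)),
            reduction_pct=float(rng.uniform(30.0, 65.0)),
        )]
    return spec


def make_calibration_set(true_C: CorrectionFactors, n: int,
                         noise: float = 0.0, seed: int = 0,
                         fluid: Fluid = BLOOD,
                         params: PatientParams | None = None,
                         lesion_fraction: float = 0.7) -> list[CalibrationCase]:
    """n reference cases with pressures from the package's own forward model.

    Trees carry tapers, bends, bifurcations and (for ``lesion_fraction`` of
    cases) focal lesions, so all six loss patterns are active across the set.
    ``noise`` applies multiplicative Gaussian perturbation to the cumulative
    pressure drops.  Deterministic for a fixed seed.
    """
    from .solver import SolverOptions, solve_flows  # local: avoid cycle

    if n < 1:
        raise ValueError("need at least one case")
    rng = np.random.default_rng(seed)
    params = params or PatientParams()
    cases = []
    for i in range(n):
        spec = random_tree_spec(rng, with_lesion=(rng.uniform() < lesion_fraction))
        tree, _ = make_tree(spec)
        bc = build_boundary_model(tree, params)
        state = solve_flows(tree, bc, true_C, fluid,
                            SolverOptions(tol_mmHg=1e-6))
        pressures = {}
        for bid, p in state.pressures.items():
            drop = bc.P_inlet_hyper - p
            if noise > 0:
                drop = drop * (1.0 + noise * rng.normal(size=drop.shape))
            p_noisy = bc.P_inlet_hyper - drop
            p_noisy[0] = p[0] if tree.branches[bid].parent_id else bc.P_inlet_hyper
            pressures[bid] = p_noisy
        if noise > 0:
            # junction duplicates must stay consistent with the parent side
            for bid in tree.preorder():
                parent = tree.branches[bid].parent_id
                if parent is not None:
                    pressures[bid][0] = pressures[parent][-1]
        cases.append(CalibrationCase(tree=tree,
                                     branch_flows=dict(state.branch_flows),
                                     pressures=pressures,
                                     P0=bc.P_inlet_hyper))
    return cases
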