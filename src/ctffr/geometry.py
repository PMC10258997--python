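"""Per-element geometric features of a discretized centerline.

Each pair of adjacent centerline points bounds one micro-flow element (a short
1D pipe, ~0.3 mm).  The pressure-loss operators consume, per element: length,
mean diameter, inlet/outlet cross-sectional areas, taper half-geometry angles
(constriction theta_c or expansion theta_e, never both), the centerline bend
angle theta_b between adjacent tangents, and the local curvature radius from
the three-point circumcircle.

Taper convention: the full cone angle theta = 2*arctan(dr/l), where
dr = |d1 - d2|/2 is the radius change over element length l.  The constant
absorbed by this convention choice is calibrated away by the constriction and
expansion correction factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .centerline import CoronaryTree


def reynolds(U: float, d: float, rho: float, mu: float) -> float:
    """Reynolds number Re = rho*U*d/mu. All inputs must be positive."""
    if not (U > 0 and d > 0 and rho > 0 and mu > 0):
        raise ValueError(f"reynolds: all inputs must be positive, got "
                         f"U={U}, d={d}, rho={rho}, mu={mu}")
    return rho * U * d / mu


def circumradius(p0, p1, p2) -> float:
    """Radius of the circle through three points; inf when collinear."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    a = np.linalg.norm(p1 - p0)
    b = np.linalg.norm(p2 - p1)
    c = np.linalg.norm(p2 - p0)
    cross = np.linalg.norm(np.cross(p1 - p0, p2 - p0))
    if cross < 1e-12 * max(a, b, c) ** 2:
        return np.inf
    return a * b * c / (2.0 * cross)


def _angle_deg(u, v) -> float:
    """Angle between two vectors, in degrees."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length tangent vector")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def taper_angles(d1: float, d2: float, length: float) -> tuple[float, float]:
    """(theta_c, theta_e) in degrees for an element tapering d1 -> d2."""
    if not (length > 0):
        raise ValueError("element length must be positive")
    theta = float(np.degrees(2.0 * np.arctan(abs(d1 - d2) / (2.0 * length))))
    if d2 < d1:
        return theta, 0.0
    if d2 > d1:
        return 0.0, theta
    return 0.0, 0.0


@dataclass
class SegmentFeatures:
    """Geometry of one micro-flow element.

    Lengths/diameters/radii in meters, areas in m^2, angles in degrees.
    Exactly one of ``theta_c`` (constriction) and ``theta_e`` (expansion) may
    be nonzero.  ``R_bend`` is the local three-point circumcircle radius
    (inf for locally straight centerlines).
    """

    l: float
    d_mean: float
    A1: float
    A2: float
    theta_c: float = 0.0
    theta_e: float = 0.0
    theta_b: float = 0.0
    R_bend: float = np.inf
    is_post_bifurcation: bool = False

    def __post_init__(self):
        if not (self.l > 0):
            raise ValueError(f"element length must be positive, got {self.l}")
        if not (self.A1 > 0 and self.A2 > 0):
            raise ValueError("element areas must be positive")
        if self.theta_c < 0 or self.theta_e < 0:
            raise ValueError("taper angles must be nonnegative")
        if self.theta_c > 0 and self.theta_e > 0:
            raise ValueError("at most one of theta_c/theta_e may be nonzero")


def segment_features(p1, p2, tangent_before=None, tangent_after=None,
                     context_point=None, is_post_bifurcation=False) -> SegmentFeatures:
    """Features of the element between two adjacent centerline points.

    ``p1``/``p2`` are objects with ``position`` (3-vector, m), ``diameter``
    (m) and optional ``area`` (m^2); plain ``(position, diameter)`` tuples are
    accepted too.  ``tangent_before`` is the direction of the preceding
    element (defaults to this element's own chord, giving theta_b = 0);
    ``tangent_after`` defaults likewise.  ``context_point`` is the point
    preceding ``p1``, used for the bend circumcircle.
    """
    def unpack(p):
        if hasattr(p, "position"):
            pos = np.asarray(p.position, float)
            d = float(p.diameter)
            a = getattr(p, "area", None)
        else:
            pos = np.asarray(p[0], float)
            d = float(p[1])
            a = p[2] if len(p) > 2 else None
        if a is None:
            a = np.pi * d ** 2 / 4.0
        return pos, d, float(a)

    x1, d1, a1 = unpack(p1)
    x2, d2, a2 = unpack(p2)
    chord = x2 - x1
    length = float(np.linalg.norm(chord))
    if length == 0:
        raise ValueError("coincident centerline points (zero-length element)")
    theta_c, theta_e = taper_angles(d1, d2, length)
    tb = chord if tangent_before is None else np.asarray(tangent_before, float)
    ta = chord if tangent_after is None else np.asarray(tangent_after, float)
    theta_b = _angle_deg(tb, ta)
    if context_point is not None:
        R = circumradius(np.asarray(context_point, float), x1, x2)
    else:
        R = np.inf
    return SegmentFeatures(l=length, d_mean=0.5 * (d1 + d2), A1=a1, A2=a2,
                           theta_c=theta_c, theta_e=theta_e, theta_b=theta_b,
                           R_bend=R, is_post_bifurcation=is_post_bifurcation)


@dataclass
class FeatureTable:
    """Vectorized element features for one branch (arrays of length n-1)."""

    l: np.ndarray
    d_mean: np.ndarray
    A1: np.ndarray
    A2: np.ndarray
    theta_c: np.ndarray
    theta_e: np.ndarray
    theta_b: np.ndarray
    R_bend: np.ndarray
    is_post_bifurcation: np.ndarray  # bool

    @property
    def n_elements(self) -> int:
        return len(self.l)


def _smooth_tangents(t: np.ndarray, window: int) -> np.ndarray:
    """Centered moving-average of unit tangents (renormalized).

    Suppresses jagged pixel-scale direction noise before bend angles are
    measured; window 1 disables smoothing.
    """
    if window <= 1 or len(t) <= 2:
        return t
    half = window // 2
    out = np.empty_like(t)
    for i in range(len(t)):
        lo, hi = max(0, i - half), min(len(t), i + half + 1)
        v = t[lo:hi].mean(axis=0)
        n = np.linalg.norm(v)
        out[i] = t[i] if n == 0 else v / n
    return out


def branch_features(tree: CoronaryTree, branch_id: str,
                    smooth_window: int = 3) -> FeatureTable:
    """FeatureTable for one branch, using parent-end context at junctions."""
    b = tree.branches[branch_id]
    pos, d, A = b.positions, b.diameters, b.areas
    seg = np.diff(pos, axis=0)
    l = np.linalg.norm(seg, axis=1)
    tang = seg / l[:, None]

    is_root = b.parent_id is None
    if not is_root:
        parent = tree.branches[b.parent_id]
        ctx_point = parent.positions[-2]
        ctx_vec = pos[0] - ctx_point
        n = np.linalg.norm(ctx_vec)
        ctx_tangent = tang[0] if n == 0 else ctx_vec / n
    else:
        ctx_point = None
        ctx_tangent = tang[0]

    ext = np.vstack([ctx_tangent, tang])
    ext = _smooth_tangents(ext, smooth_window)
    theta_b = np.array([_angle_deg(ext[i], ext[i + 1]) for i in range(len(tang))])

    n_el = len(l)
    R = np.empty(n_el)
    for i in range(n_el):
        if i == 0:
            prev = ctx_point if ctx_point is not None else (
                pos[0] - (pos[1] - pos[0]))  # collinear backcast -> inf
        else:
            prev = pos[i - 1]
        R[i] = circumradius(prev, pos[i], pos[i + 1])

    theta_c = np.zeros(n_el)
    theta_e = np.zeros(n_el)
    for i in range(n_el):
        theta_c[i], theta_e[i] = taper_angles(d[i], d[i + 1], l[i])

    post_bif = np.zeros(n_el, dtype=bool)
    if not is_root:
        post_bif[0] = True

    return FeatureTable(l=l, d_mean=0.5 * (d[:-1] + d[1:]), A1=A[:-1], A2=A[1:],
                        theta_c=theta_c, theta_e=theta_e, theta_b=theta_b,
                        R_bend=R, is_post_bifurcation=post_bif)


def tree_features(tree: CoronaryTree, smooth_window: int = 3) -> dict[str, FeatureTable]:
    """Element features for every branch of the tree."""
    return {bid: branch_features(tree, bid, smooth_window)
            for bid in tree.preorder()}


def features_frame(tree: CoronaryTree, smooth_window: int = 3):
    """Per-element feature table as a pandas DataFrame (CSV-exportable)."""
    import pandas as pd

    rows = []
    for bid, ft in tree_features(tree, smooth_window).items():
        for i in range(ft.n_elements):
            rows.append({"branch_id": bid, "index": i, "l": ft.l[i],
                         "d_mean": ft.d_mean[i], "A1": ft.A1[i], "A2": ft.A2[i],
                         "theta_c": ft.theta_c[i], "theta_e": ft.theta_e[i],
                         "theta_b": ft.theta_b[i], "R_bend": ft.R_bend[i]})
    return pd.DataFrame(rows)
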