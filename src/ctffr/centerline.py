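"""Coronary-tree centerline data model and I/O.

A coronary tree is a rooted, directed tree of branches.  Each branch is a
polyline of centerline points carrying 3D position, lumen diameter and
cross-sectional area, ordered proximal to distal.  Bifurcations occur at
branch ends: the junction point is the last point of the parent branch and is
repeated (with the daughter's own lumen size) as point 0 of every daughter.

Two on-disk dialects are supported:

* JSON: ``{"inlet_pressure_mmHg": float, "branches": [{"id", "parent_id",
  "label", "points": [[x, y, z, d], ...], "area_m2": [...],
  "curvature_radius_m": [...]}]}`` with positions/diameters in meters.
* CSV directory: a ``manifest.csv`` (``branch_id,parent_id,label``) plus one
  ``<branch_id>.csv`` per branch with header ``x,y,z,d[,area,curv_radius]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class TreeValidationError(ValueError):
    """Raised when a centerline tree violates a structural invariant."""


class TreeParseError(ValueError):
    """Raised when an on-disk tree file is malformed."""


@dataclass
class Branch:
    """One centerline branch (polyline of points, proximal to distal).

    ``positions`` is an (n, 3) array in meters, ``diameters`` an (n,) array in
    meters.  ``areas`` (m^2) is reconstructed as pi*d^2/4 when not supplied;
    ``explicit_areas`` records whether areas came from the input (in which case
    they are authoritative for velocity computation and are interpolated on
    resampling rather than recomputed).
    """

    id: str
    positions: np.ndarray
    diameters: np.ndarray
    parent_id: str | None = None
    label: str = ""
    areas: np.ndarray | None = None
    curvature_radii: np.ndarray | None = None
    explicit_areas: bool = False

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TreeValidationError(
                f"branch {self.id!r}: positions must be (n, 3), got {self.positions.shape}")
        n = len(self.positions)
        if n < 2:
            raise TreeValidationError(f"branch {self.id!r}: needs >= 2 points, got {n}")
        if self.diameters.shape != (n,):
            raise TreeValidationError(
                f"branch {self.id!r}: {n} points but {self.diameters.shape} diameters")
        bad = np.flatnonzero(~(self.diameters > 0))
        if bad.size:
            raise TreeValidationError(
                f"branch {self.id!r}: nonpositive diameter at point {bad[0]}")
        if self.areas is None:
            self.areas = np.pi * self.diameters ** 2 / 4.0
            self.explicit_areas = False
        else:
            self.areas = np.asarray(self.areas, dtype=float)
            if self.areas.shape != (n,):
                raise TreeValidationError(
                    f"branch {self.id!r}: {n} points but {self.areas.shape} areas")
            bad = np.flatnonzero(~(self.areas > 0))
            if bad.size:
                raise TreeValidationError(
                    f"branch {self.id!r}: nonpositive area at point {bad[0]}")
            self.explicit_areas = True
        if self.curvature_radii is not None:
            self.curvature_radii = np.asarray(self.curvature_radii, dtype=float)
        seg = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
        zero = np.flatnonzero(seg == 0)
        if zero.size:
            raise TreeValidationError(
                f"branch {self.id!r}: coincident points {zero[0]} and {zero[0] + 1}")

    @property
    def n_points(self) -> int:
        return len(self.positions)

    def arclengths(self) -> np.ndarray:
        """Cumulative arc length (chord sums) per point, starting at 0."""
        seg = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclengths()[-1])


@dataclass
class CoronaryTree:
    """Rooted directed tree of branches; the sole geometric substrate."""

    branches: dict[str, Branch] = field(default_factory=dict)
    inlet_pressure_mmHg: float | None = None

    def __post_init__(self):
        if isinstance(self.branches, (list, tuple)):
            self.branches = {b.id: b for b in self.branches}
        self.validate()

    # -- topology -----------------------------------------------------------
    def validate(self) -> None:
        roots = [b.id for b in self.branches.values() if b.parent_id is None]
        if len(roots) != 1:
            raise TreeValidationError(f"tree must have exactly one root, found {roots}")
        for b in self.branches.values():
            if b.parent_id is not None and b.parent_id not in self.branches:
                raise TreeValidationError(
                    f"branch {b.id!r}: unknown parent {b.parent_id!r}")
        # acyclicity / reachability: walk to root from every branch
        for b in self.branches.values():
            seen = set()
            cur = b
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise TreeValidationError(f"cycle involving branch {cur.id!r}")
                seen.add(cur.id)
                cur = self.branches[cur.parent_id]

    @property
    def root(self) -> Branch:
        return next(b for b in self.branches.values() if b.parent_id is None)

    def children(self, branch_id: str) -> list[str]:
        return [b.id for b in self.branches.values() if b.parent_id == branch_id]

    def leaves(self) -> list[str]:
        has_child = {b.parent_id for b in self.branches.values() if b.parent_id}
        return [bid for bid in self.branches if bid not in has_child]

    def preorder(self) -> list[str]:
        order, stack = [], [self.root.id]
        while stack:
            bid = stack.pop()
            order.append(bid)
            stack.extend(sorted(self.children(bid), reverse=True))
        return order

    @property
    def inlet_point(self) -> np.ndarray:
        return self.root.positions[0]

    def outlet_points(self) -> dict[str, np.ndarray]:
        return {bid: self.branches[bid].positions[-1] for bid in self.leaves()}

    def total_points(self) -> int:
        return sum(b.n_points for b in self.branches.values())


def enumerate_paths(tree: CoronaryTree) -> list[list[str]]:
    """All root-to-leaf branch-id sequences, one per leaf, deterministic order."""
    paths = []
    for leaf in sorted(tree.leaves()):
        path = [leaf]
        while tree.branches[path[0]].parent_id is not None:
            path.insert(0, tree.branches[path[0]].parent_id)
        paths.append(path)
    return paths


def path_points(tree: CoronaryTree, path: list[str]):
    """Concatenated per-point arrays along one root-to-leaf path.

    Returns ``(keys, s, d)`` where ``keys`` are (branch_id, index_in_branch)
    pairs, ``s`` is global arclength along the path and ``d`` diameters.  The
    shared junction point appears twice (parent last, daughter first) at the
    same arclength, carrying each branch's own lumen size.
    """
    keys, s_all, d_all = [], [], []
    offset = 0.0
    for bid in path:
        b = tree.branches[bid]
        s = b.arclengths() + offset
        keys.extend((bid, i) for i in range(b.n_points))
        s_all.append(s)
        d_all.append(b.diameters)
        offset = s[-1]
    return keys, np.concatenate(s_all), np.concatenate(d_all)


# -- resampling -------------------------------------------------------------

def resample(tree: CoronaryTree, spacing: float) -> CoronaryTree:
    """Arc-length resampling of every branch at ~``spacing`` meters.

    Each branch gets ``round(L/spacing) + 1`` evenly spaced points; endpoints
    (hence bifurcation junctions) are preserved exactly.  Diameters (and
    explicit areas, when present) are linearly interpolated; derived areas are
    recomputed from the interpolated diameters.
    """
    if not (spacing > 0):
        raise ValueError(f"spacing must be positive, got {spacing}")
    new = {}
    for bid, b in tree.branches.items():
        s = b.arclengths()
        L = s[-1]
        if spacing >= L:
            raise ValueError(
                f"branch {bid!r}: spacing {spacing} >= branch length {L:.6g}")
        n = max(int(round(L / spacing)) + 1, 2)
        si = np.linspace(0.0, L, n)
        pos = np.column_stack([np.interp(si, s, b.positions[:, k]) for k in range(3)])
        pos[0], pos[-1] = b.positions[0], b.positions[-1]
        d = np.interp(si, s, b.diameters)
        areas = np.interp(si, s, b.areas) if b.explicit_areas else None
        curv = (np.interp(si, s, b.curvature_radii)
                if b.curvature_radii is not None else None)
        new[bid] = Branch(id=bid, positions=pos, diameters=d, parent_id=b.parent_id,
                          label=b.label, areas=areas, curvature_radii=curv)
    return CoronaryTree(branches=new, inlet_pressure_mmHg=tree.inlet_pressure_mmHg)


# -- I/O --------------------------------------------------------------------

def _branch_from_json(obj: dict) -> Branch:
    try:
        bid = str(obj["id"])
        pts = np.asarray(obj["points"], dtype=float)
    except (KeyError, TypeError, ValueError) as exc:
        raise TreeParseError(f"malformed branch record: {exc}") from exc
    if pts.ndim != 2 or pts.shape[1] != 4:
        raise TreeParseError(
            f"branch {bid!r}: points must be [[x,y,z,d],...], got shape {pts.shape}")
    parent = obj.get("parent_id")
    return Branch(
        id=bid,
        positions=pts[:, :3],
        diameters=pts[:, 3],
        parent_id=None if parent is None else str(parent),
        label=obj.get("label", ""),
        areas=obj.get("area_m2"),
        curvature_radii=obj.get("curvature_radius_m"),
    )


def read_tree_json(path) -> CoronaryTree:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TreeParseError(f"{path}: invalid JSON: {exc}") from exc
    if "branches" not in doc:
        raise TreeParseError(f"{path}: missing 'branches' key")
    branches = [_branch_from_json(b) for b in doc["branches"]]
    return CoronaryTree(branches={b.id: b for b in branches},
                        inlet_pressure_mmHg=doc.get("inlet_pressure_mmHg"))


def write_tree_json(tree: CoronaryTree, path) -> None:
    doc = {"branches": []}
    if tree.inlet_pressure_mmHg is not None:
        doc["inlet_pressure_mmHg"] = tree.inlet_pressure_mmHg
    for bid in tree.preorder():
        b = tree.branches[bid]
        rec = {
            "id": b.id,
            "parent_id": b.parent_id,
            "label": b.label,
            "points": np.column_stack([b.positions, b.diameters]).tolist(),
        }
        if b.explicit_areas:
            rec["area_m2"] = b.areas.tolist()
        if b.curvature_radii is not None:
            rec["curvature_radius_m"] = b.curvature_radii.tolist()
        doc["branches"].append(rec)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_tree_csvdir(path) -> CoronaryTree:
    path = Path(path)
    manifest = path / "manifest.csv"
    if not manifest.exists():
        raise TreeParseError(f"{path}: missing manifest.csv")
    man = pd.read_csv(manifest, dtype=str)
    for col in ("branch_id", "parent_id"):
        if col not in man.columns:
            raise TreeParseError(f"{manifest}: missing column {col!r}")
    branches = {}
    for _, row in man.iterrows():
        bid = row["branch_id"]
        fp = path / f"{bid}.csv"
        if not fp.exists():
            raise TreeParseError(f"{path}: missing branch file {fp.name}")
        df = pd.read_csv(fp)
        for col in ("x", "y", "z", "d"):
            if col not in df.columns:
                raise TreeParseError(f"{fp}: missing column {col!r}")
        parent = row["parent_id"]
        parent = None if (pd.isna(parent) or parent == "") else str(parent)
        branches[bid] = Branch(
            id=bid,
            positions=df[["x", "y", "z"]].to_numpy(float),
            diameters=df["d"].to_numpy(float),
            parent_id=parent,
            label="" if "label" not in man.columns or pd.isna(row.get("label"))
            else str(row["label"]),
            areas=df["area"].to_numpy(float) if "area" in df.columns else None,
            curvature_radii=df["curv_radius"].to_numpy(float)
            if "curv_radius" in df.columns else None,
        )
    return CoronaryTree(branches=branches)


def write_tree_csvdir(tree: CoronaryTree, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for bid in tree.preorder():
        b = tree.branches[bid]
        rows.append({"branch_id": b.id, "parent_id": b.parent_id or "",
                     "label": b.label})
        df = pd.DataFrame(b.positions, columns=["x", "y", "z"])
        df["d"] = b.diameters
        if b.explicit_areas:
            df["area"] = b.areas
        if b.curvature_radii is not None:
            df["curv_radius"] = b.curvature_radii
        df.to_csv(path / f"{bid}.csv", index=False)
    pd.DataFrame(rows).to_csv(path / "manifest.csv", index=False)


def read_tree(path, format: str | None = None) -> CoronaryTree:
    """Read a centerline tree, auto-detecting JSON file vs CSV directory."""
    p = Path(path)
    if format is None:
        format = "csv-dir" if p.is_dir() else "json"
    if format == "json":
        return read_tree_json(p)
    if format == "csv-dir":
        return read_tree_csvdir(p)
    raise ValueError(f"unknown tree format {format!r}")


def write_tree(tree: CoronaryTree, path, format: str | None = None) -> None:
    p = Path(path)
    if format is None:
        format = "csv-dir" if (p.is_dir() or p.suffix == "") else "json"
    if format == "json":
        write_tree_json(tree, p)
    elif format == "csv-dir":
        write_tree_csvdir(tree, p)
    else:
        raise ValueError(f"unknown tree format {format!r}")
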