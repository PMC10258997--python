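"""Minimal ASCII VTK XML PolyData (.vtp) polyline export.

Writes the centerline as one polyline per branch with point-data arrays
(e.g. P_mmHg, U_m_s, FFR) readable by ParaView and other VTK-based viewers.
Plain-text XML only; no binary appended data.
"""

from __future__ import annotations

from xml.etree import ElementTree as ET

import numpy as np

from .centerline import CoronaryTree


def export_vtp(tree: CoronaryTree, path,
               point_data: dict[str, dict[str, np.ndarray]] | None = None) -> None:
    """Write the tree (and optional per-branch point arrays) as .vtp.

    ``point_data`` maps array name -> {branch_id -> (n_points,) array}.
    """
    order = tree.preorder()
    counts = [tree.branches[b].n_points for b in order]
    offsets = np.cumsum(counts)
    n_pts = int(offsets[-1])

    root = ET.Element("VTKFile", type="PolyData", version="0.1",
                      byte_order="LittleEndian")
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(poly, "Piece", NumberOfPoints=str(n_pts),
                          NumberOfVerts="0", NumberOfLines=str(len(order)),
                          NumberOfStrips="0", NumberOfPolys="0")

    def data_array(parent, name, values, ncomp=1):
        da = ET.SubElement(parent, "DataArray", type="Float64", Name=name,
                           NumberOfComponents=str(ncomp), format="ascii")
        da.text = " ".join(f"{v:.10g}" for v in np.asarray(values).ravel())
        return da

    pts = ET.SubElement(piece, "Points")
    coords = np.vstack([tree.branches[b].positions for b in order])
    data_array(pts, "Points", coords, ncomp=3)

    pd = ET.SubElement(piece, "PointData")
    diam = np.concatenate([tree.branches[b].diameters for b in order])
    data_array(pd, "diameter_m", diam)
    for name, per_branch in (point_data or {}).items():
        arr = np.concatenate([np.asarray(per_branch[b], float) for b in order])
        if len(arr) != n_pts:
            raise ValueError(f"point-data array {name!r} has {len(arr)} values "
                             f"for {n_pts} points")
        data_array(pd, name, arr)

    lines = ET.SubElement(piece, "Lines")
    conn = np.arange(n_pts)
    ca = ET.SubElement(lines, "DataArray", type="Int64", Name="connectivity",
                       format="ascii")
    ca.text = " ".join(str(i) for i in conn)
    oa = ET.SubElement(lines, "DataArray", type="Int64", Name="offsets",
                       format="ascii")
    oa.text = " ".join(str(int(o)) for o in offsets)

    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
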