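import numpy as np
import pytest

from ctffr.boundary import BoundaryModel
from ctffr.centerline import Branch, CoronaryTree
from ctffr.units import mmhg_to_pa


def straight_tube(length=0.02, diameter=3e-3, n=21, d_end=None, bid="b0"):
    """Single straight branch along +x, optionally linearly tapering."""
    x = np.linspace(0.0, length, n)
    pos = np.column_stack([x, np.zeros(n), np.zeros(n)])
    d = np.full(n, diameter) if d_end is None else np.linspace(diameter, d_end, n)
    return CoronaryTree(branches={bid: Branch(id=bid, positions=pos, diameters=d)})


def symmetric_y(length=0.015, d_root=3e-3, n=16, angle_deg=30.0):
    """Root plus two mirror-image daughters of equal caliber."""
    x = np.linspace(0.0, length, n)
    zeros = np.zeros(n)
    root = Branch(id="b0", positions=np.column_stack([x, zeros, zeros]),
                  diameters=np.full(n, d_root))
    d_child = d_root / 2.0 ** (1.0 / 3.0)  # Murray-consistent
    a = np.radians(angle_deg)
    s = np.linspace(0.0, length, n)
    branches = {"b0": root}
    for bid, sign in (("b0.0", 1.0), ("b0.1", -1.0)):
        pos = np.column_stack([length + s * np.cos(a),
                               sign * s * np.sin(a), zeros])
        branches[bid] = Branch(id=bid, positions=pos,
                               diameters=np.full(n, d_child), parent_id="b0")
    return CoronaryTree(branches=branches)


def resistance_bc(tree, R_hyper=2.4e9, P_in_mmHg=90.0, P_v_mmHg=6.5):
    """Boundary model with a fixed hyperemic resistance at every outlet."""
    leaves = tree.leaves()
    r_h = {k: R_hyper for k in leaves}
    r_rest = {k: R_hyper / 0.24 for k in leaves}
    dP = mmhg_to_pa(100.0 - P_v_mmHg)
    return BoundaryModel(Q_rest={k: dP / r for k, r in r_rest.items()},
                         R_rest=r_rest, R_hyper=r_h,
                         P_inlet_hyper=mmhg_to_pa(P_in_mmHg),
                         P_v=mmhg_to_pa(P_v_mmHg))


@pytest.fixture
def tube():
    return straight_tube()


@pytest.fixture
def y_tree():
    return symmetric_y()
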