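import numpy as np
import pytest

from snotools.structure_io import Atom, Residue, StructureModel
from snotools import fixtures as fx


def make_atom(name, element, xyz, **kw):
    return Atom(name=name, element=element, coord=np.asarray(xyz, dtype=float), **kw)


def make_cys(resseq, cb_xyz, sg_xyz, chain_id="A", altloc_sg=None):
    """Minimal cysteine with backbone stubs for COM / geometry tests."""
    cb = np.asarray(cb_xyz, dtype=float)
    sg = np.asarray(sg_xyz, dtype=float)
    ca = cb + np.array([0.0, 1.53, 0.0])
    n = ca + np.array([1.2, 0.8, 0.0])
    res = Residue(chain_id=chain_id, resseq=resseq, icode="", resname="CYS")
    res.atoms = [
        make_atom("N", "N", n),
        make_atom("CA", "C", ca),
        make_atom("C", "C", ca + np.array([-1.0, 0.9, 0.3])),
        make_atom("O", "O", ca + np.array([-1.5, 1.9, 0.3])),
        make_atom("CB", "C", cb),
        make_atom("SG", "S", sg, altloc=altloc_sg or ""),
    ]
    return res


@pytest.fixture(scope="session")
def helix_model():
    return fx.build_scaffold(fx.ScaffoldSpec(ss_type="helix", sequence="A" * 12))


@pytest.fixture(scope="session")
def sheet_model():
    return fx.build_sheet_pair()


@pytest.fixture(scope="session")
def cys_pair_model():
    """Two-scaffold construct with the cysteine pair at (2.05 Å, -90 deg)."""
    return fx.place_cys_pair(
        fx.ScaffoldSpec(sequence="GAGCGAG"),
        fx.ScaffoldSpec(sequence="GAGCGAG"),
        target_sg_sg=2.05,
        target_dihedral=-90.0,
    )
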