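"""Torsion math, rotamer binning, pair geometry and disulfide grading."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snotools.geometry import (
    GeometryError, IncompleteResidueError, PairGeometry, chi1_and_rotamer,
    dihedral, grade_disulfide, pair_geometry, rotamer_state,
    survey_pair_over_structures,
)
from snotools.structure_io import StructureModel

from conftest import make_atom, make_cys


class TestDihedral:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], 0.0),      # planar cis
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)], 180.0),    # planar trans
            # sign frozen against an independent torsion routine (MDAnalysis)
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)], 90.0),
        ],
    )
    def test_reference_values(self, points, expected):
        assert dihedral(*points) == pytest.approx(expected, abs=1e-9)

    def test_matches_mdanalysis_on_random_points(self):
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(2024)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)).astype(np.float64)
            mine = dihedral(*pts)
            out = calc_dihedrals(*(p[None].astype(np.float32) for p in pts))
            ref = float(np.degrees(np.asarray(out).ravel()[0]))
            assert mine == pytest.approx(ref, abs=1e-3)

    def test_rigid_motion_invariance_reversal_and_mirror(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(7)
        for _ in range(25):
            pts = rng.normal(size=(4, 3)) * 3
            base = dihedral(*pts)
            rot = Rotation.random(random_state=int(rng.integers(2**31)))
            shift = rng.normal(size=3) * 10
            moved = rot.apply(pts) + shift
            assert dihedral(*moved) == pytest.approx(base, abs=1e-8)
            # a torsion reads the same from either end of the chain...
            assert dihedral(*pts[::-1]) == pytest.approx(base, abs=1e-8)
            # ...and mirror reflection flips its sign
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            if abs(abs(base) - 180.0) > 1e-6:
                assert dihedral(*mirrored) == pytest.approx(-base, abs=1e-8)

    def test_degenerate_points_raise(self):
        p = (0.0, 0.0, 0.0)
        with pytest.raises(GeometryError):
            dihedral(p, p, (1, 0, 0), (2, 0, 0))


class TestRotamerBins:
    @pytest.mark.parametrize("chi1,state", [(-60.0, "m"), (60.0, "p"),
                                            (175.0, "t"), (-175.0, "t"),
                                            (0.0, "m"), (120.0, "p"),
                                            (-120.0, "t"), (180.0, "t")])
    def test_bin_centers_and_edges(self, chi1, state):
        assert rotamer_state(chi1) == state

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=-180.0, max_value=180.0,
                     allow_nan=False, allow_infinity=False))
    def test_bins_partition_the_circle(self, chi1):
        assert rotamer_state(chi1) in {"t", "m", "p"}


class TestChi1:
    def test_ideal_chi1_from_scaffold(self):
        from snotools import fixtures as fx

        model = fx.build_scaffold(fx.ScaffoldSpec(sequence="GCG", chi1=-60.0))
        chi1, state = chi1_and_rotamer(model.polymer()[1])
        assert chi1 == pytest.approx(-60.0, abs=1e-6)
        assert state == "m"

    def test_missing_atom_named(self):
        res = make_cys(1, [0, 0, 0], [1.8, 0, 0])
        res.atoms = [a for a in res.atoms if a.name != "CB"]
        with pytest.raises(IncompleteResidueError, match="CB"):
            chi1_and_rotamer(res)


class TestPairGeometry:
    def test_constructed_distance_read_back(self):
        a = make_cys(1, [0, 0, 0], [1.81, 0, 0])
        sg_b = np.array([1.81, 0, 0]) + 2.05 * np.array([0.8, 0.6, 0.0])
        b = make_cys(10, sg_b + [1.0, 1.2, 0.4], sg_b)
        model = StructureModel(1, [a, b])
        pgs = pair_geometry(model, a, b)
        assert len(pgs) == 1
        assert pgs[0].sg_sg_distance == pytest.approx(2.05, abs=0.01)

    def test_altloc_cross_product(self):
        a = make_cys(1, [0, 0, 0], [1.81, 0, 0])
        sg_near = np.array([1.81 + 1.6, 1.2, 0])     # 2.0 Å from a's SG
        sg_far = np.array([1.81 + 3.2, 2.4, 0])      # 4.0 Å
        b = make_cys(10, sg_far + [1.0, 1.0, 0.5], sg_near, altloc_sg="A")
        b.atoms.append(make_atom("SG", "S", sg_far, altloc="B"))
        model = StructureModel(1, [a, b])
        pgs = pair_geometry(model, a, b)
        assert len(pgs) == 2
        d = sorted(p.sg_sg_distance for p in pgs)
        assert d[0] == pytest.approx(2.0, abs=0.01)
        assert d[1] == pytest.approx(4.0, abs=0.01)

    def test_symmetry_under_swap(self, cys_pair_model):
        cys = [r for r in cys_pair_model.polymer() if r.resname == "CYS"]
        ab = pair_geometry(cys_pair_model, cys[0], cys[1])[0]
        ba = pair_geometry(cys_pair_model, cys[1], cys[0])[0]
        assert ab.sg_sg_distance == pytest.approx(ba.sg_sg_distance, abs=1e-9)
        assert abs(ab.cb_sg_sg_cb) == pytest.approx(abs(ba.cb_sg_sg_cb), abs=1e-9)

    def test_self_pair_rejected(self):
        a = make_cys(1, [0, 0, 0], [1.8, 0, 0])
        with pytest.raises(ValueError):
            pair_geometry(StructureModel(1, [a]), a, a)

    def test_non_cysteine_rejected(self):
        a = make_cys(1, [0, 0, 0], [1.8, 0, 0])
        b = make_cys(2, [4, 0, 0], [5, 0, 0])
        b.resname = "SER"
        with pytest.raises(TypeError):
            pair_geometry(StructureModel(1, [a, b]), a, b)


class TestGrade:
    @pytest.mark.parametrize(
        "d,dih,rot,expected",
        [
            (2.05, -87.0, ("m", "m"), "A"),
            (2.05, 0.0, ("m", "m"), "B"),
            (1.0, -90.0, ("m", "m"), "C"),
            (2.05, 90.0, ("p", "m"), "D"),   # strained plus rotamer
            (5.0, -90.0, ("m", "m"), "none"),
            (2.5, 119.9, ("t", "t"), "A"),   # boundary: distance ceiling, window edge
        ],
    )
    def test_grading_rules(self, d, dih, rot, expected):
        pg = PairGeometry(sg_sg_distance=d, chi1_sno=-60, chi1_proxy=-60,
                          cb_sg_sg_cb=dih, rotamer_sno=rot[0], rotamer_proxy=rot[1])
        assert grade_disulfide(pg) == expected

    def test_total_over_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            pg = PairGeometry(
                sg_sg_distance=float(rng.uniform(0, 8)),
                chi1_sno=float(rng.uniform(-180, 180)),
                chi1_proxy=float(rng.uniform(-180, 180)),
                cb_sg_sg_cb=float(rng.uniform(-180, 180)),
                rotamer_sno=rng.choice(["t", "m", "p"]),
                rotamer_proxy=rng.choice(["t", "m", "p"]),
            )
            assert grade_disulfide(pg) in {"A", "B", "C", "D", "none"}


class TestSurvey:
    def test_pools_altloc_conformers_across_structures(self):
        """Alternate conformations in independent structures pool into one
        distance/dihedral distribution whose range spans the conformers."""
        models = []
        direction = np.array([0.8, 0.6, 0.0])
        for k, d_b in enumerate((3.8, 4.6, 5.6)):
            a = make_cys(501, [0, 0, 0], [1.81, 0, 0])
            sg_a_coord = np.array([1.81, 0, 0])
            b = make_cys(527, [6, 1, 0], sg_a_coord + 2.0 * direction,
                         altloc_sg="A")
            b.atoms.append(make_atom("SG", "S", sg_a_coord + d_b * direction,
                                     altloc="B"))
            for atom in b.atoms:
                if atom.name == "SG":
                    atom.occupancy = 0.5
            models.append(StructureModel(k + 1, [a, b]))
        pooled = survey_pair_over_structures(models, 501, 527)
        assert len(pooled) == 6  # 2 conformers per structure
        distances = [p.sg_sg_distance for p in pooled]
        assert min(distances) == pytest.approx(2.0, abs=0.01)
        assert max(distances) == pytest.approx(5.6, abs=0.01)

    def test_skips_structures_missing_the_pair(self):
        a = make_cys(501, [0, 0, 0], [1.81, 0, 0])
        only_one = StructureModel(1, [a])
        assert survey_pair_over_structures([only_one], 501, 527) == []
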