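"""Cysteine-pair geometry and disulfide stereochemistry grading.

The observables are the ones canonically used to describe a (potential)
disulfide bridge between an S-nitrosylated cysteine (the SNO site) and a
nearby partner cysteine:

* the Sγ–Sγ distance between the two sulfur atoms,
* the side-chain torsion χ1 (N-CA-CB-Sγ) of each cysteine, binned into the
  three rotamer states trans (t, |χ1| > 120°), minus (m, χ1 in (−120°, 0°])
  and plus (p, χ1 in (0°, 120°]),
* the inter-residue torsion Cβ-Sγ-Sγ-Cβ, which sits near ±90° in canonical
  disulfides.

Candidate geometries are graded A–D in the spirit of stereochemical
disulfide databases: A for pairs within the accepted distance and dihedral
ranges, B for distance-compatible pairs with distorted dihedrals, C for
sulfurs too close to bond, D for otherwise acceptable pairs with a strained
(plus) rotamer. Pairs with Sγ–Sγ above the distance ceiling get no grade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure_io import Residue, StructureModel

__all__ = [
    "PairGeometry",
    "GradeParams",
    "GeometryError",
    "IncompleteResidueError",
    "dihedral",
    "chi1_and_rotamer",
    "rotamer_state",
    "pair_geometry",
    "grade_disulfide",
    "survey_pair_over_structures",
]


class GeometryError(ValueError):
    """Degenerate geometry (coincident points, zero-length bond)."""


class IncompleteResidueError(ValueError):
    """A required atom is missing from a residue."""


@dataclass
class GradeParams:
    """Thresholds for the A–D stereochemical grading (all configurable)."""

    min_distance: float = 1.8      # Å, below: too close for a bridge -> C
    max_distance: float = 2.5      # Å, above: no candidate bridge
    dihedral_center: float = 90.0  # |Cβ-Sγ-Sγ-Cβ| target, degrees
    dihedral_window: float = 30.0  # allowed deviation from ±90°


@dataclass
class PairGeometry:
    """Geometry of one (SNO, partner) cysteine pair for one altloc combination."""

    sg_sg_distance: float
    chi1_sno: float
    chi1_proxy: float
    cb_sg_sg_cb: float
    rotamer_sno: str
    rotamer_proxy: str
    altloc_sno: str = ""
    altloc_proxy: str = ""
    grade: str = "none"


def dihedral(p1: Sequence[float], p2: Sequence[float],
             p3: Sequence[float], p4: Sequence[float]) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (−180, 180].

    IUPAC sign convention: looking from p2 towards p3, a clockwise rotation
    of p4 relative to p1 is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b1) < 1e-9 or np.linalg.norm(b2) < 1e-9 or np.linalg.norm(b3) < 1e-9:
        raise GeometryError("coincident points / zero-length bond in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear points in dihedral")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    angle = -float(np.degrees(np.arctan2(y, x)))
    if angle <= -180.0:  # normalise to (−180, 180]
        angle += 360.0
    return angle


def rotamer_state(chi1: float) -> str:
    """Map χ1 (degrees) to its rotamer bin: p=(0,120], m=(−120,0], t otherwise."""
    chi1 = ((chi1 + 180.0) % 360.0) - 180.0
    if chi1 == -180.0:
        chi1 = 180.0
    if 0.0 < chi1 <= 120.0:
        return "p"
    if -120.0 < chi1 <= 0.0:
        return "m"
    return "t"


_GAMMA_ATOMS = ("SG", "OG", "OG1", "CG", "CG1", "SE", "SD")


def _gamma_atom_name(residue: Residue) -> str | None:
    present = {a.name for a in residue.atoms}
    for name in _GAMMA_ATOMS:
        if name in present:
            return name
    return None


def chi1_and_rotamer(residue: Residue, altloc: str | None = None) -> tuple[float, str]:
    """χ1 = dihedral(N, CA, CB, γ-heavy-atom) and its rotamer state."""
    gamma = _gamma_atom_name(residue)
    if gamma is None:
        raise IncompleteResidueError(
            f"residue {residue.resname}{residue.resseq} missing a gamma heavy atom"
        )
    coords = []
    for name in ("N", "CA", "CB", gamma):
        atom = residue.get_atom(name, altloc)
        if atom is None:
            raise IncompleteResidueError(
                f"residue {residue.resname}{residue.resseq} missing atom {name}"
            )
        coords.append(atom.coord)
    chi1 = dihedral(*coords)
    return chi1, rotamer_state(chi1)


def grade_disulfide(pg: PairGeometry, params: GradeParams | None = None) -> str:
    """Stereochemical grade of a candidate disulfide (total over inputs)."""
    p = params or GradeParams()
    d = pg.sg_sg_distance
    if d > p.max_distance:
        return "none"
    if d < p.min_distance:
        return "C"
    dihedral_ok = abs(abs(pg.cb_sg_sg_cb) - p.dihedral_center) <= p.dihedral_window
    if not dihedral_ok:
        return "B"
    if "p" in (pg.rotamer_sno, pg.rotamer_proxy):
        return "D"
    return "A"


def pair_geometry(
    model: StructureModel,
    sno_residue: Residue,
    proxy_residue: Residue,
    grade_params: GradeParams | None = None,
) -> list[PairGeometry]:
    """All pair-geometry observables for one SNO/partner cysteine pair.

    One :class:`PairGeometry` is produced per altloc combination (cross
    product of the altlocs present on the two Sγ atoms); a blank altloc is
    treated as its own conformer.
    """
    for res in (sno_residue, proxy_residue):
        if res.resname != "CYS":
            raise TypeError(
                f"residue {res.resname}{res.resseq} is not a cysteine"
            )
    if sno_residue.key == proxy_residue.key:
        raise ValueError("self-pair rejected: SNO and partner residue are identical")

    out: list[PairGeometry] = []
    alts_sno = sno_residue.altlocs_of("SG")
    alts_proxy = proxy_residue.altlocs_of("SG")
    if not alts_sno or not alts_proxy:
        which = sno_residue if not alts_sno else proxy_residue
        raise IncompleteResidueError(
            f"residue CYS{which.resseq} has no SG atom in any altloc"
        )
    for alt_s in alts_sno:
        sg_s = sno_residue.get_atom("SG", alt_s)
        cb_s = sno_residue.get_atom("CB", alt_s)
        if cb_s is None:
            raise IncompleteResidueError(f"CYS{sno_residue.resseq} missing CB")
        chi1_s, rot_s = chi1_and_rotamer(sno_residue, alt_s)
        for alt_p in alts_proxy:
            sg_p = proxy_residue.get_atom("SG", alt_p)
            cb_p = proxy_residue.get_atom("CB", alt_p)
            if cb_p is None:
                raise IncompleteResidueError(f"CYS{proxy_residue.resseq} missing CB")
            chi1_p, rot_p = chi1_and_rotamer(proxy_residue, alt_p)
            pg = PairGeometry(
                sg_sg_distance=float(np.linalg.norm(sg_s.coord - sg_p.coord)),
                chi1_sno=chi1_s,
                chi1_proxy=chi1_p,
                cb_sg_sg_cb=dihedral(cb_s.coord, sg_s.coord, sg_p.coord, cb_p.coord),
                rotamer_sno=rot_s,
                rotamer_proxy=rot_p,
                altloc_sno=alt_s,
                altloc_proxy=alt_p,
            )
            pg.grade = grade_disulfide(pg, grade_params)
            out.append(pg)
    return out


def survey_pair_over_structures(
    models: Sequence[StructureModel],
    sno_pos: int,
    proxy_pos: int,
    chain_id: str | None = None,
) -> list[PairGeometry]:
    """Pool pair geometries (all altloc combinations) over a set of structures.

    This is the survey used to characterise conformational heterogeneity of a
    cysteine pair across independently solved structures: the ranges of the
    pooled Sγ–Sγ distances and dihedrals summarise the accessible states.
    Structures missing either residue are skipped.
    """
    pooled: list[PairGeometry] = []
    for model in models:
        sno = model.find(sno_pos, chain_id)
        proxy = model.find(proxy_pos, chain_id)
        if sno is None or proxy is None:
            continue
        if sno.resname != "CYS" or proxy.resname != "CYS":
            continue
        try:
            pooled.extend(pair_geometry(model, sno, proxy))
        except IncompleteResidueError:
            continue
    return pooled
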