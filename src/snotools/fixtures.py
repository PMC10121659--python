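"""Deterministic synthetic structures and datasets.

Every other module of the package is testable without downloads because
this module can build, from a seed and a small spec:

* ideal-geometry peptide scaffolds (helix / strand / coil backbones with
  full heavy-atom side chains grafted from the chemical-component ideal
  coordinates shipped with biotite),
* two-scaffold constructs whose cysteine pair hits a requested Sγ–Sγ
  distance and Cβ-Sγ-Sγ-Cβ dihedral exactly (self-validating test data for
  the pair-geometry code),
* multi-model ensembles emulating coarse-grained flexibility-sampler output
  (Gaussian coordinate jitter plus per-cysteine χ1 rotamer resampling),
* dbPTM-like S-nitrosylation site tables with matching model files and
  controlled error injections, driving pipeline bookkeeping tests.

These fixtures emulate statistical structure, not physics: there is no
energy function, so they stand in for real predicted models and sampler
ensembles only at the level of geometry, accessibility and topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure.info as struc_info
from scipy.spatial.transform import Rotation

from .structure_io import Atom, Ensemble, Residue, StructureModel, write_structure

__all__ = [
    "ScaffoldSpec",
    "EnsembleSpec",
    "build_scaffold",
    "build_sheet_pair",
    "place_cys_pair",
    "synth_ensemble",
    "synth_sites_table",
    "set_chi1",
    "one_letter",
    "three_letter",
]

# Ideal backbone geometry (Engh–Huber-style averages); omega fixed at 180.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}

ELEMENT_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
                  "SE": 78.971, "P": 30.974}


def three_letter(aa: str) -> str:
    try:
        return _ONE_TO_THREE[aa.upper()]
    except KeyError:
        raise ValueError(f"unknown residue letter {aa!r}") from None


def one_letter(resname: str) -> str:
    try:
        return _THREE_TO_ONE[resname.upper()]
    except KeyError:
        raise ValueError(f"unknown residue name {resname!r}") from None


@dataclass
class ScaffoldSpec:
    """Recipe for one ideal-geometry peptide scaffold."""

    ss_type: str = "strand"          # helix | strand | coil
    sequence: str = "GCG"
    phi: float | None = None         # override; defaults per ss_type
    psi: float | None = None
    chi1: float = -60.0              # ideal side-chain chi1 unless overridden
    chain_id: str = "A"
    start_resseq: int = 1
    seed: int = 0                    # used only for coil phi/psi sampling

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class EnsembleSpec:
    """Recipe for a synthetic multi-model ensemble (sampler stand-in)."""

    n_models: int = 20
    coordinate_jitter: float = 0.3   # Å sd of Gaussian Cartesian noise
    chi1_weights: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    # per-resseq (t, m, p) rotamer weights for cysteines
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        for resseq, w in self.chi1_weights.items():
            w = np.asarray(w, dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError(f"chi1 weights for residue {resseq} must be "
                                 "nonnegative and sum to 1")


# ---------------------------------------------------------------------------
# internal-coordinate placement
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF: place the atom at distance `bond` from c, angle b-c-x, torsion a-b-c-x."""
    angle = np.radians(angle)
    torsion = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


_TEMPLATE_CACHE: dict[str, tuple[list[str], list[str], np.ndarray]] = {}


def _sidechain_template(resname: str):
    """Heavy side-chain atoms of the ideal component, in the local backbone frame."""
    if resname not in _TEMPLATE_CACHE:
        arr = struc_info.residue(resname)
        keep = (arr.element != "H") & (arr.atom_name != "OXT")
        arr = arr[keep]
        names = list(arr.atom_name)
        _TEMPLATE_CACHE[resname] = (names, list(arr.element), arr.coord.astype(float))
    return _TEMPLATE_CACHE[resname]


def set_chi1(residue: Residue, chi1: float) -> None:
    """Rotate the side chain beyond Cβ about the CA-CB axis to the target χ1."""
    from .geometry import dihedral  # local import to avoid a cycle

    n = residue.get_atom("N")
    ca = residue.get_atom("CA")
    cb = residue.get_atom("CB")
    gamma_names = ("SG", "OG", "OG1", "CG", "CG1", "SE")
    gamma = next((residue.get_atom(g) for g in gamma_names
                  if residue.get_atom(g) is not None), None)
    if n is None or ca is None or cb is None or gamma is None:
        return
    current = dihedral(n.coord, ca.coord, cb.coord, gamma.coord)
    delta = np.radians(chi1 - current)
    axis = cb.coord - ca.coord
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(delta * axis)
    backbone_or_cb = {"N", "CA", "C", "O", "OXT", "CB"}
    for atom in residue.atoms:
        if atom.name in backbone_or_cb:
            continue
        atom.coord = rot.apply(atom.coord - cb.coord) + cb.coord


def build_scaffold(spec: ScaffoldSpec, bfactor: float = 90.0) -> StructureModel:
    """Ideal-geometry peptide with the requested φ/ψ and full heavy side chains."""
    rng = np.random.default_rng(spec.seed)
    n_res = spec.length
    if spec.ss_type not in ("helix", "strand", "coil"):
        raise ValueError(f"unknown ss_type {spec.ss_type!r}")

    torsion_list: list[tuple[float, float]] = []
    for _ in range(n_res):
        if spec.phi is not None and spec.psi is not None:
            torsion_list.append((spec.phi, spec.psi))
        elif spec.ss_type == "coil":
            # broad phi/psi draws; avoids helix/strand basins only by chance
            torsion_list.append((float(rng.uniform(-160, -50)),
                                 float(rng.uniform(-60, 170))))
        else:
            torsion_list.append(PHI_PSI[spec.ss_type])

    def torsions(i: int) -> tuple[float, float]:
        return torsion_list[i]

    # backbone by NeRF
    bb: list[dict[str, np.ndarray]] = []
    for i in range(n_res):
        phi, psi = torsions(i)
        if i == 0:
            n_xyz = np.array([0.0, 0.0, 0.0])
            ca = np.array([BOND_N_CA, 0.0, 0.0])
            ang = np.radians(ANGLE_N_CA_C)
            c = ca + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev = bb[-1]
            phi_prev, psi_prev = torsions(i - 1)
            n_xyz = _place_atom(prev["N"], prev["CA"], prev["C"],
                                BOND_C_N, ANGLE_CA_C_N, psi_prev)
            ca = _place_atom(prev["CA"], prev["C"], n_xyz,
                             BOND_N_CA, ANGLE_C_N_CA, 180.0)  # omega trans
            c = _place_atom(prev["C"], n_xyz, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        bb.append({"N": n_xyz, "CA": ca, "C": c})
    # carbonyl O anti to the next N (trans peptide): torsion N-CA-C-O = psi + 180
    for i in range(n_res):
        bb[i]["O"] = _place_atom(bb[i]["N"], bb[i]["CA"], bb[i]["C"],
                                 BOND_C_O, ANGLE_CA_C_O, torsions(i)[1] + 180.0)

    model = StructureModel(model_id=1, residues=[])
    for i, letter in enumerate(spec.sequence):
        resname = three_letter(letter)
        res = Residue(chain_id=spec.chain_id, resseq=spec.start_resseq + i,
                      icode="", resname=resname)
        for name in ("N", "CA", "C", "O"):
            res.atoms.append(Atom(name=name, element=name[0],
                                  coord=bb[i][name], bfactor=bfactor))
        if resname != "GLY":
            names, elements, coords = _sidechain_template(resname)
            idx = {nm: k for k, nm in enumerate(names)}
            tmpl_frame = np.array([coords[idx["N"]], coords[idx["CA"]], coords[idx["C"]]])
            target_frame = np.array([bb[i]["N"], bb[i]["CA"], bb[i]["C"]])
            mc = tmpl_frame.mean(axis=0)
            tc = target_frame.mean(axis=0)
            rot, _ = Rotation.align_vectors(target_frame - tc, tmpl_frame - mc)
            for nm, el, xyz in zip(names, elements, coords):
                if nm in ("N", "CA", "C", "O"):
                    continue
                res.atoms.append(Atom(name=nm, element=el,
                                      coord=rot.apply(xyz - mc) + tc,
                                      bfactor=bfactor))
            set_chi1(res, spec.chi1)
        model.residues.append(res)
    return model


def build_sheet_pair(
    sequence: str = "AAAAAAAA",
    separation: float = 3.6,
    shift: float = -3.0,
    chain_ids: tuple[str, str] = ("A", "B"),
) -> StructureModel:
    """Antiparallel two-strand β-sheet: an extended strand plus its 180°-
    rotated copy offset by ``separation`` (inter-strand, Å) and ``shift``
    (along the strand axis, Å). Defaults give an H-bond registry where the
    interior residues of both strands are assigned strand (E)."""
    import copy

    a = build_scaffold(ScaffoldSpec(ss_type="strand", sequence=sequence,
                                    chain_id=chain_ids[0]))
    polymer = a.polymer()
    cas = np.array([r.get_atom("CA").coord for r in polymer])
    u = cas[-1] - cas[0]
    u /= np.linalg.norm(u)
    o_xyz = np.array([r.get_atom("O").coord for r in polymer])
    c_xyz = np.array([r.get_atom("C").coord for r in polymer])
    w = (o_xyz - c_xyz).mean(axis=0)
    w -= w.dot(u) * u
    w /= np.linalg.norm(w)
    normal = np.cross(u, w)
    center = cas.mean(axis=0)
    rot = Rotation.from_rotvec(np.pi * normal)
    b = copy.deepcopy(a)
    for res in b.residues:
        res.chain_id = chain_ids[1]
        for atom in res.atoms:
            atom.coord = (rot.apply(atom.coord - center) + center
                          + separation * w + shift * u)
    return StructureModel(model_id=1, residues=a.residues + b.residues)


# ---------------------------------------------------------------------------
# cysteine-pair construct
# ---------------------------------------------------------------------------

def _single_cys(model: StructureModel) -> Residue:
    cys = [r for r in model.polymer() if r.resname == "CYS"]
    if len(cys) != 1:
        raise ValueError(f"scaffold must contain exactly one CYS, found {len(cys)}")
    return cys[0]


class PlacementError(RuntimeError):
    """Requested pair geometry is sterically infeasible."""


def place_cys_pair(
    modelA_spec: ScaffoldSpec,
    modelB_spec: ScaffoldSpec,
    target_sg_sg: float,
    target_dihedral: float,
    resseq_offset: int = 20,
    cb_s_s_angle: float = 104.0,
    min_backbone_gap: float = 1.0,
) -> StructureModel:
    """Merge two scaffolds so their cysteines hit the target pair geometry.

    The second scaffold is rigidly placed so that the measured Sγ–Sγ distance
    equals ``target_sg_sg`` and Cβ-Sγ-Sγ-Cβ equals ``target_dihedral`` (both
    exactly, up to float round-off). Residues of the second scaffold are
    renumbered to start ``resseq_offset`` residues after the first ends, on
    the same chain, so sequence-separation classification can be exercised.
    """
    a = build_scaffold(modelA_spec)
    b = build_scaffold(modelB_spec)
    cys_a = _single_cys(a)
    cys_b = _single_cys(b)

    ca_a = cys_a.get_atom("CA").coord
    cb_a = cys_a.get_atom("CB").coord
    sg_a = cys_a.get_atom("SG").coord

    cb_b_src = cys_b.get_atom("CB").coord
    sg_b_src = cys_b.get_atom("SG").coord
    ca_b_src = cys_b.get_atom("CA").coord
    bond_cb_sg = float(np.linalg.norm(cb_b_src - sg_b_src))
    bond_ca_cb = float(np.linalg.norm(ca_b_src - cb_b_src))
    v1 = sg_b_src - cb_b_src
    v2 = ca_b_src - cb_b_src
    ang_ca = np.degrees(np.arccos(
        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))

    bb_a = np.array([at.coord for r in a.polymer() for at in r.atoms
                     if at.name in ("N", "CA", "C", "O")])
    b_coords_src = np.array([at.coord for r in b.residues for at in r.atoms])
    b_atoms = [at for r in b.residues for at in r.atoms]
    bb_b_idx = [k for k, at in enumerate(b_atoms)
                if at.name in ("N", "CA", "C", "O") and not at.is_het]

    # two torsions are free (they do not affect the target observables);
    # scan them for a clash-free rigid placement of scaffold B
    best = None
    for t_sg in np.arange(0.0, 360.0, 30.0):
        sg_b_t = _place_atom(ca_a, cb_a, sg_a, target_sg_sg, cb_s_s_angle, t_sg)
        cb_b_t = _place_atom(cb_a, sg_a, sg_b_t, bond_cb_sg, cb_s_s_angle,
                             target_dihedral)
        for t_ca in np.arange(0.0, 360.0, 30.0):
            ca_b_t = _place_atom(sg_a, sg_b_t, cb_b_t, bond_ca_cb, ang_ca, t_ca)
            src = np.array([sg_b_src, cb_b_src, ca_b_src])
            dst = np.array([sg_b_t, cb_b_t, ca_b_t])
            mc, tc = src.mean(axis=0), dst.mean(axis=0)
            rot, _ = Rotation.align_vectors(dst - tc, src - mc)
            moved = rot.apply(b_coords_src - mc) + tc
            bb_b = moved[bb_b_idx]
            d2 = ((bb_a[:, None, :] - bb_b[None, :, :]) ** 2).sum(axis=2)
            gap = float(np.sqrt(d2.min()))
            if best is None or gap > best[0]:
                best = (gap, moved)
            if gap >= min_backbone_gap * 2.0:  # comfortably clash-free
                best = (gap, moved)
                break
        else:
            continue
        break

    gap, moved = best
    if gap < min_backbone_gap:
        raise PlacementError(
            f"backbone clash: best minimum backbone distance {gap:.2f} Å "
            f"< {min_backbone_gap} Å for target ({target_sg_sg} Å, "
            f"{target_dihedral} deg)"
        )
    for atom, xyz in zip(b_atoms, moved):
        atom.coord = xyz

    last = a.residues[-1].resseq
    merged = StructureModel(model_id=1, residues=list(a.residues))
    for i, res in enumerate(b.residues):
        res.chain_id = a.residues[0].chain_id
        res.resseq = last + resseq_offset + i
        merged.residues.append(res)
    return merged


# ---------------------------------------------------------------------------
# ensembles and site tables
# ---------------------------------------------------------------------------

_ROTAMER_CHI1 = {"t": 180.0, "m": -60.0, "p": 60.0}


def synth_ensemble(base: StructureModel, spec: EnsembleSpec) -> Ensemble:
    """n_models jittered copies of ``base`` with cysteine χ1 resampled.

    Rotamers are set before Cartesian jitter, so at large jitter the realised
    rotamer fractions only approximate the requested weights.
    """
    import copy

    rng = np.random.default_rng(spec.seed)
    models = []
    for k in range(spec.n_models):
        model = copy.deepcopy(base)
        model.model_id = k + 1
        for res in model.polymer():
            if res.resname != "CYS":
                continue
            weights = spec.chi1_weights.get(res.resseq)
            if weights is None:
                continue
            state = rng.choice(["t", "m", "p"], p=np.asarray(weights, dtype=float))
            set_chi1(res, _ROTAMER_CHI1[str(state)])
        if spec.coordinate_jitter > 0:
            for res in model.residues:
                for atom in res.atoms:
                    atom.coord = atom.coord + rng.normal(
                        scale=spec.coordinate_jitter, size=3)
        models.append(model)
    return Ensemble(models=models)


def synth_sites_table(
    proteins: int,
    out_dir: str | Path,
    error_injections: dict[str, int] | None = None,
    seed: int = 0,
    pair_distance: float = 5.0,
    pair_offset: int = 20,
    ptm_type: str = "S-nitrosylation",
) -> dict:
    """Write a dbPTM-like TSV plus matching model PDBs, with injected errors.

    ``error_injections`` maps {"missing_model": k, "non_cys": k,
    "out_of_range": k}; injected sites are appended after the ``proteins``
    valid ones. Returns a manifest with the file paths and the expected
    pipeline bookkeeping counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    errs = {"missing_model": 0, "non_cys": 0, "out_of_range": 0}
    errs.update(error_injections or {})

    rows: list[tuple[str, int, str]] = []
    rng = np.random.default_rng(seed)
    # valid proteins: one Cys pair each, SNO site is the first cysteine
    for i in range(proteins):
        acc = f"SYN{i:04d}"
        specA = ScaffoldSpec(ss_type="strand", sequence="GAGCGAG",
                             seed=int(rng.integers(2**31)))
        specB = ScaffoldSpec(ss_type="strand", sequence="GAGCGAG",
                             seed=int(rng.integers(2**31)))
        model = place_cys_pair(specA, specB, pair_distance, -90.0,
                               resseq_offset=pair_offset)
        write_structure(Ensemble(models=[model]), out_dir / f"{acc}.pdb")
        sno_pos = next(r.resseq for r in model.polymer() if r.resname == "CYS")
        rows.append((acc, sno_pos, ptm_type))

    for k in range(errs["missing_model"]):
        rows.append((f"MISS{k:03d}", 4, ptm_type))  # no model file written
    for k in range(errs["non_cys"]):
        acc = f"NCYS{k:03d}"
        model = build_scaffold(ScaffoldSpec(ss_type="strand", sequence="GASAG"))
        write_structure(Ensemble(models=[model]), out_dir / f"{acc}.pdb")
        rows.append((acc, 3, ptm_type))  # position 3 is SER
    for k in range(errs["out_of_range"]):
        acc = f"OOR{k:03d}"
        model = build_scaffold(ScaffoldSpec(ss_type="strand", sequence="GACAG"))
        write_structure(Ensemble(models=[model]), out_dir / f"{acc}.pdb")
        rows.append((acc, 99, ptm_type))

    sites_path = out_dir / "sites.tsv"
    with open(sites_path, "w") as fh:
        fh.write("accession\tposition\tptm_type\n")
        for acc, pos, ptm in rows:
            fh.write(f"{acc}\t{pos}\t{ptm}\n")

    n_input = len(rows)
    manifest = {
        "sites_table": str(sites_path),
        "model_dir": str(out_dir),
        "expected_bookkeeping": {
            "n_input_sites": n_input,
            "n_missing_model": errs["missing_model"],
            "n_not_cysteine": errs["non_cys"],
            "n_out_of_range": errs["out_of_range"],
            "n_analyzed": proteins,
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
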