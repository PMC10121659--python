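"""Solvent accessibility and 3-state secondary structure.

Solvent-accessible surface area (SASA) uses the Shrake–Rupley rolling-probe
algorithm on heavy atoms: each atom is covered with a quasi-uniform point
set on its solvent-expanded sphere (radius + probe) and the accessible area
is the fraction of points not buried inside any neighbour's expanded
sphere. Relative side-chain accessibility divides a residue's side-chain
area in context by the side-chain area of the same residue type in an
extended Gly-X-Gly reference tripeptide (self-calibrated with the fixture
builder, so a fully exposed side chain reads 100% by construction).

Secondary structure is assigned from backbone hydrogen bonds with the
Kabsch–Sander electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

a bond existing when E < -0.5 kcal/mol. Helices come from i→i+4 (and
i→i+3) turn patterns on two consecutive residues, strands from parallel or
antiparallel bridge ladders; everything else is loop. The full 8-state
alphabet is collapsed to {H, E, C} because only helix/strand/loop matter
for the pair taxonomy downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import BACKBONE_ATOMS, Residue, StructureModel

__all__ = [
    "SasaParams",
    "shrake_rupley",
    "sidechain_sasa",
    "relative_sidechain_sasa",
    "reference_sidechain_area",
    "assign_ss3",
    "kabsch_sander_energy",
]

#: Element van-der-Waals radii (Å); heavy-atom mode, hydrogens excluded.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
    "P": 1.80,
}

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol, Kabsch–Sander bond threshold
KS_COUPLING = 27.888        # 0.084 * 332 kcal/mol·Å


@dataclass
class SasaParams:
    probe_radius: float = 1.4
    n_points: int = 960
    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    default_radius: float | None = None  # fallback for unknown elements
    include_hydrogens: bool = False


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (deterministic golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _collect_atoms(model: StructureModel, params: SasaParams):
    atoms = []
    for res in model.polymer():
        for a in res.atoms:
            if a.element == "H" and not params.include_hydrogens:
                continue
            atoms.append((res, a))
    return atoms


def shrake_rupley(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    params: SasaParams | None = None,
) -> dict[int, float]:
    """Per-atom solvent-accessible area (Å²) for the polymer heavy atoms.

    Returns a mapping from ``id(atom)`` to area, so residue-level sums can be
    assembled without assuming any atom ordering.
    """
    if params is None:
        params = SasaParams(probe_radius=probe_radius, n_points=n_points,
                            radii=dict(radii) if radii else dict(DEFAULT_RADII))
    atoms = _collect_atoms(model, params)
    if not atoms:
        return {}
    coords = np.array([a.coord for _, a in atoms])
    radii_arr = np.empty(len(atoms))
    for i, (_, a) in enumerate(atoms):
        r = params.radii.get(a.element.upper())
        if r is None:
            if params.default_radius is None:
                raise ValueError(
                    f"no radius for element {a.element!r} and no default_radius set"
                )
            r = params.default_radius
        radii_arr[i] = r

    expanded = radii_arr + params.probe_radius
    sphere = _sphere_points(params.n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], expanded[i] + expanded.max())
                     if j != i]
        accessible = np.ones(params.n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(coords[j] - coords[i])
            if d >= expanded[i] + expanded[j]:
                continue
            buried = np.linalg.norm(pts - coords[j], axis=1) < expanded[j]
            accessible &= ~buried
            if not accessible.any():
                break
        frac = accessible.mean()
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return {id(a): float(area) for (_, a), area in zip(atoms, areas)}


def sidechain_sasa(model: StructureModel, residue: Residue,
                   params: SasaParams | None = None,
                   per_atom: dict[int, float] | None = None) -> float:
    """Side-chain SASA (Å²) of one residue in its model context."""
    if per_atom is None:
        per_atom = shrake_rupley(model, params=params or SasaParams())
    total = 0.0
    for a in residue.atoms:
        if a.name in BACKBONE_ATOMS or a.element == "H":
            continue
        total += per_atom.get(id(a), 0.0)
    return total


_REFERENCE_CACHE: dict[tuple[str, float, int], float] = {}


def reference_sidechain_area(resname: str, params: SasaParams | None = None) -> float:
    """Side-chain SASA of residue type X in an extended Gly-X-Gly tripeptide.

    Self-calibrated with the fixture builder so the 100% point is exact by
    construction. Glycine has no side chain and returns 0.
    """
    params = params or SasaParams()
    if resname == "GLY":
        return 0.0
    key = (resname, params.probe_radius, params.n_points)
    if key not in _REFERENCE_CACHE:
        from .fixtures import ScaffoldSpec, build_scaffold, one_letter

        spec = ScaffoldSpec(ss_type="strand", sequence="G" + one_letter(resname) + "G")
        tripeptide = build_scaffold(spec)
        center = tripeptide.polymer()[1]
        _REFERENCE_CACHE[key] = sidechain_sasa(tripeptide, center, params=params)
    return _REFERENCE_CACHE[key]


def relative_sidechain_sasa(
    model: StructureModel,
    residue: Residue,
    params: SasaParams | None = None,
    per_atom: dict[int, float] | None = None,
) -> float:
    """Side-chain SASA as % of the extended Gly-X-Gly reference.

    May exceed 100 for distorted conformations. Glycine is defined as 0 with
    a warning (no side chain).
    """
    if residue.resname == "GLY":
        warnings.warn("relative side-chain SASA queried for glycine; defined as 0",
                      stacklevel=2)
        return 0.0
    ref = reference_sidechain_area(residue.resname, params)
    if ref <= 0.0:
        raise ValueError(f"no reference side-chain area for {residue.resname}")
    return 100.0 * sidechain_sasa(model, residue, params=params, per_atom=per_atom) / ref


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def kabsch_sander_energy(r_on: float, r_ch: float, r_oh: float, r_cn: float) -> float:
    """Backbone H-bond electrostatic energy (kcal/mol)."""
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _backbone_frames(residues: Sequence[Residue]):
    """(N, CA, C, O, H) coordinates per residue; H reconstructed when absent.

    The amide H sits 1.01 Å from N, anti to the carbonyl C=O of the
    preceding residue (in the peptide plane); the N-terminal residue gets
    none and cannot act as a donor.
    """
    frames = []
    prev = None
    for res in residues:
        entry = {}
        for name in ("N", "CA", "C", "O"):
            atom = res.get_atom(name)
            entry[name] = atom.coord if atom is not None else None
        h_atom = res.get_atom("H")
        if h_atom is not None:
            entry["H"] = h_atom.coord
        elif (
            prev is not None
            and entry["N"] is not None
            and prev["C"] is not None
            and prev["O"] is not None
            and res.resname != "PRO"
        ):
            direction = prev["C"] - prev["O"]
            norm = np.linalg.norm(direction)
            entry["H"] = entry["N"] + 1.01 * direction / norm if norm > 0 else None
        else:
            entry["H"] = None
        frames.append(entry)
        prev = entry
    return frames


def _hbond_matrix(frames) -> np.ndarray:
    """bonds[d, a] is True when the N-H of residue d donates to the C=O of a."""
    n = len(frames)
    bonds = np.zeros((n, n), dtype=bool)
    for d in range(n):
        nd, hd = frames[d]["N"], frames[d]["H"]
        if nd is None or hd is None:
            continue
        for a in range(n):
            if abs(d - a) < 2:
                continue
            ca, oa = frames[a]["C"], frames[a]["O"]
            if ca is None or oa is None:
                continue
            r_on = np.linalg.norm(oa - nd)
            if r_on > 5.2:  # beyond any plausible H-bond; skip the rest
                continue
            r_ch = np.linalg.norm(ca - hd)
            r_oh = np.linalg.norm(oa - hd)
            r_cn = np.linalg.norm(ca - nd)
            if min(r_ch, r_oh, r_cn) < 1e-6:
                continue
            if kabsch_sander_energy(r_on, r_ch, r_oh, r_cn) < HBOND_ENERGY_CUTOFF:
                bonds[d, a] = True
    return bonds


def assign_ss3(model: StructureModel) -> dict[tuple[str, int, str], str]:
    """Per-residue 3-state secondary structure: H (helix), E (strand), C (loop)."""
    out: dict[tuple[str, int, str], str] = {}
    chains: dict[str, list[Residue]] = {}
    for res in model.polymer():
        chains.setdefault(res.chain_id, []).append(res)

    # H-bond search must run over the whole model so inter-chain sheets work;
    # concatenate chains but forbid |d-a| < 2 only within a chain via indexing.
    residues = [r for ch in chains.values() for r in ch]
    n = len(residues)
    for res in residues:
        out[res.key] = "C"
    if n < 3:
        return out

    # reconstruct amide H chain by chain so a chain break never donates an H
    frames = []
    for ch in chains.values():
        frames.extend(_backbone_frames(ch))
    bonds = _hbond_matrix(frames)

    state = ["C"] * n

    # helix: n-turn(i) when the N-H of i+k donates to the C=O of i (k=4, then 3)
    for k in (4, 3):
        turn = np.zeros(n, dtype=bool)
        for i in range(n - k):
            if bonds[i + k, i]:
                turn[i] = True
        for i in range(1, n - k):
            if turn[i - 1] and turn[i]:
                for j in range(i, i + k):
                    if state[j] == "C":
                        state[j] = "H"

    # strand: Kabsch–Sander parallel / antiparallel bridges
    def hb(d: int, a: int) -> bool:
        return 0 <= d < n and 0 <= a < n and bonds[d, a]

    bridge = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb(i, j - 1) and hb(j + 1, i)) or (hb(j, i - 1) and hb(i + 1, j))
            anti = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if para or anti:
                bridge[i] = True
                bridge[j] = True
    for i in range(n):
        if bridge[i]:
            state[i] = "E"

    for res, s in zip(residues, state):
        out[res.key] = s
    return out
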