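"""Side-chain center-of-mass contact search.

Partner cysteines for an S-nitrosylation site are found by a
center-of-mass (COM) criterion on residue side chains: two residues are in
contact when their side-chain COMs are within the contact cutoff
(default 8 Å; 11 Å is kept as a control value). Glycine has no side chain
and is never part of the contact network — neither as a query site nor as
a neighbour — which also means mutations at glycines cannot be assessed by
the neighbourhood selection.

Pairs are classified by sequence separation: "vicinal" when the two
cysteines are fewer than 8 residues apart in sequence (CXXC-like motifs),
"proximal" when spatially close but distant in sequence; consecutive
cysteines carry an extra sequence-adjacent flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Residue, StructureModel

__all__ = [
    "ContactParams",
    "PairCategory",
    "sidechain_com",
    "find_partner_cys",
    "classify_pair_by_sequence",
    "residues_near_site",
]

ATOMIC_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
                 "SE": 78.971, "P": 30.974}


@dataclass
class ContactParams:
    com_cutoff: float = 8.0       # Å (11.0 is the control value)
    vicinal_max_sep: int = 8      # exclusive: |delta| < 8 is vicinal

    def __post_init__(self) -> None:
        if self.com_cutoff <= 0 or self.vicinal_max_sep <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class PairCategory:
    category: str                 # vicinal | proximal
    sequence_adjacent: bool
    inter_chain: bool = False


def sidechain_com(residue: Residue, altloc: str | None = None) -> np.ndarray | None:
    """Mass-weighted center of the heavy side-chain atoms (beyond Cα).

    Glycine and residues without any side-chain heavy atom return None.
    """
    atoms = residue.sidechain_atoms(altloc)
    if not atoms:
        return None
    masses = np.array([ATOMIC_MASSES.get(a.element.upper(), 12.011) for a in atoms])
    coords = np.array([a.coord for a in atoms])
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()


def _sidechain_altlocs(residue: Residue) -> list[str]:
    alts = sorted({a.altloc for a in residue.sidechain_atoms()})
    return alts or [""]


def _min_com_distance(res_a: Residue, res_b: Residue) -> tuple[float, str, str] | None:
    """Minimum COM distance over all altloc combinations, with the combo."""
    best: tuple[float, str, str] | None = None
    for alt_a in _sidechain_altlocs(res_a):
        com_a = sidechain_com(res_a, alt_a or None)
        if com_a is None:
            continue
        for alt_b in _sidechain_altlocs(res_b):
            com_b = sidechain_com(res_b, alt_b or None)
            if com_b is None:
                continue
            d = float(np.linalg.norm(com_a - com_b))
            if best is None or d < best[0]:
                best = (d, alt_a, alt_b)
    return best


def find_partner_cys(
    model: StructureModel,
    sno_residue: Residue,
    params: ContactParams | None = None,
) -> list[Residue]:
    """All other cysteines whose side-chain COM is within the contact cutoff.

    A pair counts when ANY altloc combination is within the (inclusive)
    cutoff; the site itself is excluded.
    """
    params = params or ContactParams()
    if sno_residue.resname != "CYS":
        raise TypeError(f"site {sno_residue.resname}{sno_residue.resseq} is not a cysteine")
    partners = []
    for res in model.polymer():
        if res.key == sno_residue.key or res.resname != "CYS":
            continue
        best = _min_com_distance(sno_residue, res)
        if best is not None and best[0] <= params.com_cutoff:
            partners.append(res)
    return partners


def classify_pair_by_sequence(
    sno_pos: int,
    partner_pos: int,
    params: ContactParams | None = None,
    same_chain: bool = True,
) -> PairCategory:
    """Vicinal (|Δ| < vicinal_max_sep) vs proximal, plus adjacency flag.

    Pairs on different chains have no meaningful sequence separation and
    are classified proximal with the inter-chain flag set.
    """
    params = params or ContactParams()
    if not same_chain:
        return PairCategory(category="proximal", sequence_adjacent=False,
                            inter_chain=True)
    delta = abs(int(sno_pos) - int(partner_pos))
    category = "vicinal" if delta < params.vicinal_max_sep else "proximal"
    return PairCategory(category=category, sequence_adjacent=delta == 1)


def residues_near_site(
    model: StructureModel,
    residue: Residue,
    params: ContactParams | None = None,
) -> list[Residue]:
    """Residues whose side-chain COM is within the cutoff of the site's COM.

    Glycines are never returned (no side-chain COM), and a glycine query is
    a parameter error for the same reason.
    """
    params = params or ContactParams()
    site_com = sidechain_com(residue)
    if site_com is None:
        raise ValueError(
            f"residue {residue.resname}{residue.resseq} has no side-chain COM"
        )
    out = []
    for res in model.polymer():
        if res.key == residue.key:
            continue
        best = _min_com_distance(residue, res)
        if best is not None and best[0] <= params.com_cutoff:
            out.append(res)
    return out
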