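"""Empirical cysteine pKa prediction.

The thiol pKa of a protein cysteine is shifted from its intrinsic value by
the local environment: burial destabilises the thiolate (raising pKa),
hydrogen-bond donors to Sγ and nearby cations stabilise it (lowering pKa),
and nearby anions raise it. This module implements a transparent
three-term additive model:

    pKa = model_pKa
        + c_des * max(0, 1 - relSASA/100)                 (desolvation)
        + sum over donors within hb_cutoff of hb_delta    (H-bonds, < 0)
        + sum over charges within coulomb_cutoff of
              sign * coulomb_delta * (cutoff - d)/cutoff  (Coulomb)

with model_pKa = 9.0 for cysteine and the default coefficients below. A
cysteine whose Sγ sits within the disulfide-distance ceiling of another
cysteine's Sγ is not titratable in this picture and gets the conventional
sentinel value 99.99 ("unphysical").

The coefficients are configurable, and the module contract (additivity,
monotonicity in burial and charge, sentinel behaviour) is what is tested —
this is a surrogate model, not a reimplementation of any specific
predictor. An optional delegate hook passes prediction through verbatim to
an external callable, including any 99.99 sentinel it may emit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .structure_io import Residue, StructureModel
from .geometry import IncompleteResidueError
from .surface_ss import SasaParams, relative_sidechain_sasa, shrake_rupley

__all__ = [
    "PkaParams",
    "PkaResult",
    "SENTINEL_PKA",
    "predict_cys_pka",
    "pka_environment_terms",
]

SENTINEL_PKA = 99.99

#: side-chain H-bond donor heavy atoms, by residue type
_SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "TRP": ("NE1",),
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}

#: atoms whose mean position represents a charged group, with its sign
_CATION_CENTERS: dict[str, tuple[str, ...]] = {
    "ARG": ("CZ",),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),  # treated as protonated (+1) by default
}
_ANION_CENTERS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass
class PkaParams:
    model_pka: float = 9.0
    c_des: float = 2.0            # pKa units at full burial
    hb_delta: float = -0.8        # per H-bond donor near Sγ
    hb_cutoff: float = 3.5        # Å, donor-heavy-atom to Sγ
    coulomb_delta: float = 0.5    # pKa units at zero distance
    coulomb_cutoff: float = 7.0   # Å
    sentinel_distance: float = 2.5  # Å, Cys-Cys Sγ pair ceiling
    his_charged: bool = True      # His treated as +1 (worst case)
    delegate: Callable | None = None  # external predictor pass-through


@dataclass
class PkaResult:
    value: float
    is_unphysical: bool
    terms: tuple[float, float, float]  # (desolvation, hbond, coulomb)


def _require_cys_sg(residue: Residue):
    if residue.resname != "CYS":
        raise TypeError(f"residue {residue.resname}{residue.resseq} is not a cysteine")
    sg = residue.get_atom("SG")
    if sg is None:
        raise IncompleteResidueError(f"CYS{residue.resseq} missing SG")
    return sg


def _locked_in_disulfide(model: StructureModel, residue: Residue,
                         sg, params: PkaParams) -> bool:
    for other in model.polymer():
        if other.key == residue.key or other.resname != "CYS":
            continue
        for atom in other.atoms_named("SG"):
            if np.linalg.norm(atom.coord - sg.coord) <= params.sentinel_distance:
                return True
    return False


def pka_environment_terms(
    model: StructureModel,
    residue: Residue,
    params: PkaParams | None = None,
    per_atom_sasa: dict[int, float] | None = None,
    sasa_params: SasaParams | None = None,
) -> tuple[float, float, float]:
    """(desolvation, hbond, coulomb) contributions in pKa units.

    The cysteine's own atoms never count as donors or charge centers: the
    backbone amide of the residue itself is always ~3.3 Å from Sγ and is
    part of the intrinsic model pKa, not of the environment.
    """
    params = params or PkaParams()
    sg = _require_cys_sg(residue)

    rel = relative_sidechain_sasa(model, residue, params=sasa_params,
                                  per_atom=per_atom_sasa)
    desolvation = params.c_des * max(0.0, 1.0 - rel / 100.0)

    hbond = 0.0
    coulomb = 0.0
    for other in model.polymer():
        if other.key == residue.key:
            continue
        # backbone amide donors
        n_atom = other.get_atom("N")
        if n_atom is not None and other.resname != "PRO":
            if np.linalg.norm(n_atom.coord - sg.coord) <= params.hb_cutoff:
                hbond += params.hb_delta
        for name in _SIDECHAIN_DONORS.get(other.resname, ()):
            atom = other.get_atom(name)
            if atom is not None and np.linalg.norm(atom.coord - sg.coord) <= params.hb_cutoff:
                hbond += params.hb_delta

        sign = None
        if other.resname in _CATION_CENTERS and (
            other.resname != "HIS" or params.his_charged
        ):
            centers = _CATION_CENTERS[other.resname]
            sign = -1.0  # cation stabilises thiolate: lowers pKa
        elif other.resname in _ANION_CENTERS:
            centers = _ANION_CENTERS[other.resname]
            sign = +1.0
        if sign is not None:
            coords = [other.get_atom(nm).coord for nm in centers
                      if other.get_atom(nm) is not None]
            if coords:
                d = float(np.linalg.norm(np.mean(coords, axis=0) - sg.coord))
                if d <= params.coulomb_cutoff:
                    w = (params.coulomb_cutoff - d) / params.coulomb_cutoff
                    coulomb += sign * params.coulomb_delta * w
    return (desolvation, hbond, coulomb)


def predict_cys_pka(
    model: StructureModel,
    residue: Residue,
    params: PkaParams | None = None,
    per_atom_sasa: dict[int, float] | None = None,
    sasa_params: SasaParams | None = None,
) -> PkaResult:
    """Predict the pKa of a cysteine thiol in its structural context.

    Returns the 99.99 sentinel (``is_unphysical``) when another cysteine's
    Sγ lies within the disulfide-distance ceiling. When a ``delegate``
    callable is configured it is used verbatim instead of the built-in
    model (its own 99.99 sentinels pass through).
    """
    params = params or PkaParams()
    sg = _require_cys_sg(residue)

    if params.delegate is not None:
        value = float(params.delegate(model, residue))
        return PkaResult(value=value, is_unphysical=value == SENTINEL_PKA,
                         terms=(np.nan, np.nan, np.nan))

    if _locked_in_disulfide(model, residue, sg, params):
        return PkaResult(value=SENTINEL_PKA, is_unphysical=True,
                         terms=(0.0, 0.0, 0.0))

    terms = pka_environment_terms(model, residue, params,
                                  per_atom_sasa=per_atom_sasa,
                                  sasa_params=sasa_params)
    return PkaResult(value=params.model_pka + sum(terms),
                     is_unphysical=False, terms=terms)
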