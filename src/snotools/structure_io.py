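"""Structure reading/writing and the atomic data model.

Structures come in three flavours that all map onto the same
:class:`Ensemble` container:

* single-model predicted structures (AlphaFold-style, with the per-residue
  confidence score pLDDT stored in the B-factor column),
* multi-model PDB files holding structural ensembles (e.g. coarse-grained
  flexibility sampling output; typically 20 models),
* experimental PDB entries, possibly with alternate-location (altloc)
  conformers.

Altloc atoms are always preserved, never collapsed: downstream geometry
enumerates conformer combinations explicitly. Parsing and serialisation are
delegated to gemmi; this module only adapts gemmi's hierarchy to the
lightweight containers used by the rest of the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "Ensemble",
    "TrimResult",
    "StructureError",
    "EmptyStructureError",
    "TopologyError",
    "read_structure",
    "write_structure",
    "plddt_profile",
    "trim_low_confidence",
]

#: Default pLDDT value below which a residue counts as low-confidence
#: (AlphaFold's "very low" band starts at 50).
DEFAULT_PLDDT_THRESHOLD = 50.0

#: Internal low-confidence loops of at least this many residues are removed
#: during trimming; shorter internal loops connecting confident segments are
#: kept.
DEFAULT_MAX_INTERNAL_LOOP = 20

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD"})


class StructureError(ValueError):
    """Base class for structure-level problems."""


class EmptyStructureError(StructureError):
    """Raised when a coordinate file contains no ATOM records."""


class TopologyError(StructureError):
    """Raised when MODELs in a multi-model file disagree on residue topology."""


@dataclass
class Atom:
    """A single atomic site (one altloc conformer of one atom)."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0
    is_het: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            warnings.warn(
                f"occupancy {self.occupancy} for atom {self.name} outside [0,1]; clamping",
                stacklevel=2,
            )
            self.occupancy = float(min(1.0, max(0.0, self.occupancy)))


@dataclass
class Residue:
    """One residue: author numbering, 3-letter code, atom list.

    ``(chain_id, resseq, icode)`` identifies the residue within a model.
    Author numbering is kept as-is (AlphaFold models are UniProt-numbered,
    so positions from PTM tables map directly).
    """

    chain_id: str
    resseq: int
    icode: str
    resname: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resseq, self.icode)

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    @property
    def is_het(self) -> bool:
        return bool(self.atoms) and all(a.is_het for a in self.atoms)

    def atoms_named(self, name: str) -> list[Atom]:
        return [a for a in self.atoms if a.name == name]

    def get_atom(self, name: str, altloc: str | None = None) -> Atom | None:
        """Return the atom ``name``; prefer the requested altloc, fall back to
        blank, then to the highest-occupancy conformer."""
        candidates = self.atoms_named(name)
        if not candidates:
            return None
        if altloc is not None:
            for a in candidates:
                if a.altloc == altloc:
                    return a
            for a in candidates:
                if a.altloc == "":
                    return a
        return max(candidates, key=lambda a: a.occupancy)

    def altlocs_of(self, name: str) -> list[str]:
        """Altloc labels present for atom ``name`` (blank counts as its own
        conformer)."""
        return sorted({a.altloc for a in self.atoms_named(name)})

    def sidechain_atoms(self, altloc: str | None = None) -> list[Atom]:
        """Heavy side-chain atoms (beyond the backbone, Cβ included)."""
        out = []
        for a in self.atoms:
            if a.name in BACKBONE_ATOMS or a.element == "H":
                continue
            if altloc is not None and a.altloc not in ("", altloc):
                continue
            out.append(a)
        return out


@dataclass
class StructureModel:
    """One MODEL of a coordinate file: ordered residues plus HETATM ligands."""

    model_id: int
    residues: list[Residue] = field(default_factory=list)
    source_path: str | None = None

    def polymer(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_het and not r.is_water]

    def ligands(self) -> list[Residue]:
        """Non-water HETATM residues (cofactors, ions...)."""
        return [r for r in self.residues if r.is_het and not r.is_water]

    def find(self, resseq: int, chain_id: str | None = None) -> Residue | None:
        for r in self.polymer():
            if r.resseq == resseq and (chain_id is None or r.chain_id == chain_id):
                return r
        return None

    def topology(self) -> tuple[tuple[str, int, str], ...]:
        return tuple((r.chain_id, r.resseq, r.resname) for r in self.residues)


@dataclass
class Ensemble:
    """A set of models sharing residue topology; size 1 for single-model files."""

    models: list[StructureModel]

    def __post_init__(self) -> None:
        if not self.models:
            raise EmptyStructureError("ensemble must contain at least one model")
        ref = self.models[0].topology()
        for m in self.models[1:]:
            top = m.topology()
            if top != ref:
                for a, b in zip(ref, top):
                    if a != b:
                        raise TopologyError(
                            f"model {m.model_id} disagrees with model "
                            f"{self.models[0].model_id} at residue {a} vs {b}"
                        )
                raise TopologyError(
                    f"model {m.model_id} has {len(top)} residues, "
                    f"expected {len(ref)}"
                )

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator[StructureModel]:
        return iter(self.models)

    @property
    def first(self) -> StructureModel:
        return self.models[0]


# ---------------------------------------------------------------------------
# gemmi adapters
# ---------------------------------------------------------------------------

def _from_gemmi(st: gemmi.Structure, source_path: str | None) -> Ensemble:
    models: list[StructureModel] = []
    for gm in st:
        residues: list[Residue] = []
        for chain in gm:
            for gres in chain:
                het = gres.het_flag == "H"
                res = Residue(
                    chain_id=chain.name,
                    resseq=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    resname=gres.name,
                )
                for ga in gres:
                    res.atoms.append(
                        Atom(
                            name=ga.name,
                            element=ga.element.name,
                            coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                            occupancy=ga.occ,
                            altloc=(ga.altloc or "").strip(),
                            bfactor=ga.b_iso,
                            is_het=het,
                        )
                    )
                residues.append(res)
        models.append(StructureModel(model_id=gm.num, residues=residues,
                                     source_path=source_path))
    return Ensemble(models=models)


def _to_gemmi(ensemble: Ensemble, name: str = "model") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for model in ensemble.models:
        gm = gemmi.Model(model.model_id)
        chain_order: list[str] = []
        chain_residues: dict[str, list[gemmi.Residue]] = {}
        for res in model.residues:
            if res.chain_id not in chain_residues:
                chain_residues[res.chain_id] = []
                chain_order.append(res.chain_id)
            gres = gemmi.Residue()
            gres.name = res.resname
            gres.seqid = gemmi.SeqId(res.resseq, res.icode or " ")
            gres.het_flag = "H" if res.is_het or res.is_water else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = atom.occupancy
                ga.altloc = atom.altloc if atom.altloc else "\0"
                ga.b_iso = atom.bfactor
                gres.add_atom(ga)
            chain_residues[res.chain_id].append(gres)
        for cid in chain_order:
            chain = gemmi.Chain(cid or "A")
            for gres in chain_residues[cid]:
                chain.add_residue(gres)
            gm.add_chain(chain)
        st.add_model(gm)
    return st


def read_structure(path: str | Path, format: str = "pdb") -> Ensemble:
    """Read a coordinate file into an :class:`Ensemble`.

    Every MODEL record becomes one :class:`StructureModel`; single-model files
    yield an ensemble of size 1. Altloc atoms are preserved.
    """
    path = Path(path)
    if format not in {"pdb", "cif", "mmcif"}:
        raise ValueError(f"unsupported format {format!r}")
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"failed to parse {path}: {exc}") from exc
    n_atoms = sum(1 for _ in st[0].all()) if len(st) else 0
    if n_atoms == 0:
        raise EmptyStructureError(f"{path} contains no ATOM records")
    return _from_gemmi(st, str(path))


def write_structure(ensemble: Ensemble, path: str | Path) -> None:
    """Serialise an ensemble as a (multi-MODEL when size > 1) PDB file."""
    st = _to_gemmi(ensemble)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Confidence handling
# ---------------------------------------------------------------------------

def plddt_profile(model: StructureModel) -> dict[tuple[str, int, str], float]:
    """Per-residue confidence: mean of atom B-factors for each polymer residue.

    For AlphaFold-style inputs this is the pLDDT in [0, 100]; experimental
    B-factors pass through unchanged and interpretation is left to the caller.
    Residues with no atoms map to NaN.
    """
    out: dict[tuple[str, int, str], float] = {}
    for res in model.polymer():
        if res.atoms:
            out[res.key] = float(np.mean([a.bfactor for a in res.atoms]))
        else:
            out[res.key] = float("nan")
    return out


@dataclass
class TrimResult:
    model: StructureModel
    removed_segments: list[tuple[int, int]]
    disqualified_sites: set[int]


def _low_confidence_runs(
    residues: Sequence[Residue],
    profile: dict[tuple[str, int, str], float],
    threshold: float,
) -> list[tuple[int, int]]:
    """Index runs (start, end inclusive) of residues below threshold."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, res in enumerate(residues):
        low = profile[res.key] < threshold
        if low and start is None:
            start = i
        elif not low and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(residues) - 1))
    return runs


def trim_low_confidence(
    model: StructureModel,
    plddt_threshold: float = DEFAULT_PLDDT_THRESHOLD,
    max_internal_loop: int = DEFAULT_MAX_INTERNAL_LOOP,
    sites: Iterable[int] | None = None,
) -> TrimResult:
    """Remove low-confidence segments the way predicted models are prepared
    for coarse-grained sampling.

    Contiguous runs of residues with confidence below ``plddt_threshold`` are
    removed when they are terminal, or when they are internal and at least
    ``max_internal_loop`` residues long. Shorter internal low-confidence loops
    connecting confident segments are kept. Any queried ``sites`` residue
    number falling inside a removed segment, or inside a low-confidence
    segment of at least ``max_internal_loop`` residues, is flagged
    disqualified (long disordered context makes the site unreliable).
    """
    if not 0.0 <= plddt_threshold <= 100.0:
        raise ValueError(f"plddt_threshold {plddt_threshold} outside [0, 100]")
    profile = plddt_profile(model)
    polymer = model.polymer()
    sites = set(sites or ())

    removed_keys: set[tuple[str, int, str]] = set()
    removed_segments: list[tuple[int, int]] = []
    disqualified: set[int] = set()

    # treat each chain independently so "terminal" means chain terminal
    chains: dict[str, list[Residue]] = {}
    for res in polymer:
        chains.setdefault(res.chain_id, []).append(res)

    for chain_residues in chains.values():
        runs = _low_confidence_runs(chain_residues, profile, plddt_threshold)
        for start, end in runs:
            length = end - start + 1
            terminal = start == 0 or end == len(chain_residues) - 1
            segment = chain_residues[start : end + 1]
            resseqs = {r.resseq for r in segment}
            if terminal or length >= max_internal_loop:
                removed_keys.update(r.key for r in segment)
                removed_segments.append((segment[0].resseq, segment[-1].resseq))
                disqualified.update(sites & resseqs)
            if length >= max_internal_loop:
                disqualified.update(sites & resseqs)

    trimmed = StructureModel(
        model_id=model.model_id,
        residues=[r for r in model.residues if r.key not in removed_keys],
        source_path=model.source_path,
    )
    return TrimResult(trimmed, removed_segments, disqualified)
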