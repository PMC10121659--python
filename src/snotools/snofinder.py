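"""The site-discovery pipeline: from a PTM site table and a directory of
structure models to annotated cysteine-pair tables.

Input is a dbPTM-style tab-separated table with at least (accession,
position, ptm_type) columns, positions in the model's author numbering
(predicted models are UniProt-numbered, so no mapping layer is needed).
Models are discovered as ``<model_dir>/<accession>.pdb`` or AlphaFold-style
``AF-<accession>-F*-model*.pdb`` names.

For every site the pipeline locates the model, checks that the position
exists and is a cysteine (anything else is counted, not raised), finds
partner cysteines by side-chain COM contact, and annotates each (site,
partner, altloc combination) with pair geometry, disulfide grade, relative
side-chain SASA, secondary structure, confidence (pLDDT), and predicted
pKa (sentinel rows retained, flagged). Pairs are split into vicinal and
proximal tables, and a filtered table keeps pairs whose site passes the
solvent-accessibility floor (default: at least 10%).

Sites falling inside long (>= 20 residue) low-confidence disordered
segments are kept but flagged ``disordered_region`` so the caller can apply
the usual discard.
"""

from __future__ import annotations

import glob
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import structure_io
from .structure_io import Ensemble, StructureModel, read_structure
from .geometry import GradeParams, IncompleteResidueError, pair_geometry
from .proximity import ContactParams, classify_pair_by_sequence, find_partner_cys
from .surface_ss import SasaParams, assign_ss3, relative_sidechain_sasa, shrake_rupley
from .cys_pka import PkaParams, predict_cys_pka

logger = logging.getLogger("snotools.snofinder")

__all__ = [
    "SnofinderParams",
    "Bookkeeping",
    "SnofinderResult",
    "read_sites_table",
    "locate_model",
    "run_snofinder",
    "summarize_dataset",
]

PAIR_COLUMNS = [
    "accession", "sno_pos", "partner_pos", "category", "sequence_adjacent",
    "inter_chain", "sg_sg_distance", "chi1_sno", "chi1_proxy", "cb_sg_sg_cb",
    "rotamer_sno", "rotamer_proxy", "altloc_sno", "altloc_proxy", "grade",
    "rel_sasa_sno", "rel_sasa_proxy", "ss_sno", "ss_proxy",
    "plddt_sno", "plddt_proxy", "pka_sno", "pka_proxy",
    "pka_sno_unphysical", "pka_proxy_unphysical", "disordered_region",
]


@dataclass
class SnofinderParams:
    contact: ContactParams = field(default_factory=ContactParams)
    grade: GradeParams = field(default_factory=GradeParams)
    sasa: SasaParams = field(default_factory=SasaParams)
    pka: PkaParams = field(default_factory=PkaParams)
    sasa_min: float = 10.0       # %, site accessibility floor ("at least 10%")
    plddt_threshold: float = structure_io.DEFAULT_PLDDT_THRESHOLD
    max_internal_loop: int = structure_io.DEFAULT_MAX_INTERNAL_LOOP
    expected_ptm: str | None = "S-nitrosylation"


@dataclass
class Bookkeeping:
    """Per-site accounting; input sites are partitioned exactly once."""

    n_input_sites: int = 0
    n_missing_model: int = 0
    n_not_cysteine: int = 0
    n_out_of_range: int = 0
    n_analyzed: int = 0
    n_with_partner: int = 0
    n_pass_sasa: int = 0

    def check(self) -> None:
        total = (self.n_missing_model + self.n_not_cysteine
                 + self.n_out_of_range + self.n_analyzed)
        if total != self.n_input_sites:
            raise AssertionError(
                f"bookkeeping identity violated: {self.n_input_sites} input "
                f"!= {total} partitioned"
            )

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


@dataclass
class SnofinderResult:
    pairs_all: pd.DataFrame
    pairs_vicinal: pd.DataFrame
    pairs_proximal: pd.DataFrame
    pairs_filtered: pd.DataFrame
    bookkeeping: Bookkeeping

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.pairs_all.to_csv(out_dir / "pairs_all.csv", index=False)
        self.pairs_vicinal.to_csv(out_dir / "pairs_vicinal.csv", index=False)
        self.pairs_proximal.to_csv(out_dir / "pairs_proximal.csv", index=False)
        self.pairs_filtered.to_csv(out_dir / "pairs_filtered.csv", index=False)
        with open(out_dir / "bookkeeping.json", "w") as fh:
            json.dump(self.bookkeeping.as_dict(), fh, indent=2)


def read_sites_table(path: str | Path, expected_ptm: str | None = None) -> pd.DataFrame:
    """Parse a dbPTM-like TSV; tolerant of extra columns and missing header.

    Returns a frame with (accession, position, ptm_type); malformed rows are
    dropped with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if not {"accession", "position"} <= set(cols):
        # headerless dbPTM export: assume (accession, position, ptm_type, ...)
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
        df = df.rename(columns={0: "accession", 1: "position", 2: "ptm_type"})
    else:
        df = df.rename(columns={cols["accession"]: "accession",
                                cols["position"]: "position",
                                cols.get("ptm_type", "ptm_type"): "ptm_type"})
    if "ptm_type" not in df.columns:
        df["ptm_type"] = expected_ptm or ""
    before = len(df)
    df["position"] = pd.to_numeric(df["position"], errors="coerce")
    bad = df["position"].isna() | df["accession"].isna()
    if bad.any():
        logger.warning("dropping %d malformed site rows", int(bad.sum()))
    df = df[~bad].copy()
    df["position"] = df["position"].astype(int)
    if expected_ptm:
        mismatch = df["ptm_type"].str.strip().str.lower() != expected_ptm.lower()
        if mismatch.any():
            logger.warning("%d rows have unexpected ptm_type; kept",
                           int(mismatch.sum()))
    logger.info("read %d sites (%d raw rows)", len(df), before)
    return df[["accession", "position", "ptm_type"]]


def locate_model(model_dir: str | Path, accession: str) -> Path | None:
    model_dir = Path(model_dir)
    direct = model_dir / f"{accession}.pdb"
    if direct.exists():
        return direct
    hits = sorted(glob.glob(str(model_dir / f"AF-{accession}-F*-model*.pdb")))
    return Path(hits[0]) if hits else None


def _annotate_model(model: StructureModel, params: SnofinderParams):
    """Precompute per-model annotations shared by all sites of a protein."""
    per_atom = shrake_rupley(model, params=params.sasa)
    ss = assign_ss3(model)
    plddt = structure_io.plddt_profile(model)
    trim = structure_io.trim_low_confidence(
        model, params.plddt_threshold, params.max_internal_loop,
        sites=[r.resseq for r in model.polymer()],
    )
    return per_atom, ss, plddt, trim.disqualified_sites


def run_snofinder(
    sites_table: str | Path | pd.DataFrame,
    model_dir: str | Path,
    params: SnofinderParams | None = None,
) -> SnofinderResult:
    """Run the discovery pipeline over a site table and a model directory."""
    params = params or SnofinderParams()
    if isinstance(sites_table, pd.DataFrame):
        sites = sites_table
    else:
        sites = read_sites_table(sites_table, params.expected_ptm)

    bk = Bookkeeping(n_input_sites=len(sites))
    rows: list[dict] = []

    cache: dict[str, tuple] = {}
    for accession, group in sites.groupby("accession", sort=True):
        model_path = locate_model(model_dir, str(accession))
        if model_path is None:
            logger.warning("no model for %s; %d site(s) skipped",
                           accession, len(group))
            bk.n_missing_model += len(group)
            continue
        if accession not in cache:
            ensemble = read_structure(model_path)
            model = ensemble.first
            cache[accession] = (model, *_annotate_model(model, params))
        model, per_atom, ss, plddt, disordered = cache[accession]

        for _, site in group.sort_values("position").iterrows():
            pos = int(site["position"])
            residue = model.find(pos)
            if residue is None:
                logger.warning("%s position %d not in model", accession, pos)
                bk.n_out_of_range += 1
                continue
            if residue.resname != "CYS":
                logger.warning("%s position %d is %s, not CYS",
                               accession, pos, residue.resname)
                bk.n_not_cysteine += 1
                continue
            bk.n_analyzed += 1

            partners = find_partner_cys(model, residue, params.contact)
            if not partners:
                continue
            bk.n_with_partner += 1

            rel_sno = relative_sidechain_sasa(model, residue,
                                              params=params.sasa,
                                              per_atom=per_atom)
            pka_sno = predict_cys_pka(model, residue, params.pka,
                                      per_atom_sasa=per_atom,
                                      sasa_params=params.sasa)
            if rel_sno >= params.sasa_min:
                bk.n_pass_sasa += 1

            for partner in partners:
                cat = classify_pair_by_sequence(
                    pos, partner.resseq, params.contact,
                    same_chain=partner.chain_id == residue.chain_id,
                )
                rel_proxy = relative_sidechain_sasa(model, partner,
                                                    params=params.sasa,
                                                    per_atom=per_atom)
                pka_proxy = predict_cys_pka(model, partner, params.pka,
                                            per_atom_sasa=per_atom,
                                            sasa_params=params.sasa)
                try:
                    geometries = pair_geometry(model, residue, partner,
                                               params.grade)
                except IncompleteResidueError as exc:
                    logger.warning("%s %d/%d: %s", accession, pos,
                                   partner.resseq, exc)
                    continue
                for pg in geometries:
                    rows.append({
                        "accession": accession,
                        "sno_pos": pos,
                        "partner_pos": partner.resseq,
                        "category": cat.category,
                        "sequence_adjacent": cat.sequence_adjacent,
                        "inter_chain": cat.inter_chain,
                        "sg_sg_distance": pg.sg_sg_distance,
                        "chi1_sno": pg.chi1_sno,
                        "chi1_proxy": pg.chi1_proxy,
                        "cb_sg_sg_cb": pg.cb_sg_sg_cb,
                        "rotamer_sno": pg.rotamer_sno,
                        "rotamer_proxy": pg.rotamer_proxy,
                        "altloc_sno": pg.altloc_sno,
                        "altloc_proxy": pg.altloc_proxy,
                        "grade": pg.grade,
                        "rel_sasa_sno": rel_sno,
                        "rel_sasa_proxy": rel_proxy,
                        "ss_sno": ss[residue.key],
                        "ss_proxy": ss[partner.key],
                        "plddt_sno": plddt[residue.key],
                        "plddt_proxy": plddt[partner.key],
                        "pka_sno": pka_sno.value,
                        "pka_proxy": pka_proxy.value,
                        "pka_sno_unphysical": pka_sno.is_unphysical,
                        "pka_proxy_unphysical": pka_proxy.is_unphysical,
                        "disordered_region": pos in disordered,
                    })

    bk.check()
    pairs_all = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    vicinal = pairs_all[pairs_all["category"] == "vicinal"].reset_index(drop=True)
    proximal = pairs_all[pairs_all["category"] == "proximal"].reset_index(drop=True)
    filtered = pairs_all[pairs_all["rel_sasa_sno"] >= params.sasa_min].reset_index(drop=True)
    return SnofinderResult(pairs_all, vicinal, proximal, filtered, bk)


def summarize_dataset(result: SnofinderResult) -> dict[str, int]:
    """Per-protein rollups of the pair tables.

    A protein is "both" when it has at least one vicinal and one proximal
    pair; "multi-SNO" when more than one distinct site has a partner.
    """
    pairs = result.pairs_all
    if pairs.empty:
        return {
            "n_proteins": 0, "n_sites_with_partner": 0,
            "n_proteins_vicinal_only": 0, "n_proteins_proximal_only": 0,
            "n_proteins_both": 0, "n_proteins_single_sno": 0,
            "n_proteins_multi_sno": 0,
        }
    by_protein = pairs.groupby("accession")
    vicinal_set = set(pairs.loc[pairs["category"] == "vicinal", "accession"])
    proximal_set = set(pairs.loc[pairs["category"] == "proximal", "accession"])
    both = vicinal_set & proximal_set
    n_sites = pairs.groupby("accession")["sno_pos"].nunique()
    return {
        "n_proteins": int(by_protein.ngroups),
        "n_sites_with_partner": int(pairs.groupby(["accession", "sno_pos"]).ngroups),
        "n_proteins_vicinal_only": len(vicinal_set - proximal_set),
        "n_proteins_proximal_only": len(proximal_set - vicinal_set),
        "n_proteins_both": len(both),
        "n_proteins_single_sno": int((n_sites == 1).sum()),
        "n_proteins_multi_sno": int((n_sites > 1).sum()),
    }
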