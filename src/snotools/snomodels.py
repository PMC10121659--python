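"""Ensemble analysis and variant-effect classification.

Given a structural ensemble (multi-model PDB) and a (SNO site, partner
cysteine) pair, compute for every model the Sγ–Sγ distance, both χ1
torsions, the Cβ-Sγ-Sγ-Cβ dihedral, relative side-chain accessibilities
and predicted pKa values; summarise with means and standard deviations,
and with the fraction of models below a distance threshold (default 6 Å —
the distance under which the rotamer states compatible with disulfide
formation concentrate). Distance histograms can be turned into
one-dimensional pseudo-free-energy profiles F_i = −RT ln p_i.

The pair is also classified into one of nine secondary-structure classes
(helix/strand/loop for the SNO site crossed with the same for the partner)
and mutant ensembles are compared with wild type:

* stabilizing    — lower site pKa AND shorter Sγ–Sγ distance than WT,
* neutral        — both pKa and distance similar to WT (within tolerance),
* destabilizing  — higher pKa AND longer distance, or any large pKa
                   increase on its own,
* uncertain      — every other pattern (mixed signals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import Ensemble, StructureModel, Residue
from .geometry import GradeParams, PairGeometry, pair_geometry
from .surface_ss import SasaParams, assign_ss3, relative_sidechain_sasa, shrake_rupley
from .cys_pka import PkaParams, SENTINEL_PKA, predict_cys_pka

__all__ = [
    "EnsembleParams",
    "EnsembleSummary",
    "VariantParams",
    "VariantEffect",
    "analyze_ensemble",
    "summary_from_metric_samples",
    "fraction_below",
    "pmf_1d",
    "classify_pair_ss",
    "classify_variant_effect",
    "cofactor_proximity_flag",
    "PAIR_CLASSES",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal/(mol·K)

_SS_NAMES = {"H": "helix", "E": "strand", "C": "loop"}
PAIR_CLASSES = [f"{a}-{b}" for a in ("helix", "strand", "loop")
                for b in ("helix", "strand", "loop")]

METRIC_COLUMNS = ["sg_sg_distance", "chi1_sno", "chi1_proxy", "cb_sg_sg_cb",
                  "rel_sasa_sno", "rel_sasa_proxy", "pka_sno", "pka_proxy"]


@dataclass
class EnsembleParams:
    distance_threshold: float = 6.0   # Å, strict '<' when counting
    sasa: SasaParams = field(default_factory=SasaParams)
    pka: PkaParams = field(default_factory=PkaParams)
    grade: GradeParams = field(default_factory=GradeParams)


@dataclass
class EnsembleSummary:
    per_model: pd.DataFrame            # one row per model
    mean: pd.Series                    # per metric; pKa over non-sentinel only
    sd: pd.Series                      # population sd (ddof=0)
    fraction_below: float              # Sγ–Sγ < threshold
    distance_threshold: float
    sno_pos: int
    proxy_pos: int


def _best_altloc_geometry(model: StructureModel, sno: Residue, proxy: Residue,
                          grade: GradeParams) -> PairGeometry:
    """Highest-occupancy altloc combination for per-model metrics."""
    geoms = pair_geometry(model, sno, proxy, grade)
    if len(geoms) == 1:
        return geoms[0]

    def occ(res: Residue, alt: str) -> float:
        atom = res.get_atom("SG", alt)
        return atom.occupancy if atom is not None else 0.0

    return max(geoms, key=lambda g: occ(sno, g.altloc_sno) + occ(proxy, g.altloc_proxy))


def analyze_ensemble(
    ensemble: Ensemble,
    sno_pos: int,
    proxy_pos: int,
    params: EnsembleParams | None = None,
) -> EnsembleSummary:
    """Per-model metric rows plus mean/sd and the distance-threshold fraction.

    pKa means and sds are computed over non-sentinel values only; if every
    model is sentinel the mean is NaN. Single-model ensembles are valid and
    give sd 0.
    """
    params = params or EnsembleParams()
    rows = []
    for model in ensemble:
        sno = model.find(sno_pos)
        proxy = model.find(proxy_pos)
        if sno is None or proxy is None:
            raise ValueError(f"positions {sno_pos}/{proxy_pos} not in model "
                             f"{model.model_id}")
        for res in (sno, proxy):
            if res.resname != "CYS":
                raise TypeError(f"position {res.resseq} is {res.resname}, not CYS")
        pg = _best_altloc_geometry(model, sno, proxy, params.grade)
        per_atom = shrake_rupley(model, params=params.sasa)
        row = {
            "model_id": model.model_id,
            "sg_sg_distance": pg.sg_sg_distance,
            "chi1_sno": pg.chi1_sno,
            "chi1_proxy": pg.chi1_proxy,
            "cb_sg_sg_cb": pg.cb_sg_sg_cb,
            "rotamer_sno": pg.rotamer_sno,
            "rotamer_proxy": pg.rotamer_proxy,
            "grade": pg.grade,
            "rel_sasa_sno": relative_sidechain_sasa(model, sno,
                                                    params=params.sasa,
                                                    per_atom=per_atom),
            "rel_sasa_proxy": relative_sidechain_sasa(model, proxy,
                                                      params=params.sasa,
                                                      per_atom=per_atom),
        }
        for label, res in (("pka_sno", sno), ("pka_proxy", proxy)):
            result = predict_cys_pka(model, res, params.pka,
                                     per_atom_sasa=per_atom,
                                     sasa_params=params.sasa)
            row[label] = result.value
            row[label + "_unphysical"] = result.is_unphysical
        rows.append(row)

    per_model = pd.DataFrame(rows)
    mean = {}
    sd = {}
    for col in METRIC_COLUMNS:
        values = per_model[col].to_numpy(dtype=float)
        if col.startswith("pka"):
            values = values[per_model[col + "_unphysical"].to_numpy() == False]  # noqa: E712
        if values.size == 0:
            mean[col] = float("nan")
            sd[col] = float("nan")
        else:
            mean[col] = float(np.mean(values))
            sd[col] = float(np.std(values, ddof=0))
    distances = per_model["sg_sg_distance"].to_numpy(dtype=float)
    return EnsembleSummary(
        per_model=per_model,
        mean=pd.Series(mean),
        sd=pd.Series(sd),
        fraction_below=fraction_below(distances, params.distance_threshold),
        distance_threshold=params.distance_threshold,
        sno_pos=sno_pos,
        proxy_pos=proxy_pos,
    )


def summary_from_metric_samples(
    per_model: pd.DataFrame,
    sno_pos: int,
    proxy_pos: int,
    distance_threshold: float = 6.0,
) -> EnsembleSummary:
    """Build an :class:`EnsembleSummary` from an externally computed
    per-model metric table (columns as in :data:`METRIC_COLUMNS`; missing
    metrics are allowed and come back NaN). Useful when the per-model
    metrics come from another tool or from a simulation study design."""
    mean = {}
    sd = {}
    for col in METRIC_COLUMNS:
        if col in per_model.columns:
            flag = col + "_unphysical"
            values = per_model[col].to_numpy(dtype=float)
            if col.startswith("pka") and flag in per_model.columns:
                values = values[~per_model[flag].to_numpy(dtype=bool)]
            mean[col] = float(np.mean(values)) if values.size else float("nan")
            sd[col] = float(np.std(values, ddof=0)) if values.size else float("nan")
        else:
            mean[col] = float("nan")
            sd[col] = float("nan")
    if "sg_sg_distance" in per_model.columns:
        frac = fraction_below(per_model["sg_sg_distance"].to_numpy(dtype=float),
                              distance_threshold)
    else:
        frac = float("nan")
    return EnsembleSummary(per_model=per_model, mean=pd.Series(mean),
                           sd=pd.Series(sd), fraction_below=frac,
                           distance_threshold=distance_threshold,
                           sno_pos=sno_pos, proxy_pos=proxy_pos)


def fraction_below(values, threshold: float) -> float:
    """count(values < threshold) / n; boundary values count as 'higher'."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("fraction_below undefined for empty input")
    return float(np.count_nonzero(values < threshold) / values.size)


def pmf_1d(
    samples,
    n_bins: int = 30,
    temperature_K: float = 298.0,
    bin_range: tuple[float, float] | None = None,
):
    """Pseudo-free-energy profile from a sample histogram.

    F_i = −RT ln(p_i), shifted so the minimum is 0; empty bins are NaN
    (undefined, not zero). Returns (bin_centers, free_energy) in kcal/mol.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("pmf_1d needs at least one sample")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts, edges = np.histogram(samples, bins=n_bins, range=bin_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = counts / counts.sum()
    with np.errstate(divide="ignore"):
        f = -GAS_CONSTANT_KCAL * temperature_K * np.log(p)
    f[counts == 0] = np.nan
    f = f - np.nanmin(f)
    return centers, f


def classify_pair_ss(ss_sno: str, ss_proxy: str) -> str:
    """Nine-class secondary-structure label, SNO-site element first."""
    if ss_sno not in _SS_NAMES or ss_proxy not in _SS_NAMES:
        raise ValueError(f"secondary-structure symbols must be in {{H,E,C}}, "
                         f"got ({ss_sno!r}, {ss_proxy!r})")
    return f"{_SS_NAMES[ss_sno]}-{_SS_NAMES[ss_proxy]}"


@dataclass
class VariantParams:
    tol_pka: float = 0.5       # |Δ pKa| within which pKa counts as similar
    tol_distance: float = 0.5  # Å
    large_pka: float = 2.0     # Δ pKa at/above which the variant is
                               # destabilizing regardless of distance


@dataclass
class VariantEffect:
    label: str                 # stabilizing | neutral | destabilizing | uncertain
    delta_pka: float           # mutant − WT, ensemble means (site pKa)
    delta_distance: float      # Å, mutant − WT
    reason: str = ""


def classify_variant_effect(
    wt: EnsembleSummary,
    mut: EnsembleSummary,
    params: VariantParams | None = None,
) -> VariantEffect:
    """Classify a mutant ensemble against wild type for the SNO mechanism.

    Comparison is on ensemble means (WT and mutant ensembles are
    independent samples, so no per-model pairing is meaningful). Summaries
    whose site pKa is sentinel in every model cannot be compared and come
    back uncertain.
    """
    params = params or VariantParams()
    if (wt.sno_pos, wt.proxy_pos) != (mut.sno_pos, mut.proxy_pos):
        raise ValueError("WT and mutant summaries refer to different pairs")
    dp = float(mut.mean["pka_sno"] - wt.mean["pka_sno"])
    dd = float(mut.mean["sg_sg_distance"] - wt.mean["sg_sg_distance"])
    if np.isnan(dp):
        return VariantEffect("uncertain", dp, dd,
                             reason="sentinel-only pKa in WT or mutant")
    if dp >= params.large_pka:
        return VariantEffect("destabilizing", dp, dd,
                             reason="large pKa increase of the SNO site")
    if abs(dp) <= params.tol_pka and abs(dd) <= params.tol_distance:
        return VariantEffect("neutral", dp, dd)
    if dp < -params.tol_pka and dd < -params.tol_distance:
        return VariantEffect("stabilizing", dp, dd)
    if dp > params.tol_pka and dd > params.tol_distance:
        return VariantEffect("destabilizing", dp, dd)
    return VariantEffect("uncertain", dp, dd, reason="mixed pKa/distance signals")


def cofactor_proximity_flag(
    model: StructureModel,
    residue: Residue,
    cutoff: float = 4.0,
) -> tuple[bool, str | None]:
    """Flag a cysteine whose Sγ is near any non-water HETATM atom.

    Cysteines coordinating a cofactor or metal (e.g. a structural zinc)
    are poor candidates for the disulfide mechanism; this distance flag
    stands in for a full cofactor-transplanting check.
    Returns (flag, nearest ligand resname or None).
    """
    sg = residue.get_atom("SG")
    if sg is None:
        raise ValueError(f"residue {residue.resname}{residue.resseq} has no SG")
    nearest = None
    nearest_d = np.inf
    for ligand in model.ligands():
        for atom in ligand.atoms:
            d = float(np.linalg.norm(atom.coord - sg.coord))
            if d < nearest_d:
                nearest_d = d
                nearest = ligand.resname
    if nearest is not None and nearest_d <= cutoff:
        return True, nearest
    return False, None


def variants_table(
    wt_summary: EnsembleSummary,
    mutant_summaries: dict[str, EnsembleSummary],
    params: VariantParams | None = None,
) -> pd.DataFrame:
    """Classification table over a set of named mutant ensembles."""
    rows = []
    for mutation, summary in sorted(mutant_summaries.items()):
        eff = classify_variant_effect(wt_summary, summary, params)
        rows.append({"mutation": mutation, "delta_pka": eff.delta_pka,
                     "delta_distance": eff.delta_distance, "label": eff.label,
                     "reason": eff.reason})
    return pd.DataFrame(rows, columns=["mutation", "delta_pka",
                                       "delta_distance", "label", "reason"])
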