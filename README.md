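# snotools

Structural analysis of protein S-nitrosylation (SNO) sites and the
cysteines around them.

S-nitrosylation attaches a nitric-oxide moiety to a cysteine thiol. An
S-nitrosylated cysteine can be attacked by the thiol of a nearby reduced
cysteine, resolving into a disulfide bridge — a redox switch that can alter
protein stability and function. Whether that is geometrically possible
depends on the local structure: the Sγ–Sγ distance between the two sulfurs
(canonical disulfides sit near 2.05 Å, candidates below ~2.5 Å), the χ1
side-chain rotamers of both cysteines (trans/minus/plus; the strained plus
state disfavours bridging), and the Cβ-Sγ-Sγ-Cβ inter-residue torsion
(near ±90° in native disulfides). `snotools` is a toolkit for researchers
studying redox PTMs who want to screen structure models for such candidate
pairs and to quantify, over structural ensembles, how often a pair visits
disulfide-compatible states — the population-shift picture of SNO-induced
bridge formation.

## What it computes

* **Pair discovery** — cysteines in side-chain center-of-mass contact
  (default cutoff 8 Å) with a known SNO site, split into *vicinal* pairs
  (fewer than 8 residues apart in sequence, CXXC-like) and *proximal* pairs
  (spatially close, sequence-distant), with per-site bookkeeping of missing
  models, non-cysteine positions and out-of-range positions.
* **Pair stereochemistry** — Sγ–Sγ distance, χ1(SNO), χ1(proxy),
  Cβ-Sγ-Sγ-Cβ for every altloc combination, graded A–D (A: distance in
  [1.8, 2.5] Å, |torsion| within 30° of 90°, no plus rotamer; B: distorted
  torsion; C: sulfurs too close; D: strained rotamer).
* **Annotations** — Shrake–Rupley relative side-chain accessibility
  (extended Gly-X-Gly reference), Kabsch–Sander 3-state secondary
  structure, per-residue model confidence (pLDDT from the B-factor column),
  an empirical 3-term cysteine pKa (sentinel 99.99 for disulfide-locked
  thiols), and a HETATM-proximity cofactor flag.
* **Ensemble statistics** — per-model metric tables over multi-model PDB
  ensembles, means/standard deviations, the fraction of models with
  Sγ–Sγ below a threshold (default 6 Å), and histogram-based
  pseudo-free-energy profiles F = −RT ln p.
* **Variant classification** — a mutant ensemble versus wild type:
  *stabilizing* (lower site pKa and shorter Sγ–Sγ distance), *neutral*
  (both similar), *destabilizing* (both higher/longer, or any large pKa
  increase), *uncertain* otherwise.

## Worked example

Generate a small synthetic demonstration dataset (three proteins with an
engineered cysteine pair each, plus one site with a deliberately missing
model and one pointing at a serine), then run the discovery pipeline:

```bash
snotool fixtures --recipe sites-demo --seed 0 --out demo
snotool find --sites demo/sites.tsv --models demo --out demo_out
```

The run prints the bookkeeping and per-protein rollup:

```json
{
  "n_input_sites": 5,
  "n_missing_model": 1,
  "n_not_cysteine": 1,
  "n_out_of_range": 0,
  "n_analyzed": 3,
  "n_with_partner": 3,
  "n_pass_sasa": 3
}
```

Five input sites partition exactly into one with no model file, one whose
position is a serine in the model, and three analyzed cysteines — each of
which has a partner cysteine and a solvent-accessible site. `demo_out/`
then contains `pairs_all.csv`, `pairs_vicinal.csv`, `pairs_proximal.csv`,
`pairs_filtered.csv` and `bookkeeping.json`. The first annotated pair row
reads, in part:

```
sno_pos=4  partner_pos=30  category=proximal  sg_sg_distance=5.00 Å
cb_sg_sg_cb=-90.0°  rotamers=(m,m)  grade=none  rel_sasa_sno=95.6 %
ss=(C,C)  plddt=90.0  pka_sno=9.09
```

The pair was constructed 5 Å apart, so it is in COM contact (a candidate)
but not yet disulfide-compatible (grade `none`; distances above 2.5 Å are
not graded). The site is well exposed (95.6% relative side-chain SASA) and
its predicted pKa is near the intrinsic cysteine value of 9.

Ensembles and variants run the same way:

```bash
snotool models   --ensemble ens.pdb --sno 501 --proxy 527 --out out/
snotool variants --wt wt.pdb --mut-dir muts/ --mutations muts.txt \
                 --sno 124 --proxy 141 --out out/
```

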