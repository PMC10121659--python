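# Methods

This note documents the models, conventions and numerical choices behind
`snotools`, in the order the toolchain runs.

## Structure model

Coordinate files (PDB; mmCIF optional) are parsed with gemmi into a
lightweight hierarchy: `Ensemble` → `StructureModel` (one per MODEL
record) → `Residue` (author numbering; `(chain, resseq, icode)` is the
identity) → `Atom`. Alternate locations are never collapsed: every altloc
conformer is kept as its own atom, and downstream geometry enumerates the
cross product of conformers so that, e.g., a partner cysteine refined in
two alternative positions contributes two geometry rows. HETATM residues
are kept on a separate ligand list (waters excluded) and feed only the
cofactor-proximity flag. Occupancies outside [0, 1] are clamped with a
warning. All models of a multi-model file must share the
(chain, resseq, resname) topology; the first mismatching residue is named
in the error.

Predicted models carry their per-residue confidence (pLDDT, 0–100) in the
B-factor column; the per-residue profile is the mean over the residue's
atoms. Experimental B-factors pass through the same accessor and their
interpretation is left to the caller.

### Confidence trimming

Before ensemble sampling, predicted models are commonly stripped of
low-confidence tails and long disordered linkers. `trim_low_confidence`
removes contiguous runs below the threshold when they are terminal, or
internal and at least `max_internal_loop` residues long; shorter internal
loops that connect confident segments are kept. Defaults: threshold 50
(the boundary of the "very low" confidence band — the specific cutoff is a
package choice and is configurable) and 20 residues for the internal-loop
bound. Query sites inside removed or ≥20-residue low-confidence segments
are flagged disqualified; the discovery pipeline keeps such rows but marks
them `disordered_region=true` so the caller can apply the discard.

## Pair geometry and grading

Torsions use the IUPAC sign convention (positive clockwise looking along
the central bond); the implementation was frozen against an independent
reference routine and is invariant under rigid motion and under reversing
the four points, and changes sign under mirror reflection. χ1 is
N-CA-CB-Sγ, binned into rotamers p = (0°, 120°], m = (−120°, 0°], t =
remainder; the bin edges are the standard gauche/trans thirds with
boundary values assigned to the lower-closed bin (so exactly −120° and
180° are trans).

Candidate disulfide stereochemistry is graded on the distance/torsion/
rotamer triple: **A** when 1.8 Å ≤ d(Sγ–Sγ) ≤ 2.5 Å, the Cβ-Sγ-Sγ-Cβ
magnitude is within 30° of 90°, and neither χ1 is in the strained plus
state; **B** when the distance is in range but the torsion is not; **C**
when the sulfurs are closer than 1.8 Å (too close to bond); **D** when
distance and torsion are acceptable but a plus rotamer is present; no
grade above 2.5 Å. The A–D scheme concretises the qualitative grades used
by stereochemical disulfide databases; the windows (1.8 Å floor, ±30°)
are package choices, exposed in `GradeParams`.

## Solvent accessibility

Shrake–Rupley with a deterministic golden-spiral point set (default 960
points per atom; convergence against 3840 points is under 1% on the test
fixtures), probe 1.4 Å, heavy atoms only, element radii C 1.70, N 1.55,
O 1.52, S 1.80 Å (configurable). Neighbour search uses a k-d tree.

Relative side-chain accessibility divides the side-chain area in context
by the side-chain area of the same residue type in an extended Gly-X-Gly
tripeptide built by the package's own scaffold generator. This
self-calibration makes the 100% point exact by construction and avoids
importing any external reference table; it deliberately sidesteps the
question of which reference convention (Gly-X-Gly vs Ala-X-Ala) other
accessibility programs use, so absolute percentages are comparable within
the package but may differ by a few percent from other tools. Distorted
conformations can exceed 100%. Glycine has no side chain: its relative
side-chain SASA is defined as 0 with a warning.

The discovery pipeline's accessibility filter keeps sites with relative
side-chain SASA ≥ 10% (inclusive; configurable).

## Secondary structure

Backbone hydrogen bonds use the Kabsch–Sander electrostatic energy
E = 27.888 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a bond
below −0.5 kcal/mol. Amide hydrogens are reconstructed at 1.01 Å from N,
anti to the preceding carbonyl (none on chain-initial residues or
prolines). Helix comes from i→i+4 (then i→i+3) turns on two consecutive
residues; strand from Kabsch–Sander parallel/antiparallel bridge patterns;
everything else is loop. Only the 3-state collapse {H, E, C} is exposed
(helix classes → H, bridge/extended → E), because the pair taxonomy
downstream needs exactly helix/strand/loop. On ideal helix and
antiparallel-sheet fixtures the assignment matches an independent DSSP
implementation residue for residue.

The nine pair classes (`helix-helix` … `loop-loop`, SNO-site element
first) are assigned from the input model, not per ensemble member; a
per-member assignment can be obtained by calling the classifier on each
model when sensitivity to conformational heterogeneity matters.

## Cysteine pKa

A transparent three-term additive surrogate around the intrinsic cysteine
value:

pKa = 9.0 + 2.0 · max(0, 1 − relSASA/100) + Σ_donors (−0.8) + Σ_charges ± 0.5 · (7 − d)/7

Donors are backbone amides and side-chain O-H/N-H groups whose heavy atom
is within 3.5 Å of Sγ; charge centers (Arg CZ, Lys NZ, His imidazole
midpoint — His is treated as protonated by default, the worst case —
Asp/Glu carboxylate midpoints) within 7 Å contribute with a linear
distance taper, cations lowering and anions raising the value. The
cysteine's own atoms are excluded from the environment: its backbone amide
is always ~3.3 Å from Sγ and belongs to the intrinsic value, not the
context (this keeps the contract "isolated exposed cysteine → 9.0" exact).
A cysteine whose Sγ lies within 2.5 Å of another cysteine's Sγ — the same
ceiling the disulfide grade uses — is not a titratable thiol and returns
the conventional sentinel 99.99 with `is_unphysical` set. Sentinel rows
are kept in output tables and excluded from ensemble means.

All coefficients live in `PkaParams`. The tests assert the model's own
contract (additivity, burial monotonicity, cation/anion direction,
sentinel trigger), not agreement with any external predictor; an optional
`delegate` hook passes predictions through verbatim, including a
delegate's own 99.99 sentinels.

## Contact search

Residue side-chain centers of mass use heavy atoms beyond Cα with standard
atomic masses. Glycines have no COM and are excluded from the network
entirely — as sites, as partners, and as mutation-neighbourhood members
(so glycine mutations cannot be assessed). The contact cutoff is 8 Å by
default with 11 Å kept as a control; a pair is in contact when any altloc
combination is within the (inclusive) cutoff. Sequence classification:
|Δ| < 8 → vicinal (the bound is exclusive, so Δ = 7 is the largest vicinal
separation), otherwise proximal; |Δ| = 1 adds a sequence-adjacent flag.
Inter-chain pairs have no meaningful sequence separation and are reported
as proximal with an `inter_chain` flag rather than dropped.

## Discovery pipeline bookkeeping

Every input site is partitioned exactly once: missing model, position not
in model, position not cysteine, or analyzed — the identity
`n_input = n_missing + n_out_of_range + n_not_cys + n_analyzed` is
asserted on every run and fuzzed over random synthetic site tables in the
tests. The pipeline is deterministic (no RNG), so reruns on identical
inputs are byte-identical.

## Ensemble analysis

Per-model metrics use the highest-occupancy altloc combination within each
model. Summary statistics are means and population standard deviations
(ddof = 0); pKa statistics are over non-sentinel values only. The distance
fraction uses strict `<` at the threshold (default 6 Å), so a model
exactly at the threshold counts as "higher". Pseudo-free-energy profiles
are F_i = −RT ln p_i (R = 1.9872×10⁻³ kcal/(mol·K)), shifted so the
minimum is 0; empty bins are undefined (NaN), never 0.

## Variant classification

Mutant and wild-type ensembles are independent samples, so the comparison
is on ensemble means, not per-model pairing. With Δp = mean site pKa
(mut − WT) and Δd = mean Sγ–Sγ distance (mut − WT):

| condition | label |
|---|---|
| Δp ≥ 2.0 | destabilizing (large pKa increase alone suffices) |
| \|Δp\| ≤ 0.5 and \|Δd\| ≤ 0.5 Å | neutral |
| Δp < −0.5 and Δd < −0.5 Å | stabilizing |
| Δp > 0.5 and Δd > 0.5 Å | destabilizing |
| otherwise | uncertain |

The tolerances (0.5 pKa units, 0.5 Å, large = 2.0) quantify "similar" and
"large", which are qualitative in the underlying classification scheme;
they were set at roughly the sampling noise of 20-model ensemble means and
are exposed in `VariantParams`. Summaries whose site pKa is sentinel in
every model come back uncertain with a reason. Where both deltas exceed
tolerance the rule is antisymmetric: swapping WT and mutant maps
stabilizing to destabilizing.

## Synthetic data

The fixture generator is first-class, tested code and defines the study
conditions for every test and for the acceptance script:

* **Scaffolds** — ideal-geometry backbones (N-CA 1.458, CA-C 1.525,
  C-N 1.329, C-O 1.231 Å; tetrahedral/trigonal angles; ω = 180°) built by
  torsion-driven chain extension at φ/ψ = (−57°, −47°) helix,
  (−139°, 135°) strand, or seeded random coil. Side chains are full
  heavy-atom ideal templates from the chemical-component library shipped
  with biotite, grafted onto the backbone frame and rotated to the
  requested χ1 (default −60°).
* **Cysteine-pair constructs** — a second scaffold rigidly placed so the
  measured Sγ–Sγ distance and Cβ-Sγ-Sγ-Cβ hit their targets exactly (two
  remaining torsional degrees of freedom are scanned for a clash-free
  pose; a pose with backbone atoms closer than 1 Å is a placement error).
  These fixtures are self-validating: the geometry module reads the
  targets back.
* **Sheet fixture** — an extended strand plus its 180°-rotated copy at
  3.6 Å separation, giving an antiparallel H-bond registry whose interior
  residues are assigned strand by both this package and the reference
  implementation.
* **Ensembles** — n jittered copies of a base model (default 20 models,
  matching typical coarse-grained sampler output; Gaussian coordinate
  jitter 0.3 Å sd) with cysteine χ1 resampled from per-residue
  (t, m, p) weights before jitter, so realised rotamer fractions are exact
  only at small jitter. Fully reproducible from (spec, seed).
* **Site tables** — dbPTM-like TSVs with matching model files and
  controllable injected errors (missing model, non-cysteine position,
  out-of-range position) plus a manifest of the expected bookkeeping.

These fixtures emulate geometry, accessibility and topology, not physics:
there is no energy function, no real conformational correlation along the
chain, and no force-field realism. Green tests therefore establish the
correctness of the measurements and classification logic, not the
biological realism of any particular ensemble.

## Problem sizes

The default test run uses small scaffolds (7–30 residues), 20-model
ensembles, 100-trial classifier recovery per rule region, 100 random
contact-search fixtures and 50 fuzzed pipeline runs; the acceptance script
uses a 4-protein synthetic dataset, one 20-model ensemble, 10⁵ samples for
the two-state free-energy check and 400 classifier trials. These sizes
were chosen so the full suite completes in well under a minute of compute
per module while keeping binomial noise far from the asserted margins.

## Known limitations

* The pKa model is a surrogate: it reproduces directional physics
  (burial, H-bonding, electrostatics) with fixed coefficients and is not
  expected to match dedicated predictors numerically.
* Relative SASA percentages depend on the self-calibrated reference and
  may differ slightly from NACCESS-style tools.
* Secondary structure is 3-state only; π-helices, bulges and bends all
  collapse into the nearest of H/E/C.
* The contact network is COM-distance only — no interaction typing — and
  glycines are invisible to it.
* Experimental-structure surveys pool whatever structures are supplied;
  retrieval from structure databases is out of scope, so assembling the
  input set (and its altloc conventions) is the caller's responsibility.
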