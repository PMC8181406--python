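# Methods

`rps19struct` analyses how missense mutations damage human RPS19, the
ribosomal protein most frequently mutated in Diamond-Blackfan Anemia (DBA).
The package works from a protein–RNA complex structure (the assembled small
ribosomal subunit), a mutation list, and externally computed per-mutation
stability changes (ΔΔG) and per-site conservation scores. It produces
per-residue burial and interface descriptions, a multi-label structural-basis
call for each mutation, disease-vs-neutral group statistics, and an
RPS19-specific SVM pathogenicity predictor.

## Coordinate model

Structures are read from PDB or mmCIF via gemmi into a uniform
chain/residue/atom model. Author numbering is used everywhere; mutation
positions are 1-based on the canonical 145-residue RPS19 sequence, and the two
coincide unless the caller supplies an offset. Hydrogens are kept when present
but never required (cryo-EM models lack them); for alternate conformations
only the highest-occupancy conformer is retained; waters are dropped. The
chain identifier of RPS19 in a given deposition is configuration, not a
constant.

## Solvent accessibility

SASA uses the Shrake–Rupley rolling-probe method: each atom's expanded sphere
(van der Waals radius + probe, default probe 1.4 Å) is covered with *n*
quasi-uniform points from a deterministic golden-spiral lattice (default
n = 960, so results are bit-reproducible without seeds); a point is exposed
when outside every neighbouring expanded sphere, and per-atom SASA is
`(exposed/n) · 4π(r+probe)²`. Radii are a Bondi-style element table
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å …), configurable; unknown elements
either raise or fall back to 1.70 Å with a warning. Relative SASA divides a
residue's SASA by the maximum SASA of that residue type in an extended
Gly-X-Gly tripeptide (Tien et al. theoretical values, shipped as a constant
table). Values slightly above 1 can occur at termini and are kept unless
clamping is requested. Note that published rSASA values computed with DSSP
differ slightly from Shrake–Rupley output; comparisons against printed values
should allow roughly ±0.03.

## Interface analysis

A residue is interfacial when its buried surface area
`BSA = SASA(chain alone) − SASA(chain in complex)` exceeds a threshold
(default 0.1 Å², a PISA-like ΔSASA criterion; the relative form
rBSA = BSA/SASA(alone)). Inter-molecular hydrogen bonds are detected
geometrically: typed heavy-atom donor/acceptor pairs (protein backbone N/O,
side-chain N/O/S groups; RNA phosphate and ribose oxygens, 2′-OH, and base
donors/acceptors) within a distance cutoff (default 3.5 Å), with a D–H…A
angle test (default ≥ 120°) applied only when explicit hydrogens exist. One
bond is counted per unordered atom pair. Published interface statistics from
PISA use undocumented internal criteria, so distance/angle knobs are exposed
and echoed into reports rather than tuned to reproduce a specific printed
bond count.

The five conserved, positively charged RPS19 surface patches (I–V) and the
18S rRNA secondary-structure elements they contact (h42; h41; h42+h43;
h41es10; h39es9) ship as a versioned YAML table; patch assignment is an exact
residue-number lookup, with patch V covering the N-terminal residues 2–9 plus
its listed residues.

## Ensemble flexibility

Backbone RMSF superposes every model of an ensemble onto the ensemble-average
conformation (Kabsch least squares on N/CA/C/O; the average is iterated to
self-consistency, 3 rounds) and reports per-residue root-mean-square
deviation across models. Mid-chain residues with RMSF above a threshold
(default 2 Å) form intrinsically disordered region (IDR) calls; the first and
last residues are excluded because terminal fraying is not evidence of
disorder. Conformations are clustered with DBSCAN on the pairwise
backbone-RMSD matrix (eps = 2 Å; min_samples = 4 — a low but noise-robust
value for small ensembles, configurable), with medoid representatives and
occupancy = cluster size / ensemble size. Eight-state secondary-structure
strings simplify positionwise to three states: G/H/I→H, B/E→E,
T/S/C/blank→C. Trajectory generation itself (e.g. the µs-scale MD behind
published RPS19 free-state ensembles) is out of scope; the module consumes
any multi-model PDB.

## Residue properties and per-mutation features

Property tables are versioned YAML constants: Zamyatnin residue volumes
(Gly 60.1, Arg 173.4, Glu 138.4 Å³ …), Kyte–Doolittle hydrophobicity,
side-chain formal charges (K/R +1, D/E −1, His +0.5 by default,
configurable), Pace–Scholtz helix propensities (kcal/mol, Pro worst at 3.16),
and TOP-IDP disorder propensities. BLOSUM62 comes from biopython's standard
matrices. Percent changes (volume, hydrophobicity) are taken relative to the
wild-type value, so only their sign — not magnitude — is antisymmetric under
swapping wild type and mutant; absolute deltas (charge, helix, disorder) are
fully antisymmetric. One known discrepancy: a Ser→Phe substitution is a
+113.4% volume change on Zamyatnin volumes, while a figure-caption value of
+134% circulates in the literature for that mutation; the table values are
kept as shipped.

Each mutation's feature vector carries the eight core predictor features —
BSA, rBSA, HB_Num, Δcharge, ΔΔG, Δhelix, BLOSUM62, Δdisorder — plus ten
extended structural/conservation features (rSASA, Δvolume%, Δhydrophobicity%,
conservation, patch membership, proline-substitution flag, absolute Δvolume,
wild-type hydrophobicity, mutant charge, hydrophobic-wild-type flag) forming
an 18-candidate pool for feature selection. Interface features are read from
the wild-type residue's interface record and are 0 for non-interface
residues; missing ΔΔG or conservation entries stay absent rather than being
silently zeroed. ΔΔG tables are consumed in either the package TSV dialect
(`position wt mut ddg`) or a two-column FoldX-PositionScan-style file of
mutation tokens and values. A surrogate ΔΔG estimator (burial-weighted
hydrophobicity loss + volume-clash + proline penalty) exists for synthetic
tests and demos only; it is not a physical energy function and is never a
substitute for FoldX output in real analyses.

## Structural-basis rules

Destabilization: ΔΔG > 1 kcal/mol (the conventional cutoff). Approaches:

* hydrophobic-core loss — buried site (rSASA < 0.2), hydrophobic wild type
  (L/W/V/F), hydrophobicity decreases;
* steric core clash — buried site, small wild type (G/A), volume increase
  ≥ 30%;
* helix breaking — mutant is proline at a helical position. This flag is kept
  even when the supplied ΔΔG is ≤ 1 kcal/mol, because empirical estimators
  are known to be unreliable for proline substitutions.

Interaction disruption (requires an interfacial or in-patch site). Avenues:

* hydrogen-bond loss — the wild type makes ≥ 1 inter-molecular bond through
  its side chain, and the mutant either lacks the needed donor/acceptor
  capability or changes side-chain reach by ≥ 2 bonds (bond-path length from
  CA to the terminal functional atom: Lys 5, Asn 3, Arg 6, Cys 2 …). The
  reach criterion uses bond-path length rather than a heavy-atom count
  because count-preserving substitutions (e.g. Lys→Asn, 5→4 heavy atoms but
  5→3 bonds of reach) still pull the bonding group several Å away.
  Backbone-mediated bonds survive any substitution;
* electrostatic alteration — in-patch site with Δcharge ≤ −1 (the patches are
  positively charged and bind the rRNA backbone);
* interface steric clash — interfacial site with volume increase ≥ 30%.

The burial (0.2) and steric (+30%) thresholds are package choices: the source
analyses describe these mechanisms qualitatively (destabilizing sites
"more buried", clash examples near +40% and +113%) without publishing
cutoffs. Both are configurable and echoed into every report. Flags are
multi-label; an empty basis with an explanatory note is a valid outcome — the
rule set does not claim to cover every disease mutation.

## Statistics

Group comparisons use the one-tailed Mann–Whitney U test: exact enumeration
when the smaller sample has ≤ 8 tie-free values, otherwise the normal
approximation with tie and continuity corrections (scipy implementation).
Medians of even-sized samples are the mean of the central pair. No
multiple-testing correction is applied. Classifier metrics are ACC, F1, MCC
(0 when a marginal is empty) and FPR = FP/(FP+TN).

## SVM protocol

Exhaustive search over all feature combinations of size ≥ 5 from the
candidate pool, crossed with an RBF-kernel C/γ grid of
{0.001, 0.01, 0.1, 1, 100}², scored by stratified fivefold cross-validation
MCC (pooled confusion across folds; per-fold mean also reported, since
pooling vs averaging is a genuine protocol ambiguity). Features are z-scored
with training-fold statistics only, so CV estimates are leakage-free; folds
are fixed by a seed (stratification matters at ~29/30 class balance). Ties
break deterministically: fewer features, then smaller C, smaller γ,
lexicographic feature names. The winner is refit on all data, and scores in
[0, 1] come from a Platt sigmoid fitted to the refit model's decision values
(deterministic, monotone in the margin). A saturation scan applies the model
to every position × 19 substitutions (2,755 predictions for the 145-residue
protein). The full 18-feature enumeration (~260k combinations × 25 grid
points) is allowed but guarded by a fit budget; the default demonstration
pool is smaller. No nested CV is used, matching the original protocol — CV
estimates after exhaustive selection are optimistically biased, which is a
known caveat.

## Synthetic data

The generators define the study conditions for all desk-scale tests:

* toy complexes — an ideal α-helical protein (rise 1.5 Å, 100°/residue,
  CA radius 2.3 Å) with serine contacts planted against a reduced-atom
  pseudo-RNA chain (P, OP1, OP2, O5′, C1′, N1 — enough for donor/acceptor
  typing, no real nucleotide geometry). H-bond positions put a phosphate
  oxygen 2.9 ± 0.1 Å from the serine OG; plain contacts sit at 4.0 Å
  (occluding but out of bond range); all other residues stay ≥ ~8 Å from RNA.
* ensembles — Gaussian per-coordinate jitter around the base helix,
  σ = 0.3 Å in rigid regions and 2.5 Å in planted floppy intervals, so
  expected RMSF is σ√3.
* feature tables — class sizes default to the real dataset (51 disease / 30
  neutral; 29/30 for training demonstrations) and class medians are pinned to
  the published values: ΔΔG 1.55 vs 0.106 kcal/mol, rSASA 0.13 vs 0.42,
  conservation −0.665 vs 0.0995. Dispersions are package choices made once
  for realism: disease ΔΔG is log-normal with log-scale σ = 0.8 (stability
  penalties are right-skewed, reaching ~19 kcal/mol in the real data),
  neutral ΔΔG is normal with σ = 0.35 kcal/mol, rSASA uses beta distributions
  with matching medians, conservation is normal with σ = 0.5. With n ≈ 30–51
  per class, the sampling error of a sample median under these spreads
  exceeds 15% of small-magnitude targets (most visibly the neutral
  conservation median, 0.0995), so median-recovery tests assert 15% relative
  only where the sampling error permits and absolute bands elsewhere. A
  `separation` dial scales class separation (0 = null tables for negative
  controls); the default 1.0 is the study condition.

What passing tests on these generators shows: the geometry, statistics and
learning machinery behave correctly under controlled truth. What it does not
show: performance on real structures (real side-chain packing, non-ideal
geometry, correlated features) or the published classifier's exact headline
numbers, which depend on external inputs (below).

## Reproducing the structure- and data-dependent results

The repository is self-contained and offline; three published result groups
need external inputs:

* Interface and burial of the real complex — download the human SSU entry:
  `curl -o scratch/6g5h.cif https://files.rcsb.org/download/6G5H.cif`, then
  run the interface/SASA stages on the RPS19 chain against 18S rRNA
  (~75 interface residues, 51.7% of the chain, ~46 inter-molecular H-bonds,
  rSASA(Trp52) ≈ 0.067, rSASA(Gly120) ≈ 0.135; method-dialect differences vs
  PISA/DSSP of a few residues / ±0.03 are expected).
* ΔΔG values — run FoldX: iterative `RepairPDB` on the extracted RPS19
  coordinates until the energy decrease is < 1 kcal/mol over 5 iterations,
  then `PositionScan` over all sites; load the output with the PositionScan
  reader.
* Conservation — submit the RPS19 sequence to the Consurf server and export
  normalized scores (mean 0, SD 1; lower = more conserved) as a two-column
  TSV.

With those inputs plus the curated mutation tables, the classifier protocol
(C/γ grid, ≥ 5-feature exhaustive selection, fivefold CV maximizing MCC)
reproduces the published training recipe; its headline numbers (26/29 CV
positives, FPR 8% on 25 held-out population variants, best C = 100,
γ = 0.01) are not desk-reproducible without them, and only the confusion
arithmetic is asserted offline.

## Problem sizes and runtime choices

Default test problem sizes — 20-residue toy complexes, 300-model ensembles of
40 residues, 81-row feature tables, 7-candidate selection pools — were chosen
so each check isolates one mechanism and the whole suite runs on a laptop in
minutes; enlarging them changes precision, not behaviour.

## Known limitations

No mutant side-chain rebuilding or repacking: rules judge the mutant from
typing tables, not geometry. No molecular (solvent-excluded) surface, no
interface free energies, no pKa-dependent charges, no 8-state secondary
structure assignment from geometry (DSSP-format strings are consumed).
Special-case reasoning about individual mutations (e.g. a Lys→Arg gaining an
intra-molecular bond that restrains an IDR) is reported as a note, not a
rule. HGVS cDNA notation is not parsed; analyses are protein-level.
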