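# rps19struct

Structural interpretation of missense mutations in human RPS19, the ribosomal
protein most often mutated in Diamond-Blackfan Anemia (DBA). Given a
protein–RNA complex structure, a mutation list, per-mutation folding
stability changes (ΔΔG) and per-site conservation scores, the package
computes per-residue burial (SASA/rSASA) and protein–rRNA interface
descriptors (BSA, hydrogen bonds, conserved surface patches), classifies the
structural basis of each mutation (destabilization via hydrophobic-core loss,
core steric clash or helix-breaking proline; interaction disruption via
hydrogen-bond loss, electrostatic alteration or interface clash), compares
disease and neutral groups with one-tailed Mann–Whitney U tests, and trains a
protein-specific RBF-SVM pathogenicity predictor with exhaustive feature
selection (≥ 5 of 18 candidates, C/γ ∈ {0.001, 0.01, 0.1, 1, 100}, stratified
fivefold CV maximizing MCC) able to score all 145 × 19 = 2,755 possible
substitutions.

The core quantities, in the field's usual notation:

* rSASA(i) = SASA(i) / maxSASA(aa_i), with maxSASA from an extended Gly-X-Gly
  context; BSA(i) = SASA_alone(i) − SASA_complex(i).
* A mutation is destabilizing when ΔΔG > 1 kcal/mol.
* Model selection maximizes MCC =
  (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)) over folds pooled.

Everything runs offline: synthetic generators provide toy complexes,
conformational ensembles and labeled feature tables that reproduce the real
dataset's class median structure (ΔΔG 1.55 vs 0.106 kcal/mol, rSASA 0.13 vs
0.42, conservation −0.665 vs 0.0995 for 51 disease / 30 neutral mutations).

## Worked example

```python
from rps19struct import (ToyComplexSpec, make_toy_complex, interface_residues,
                         hydrogen_bonds, hbonds_per_residue,
                         estimate_pathogenic_maf)

complex_ = make_toy_complex(ToyComplexSpec(
    n_protein_residues=20, contact_positions=(5, 9, 14),
    hbond_positions=(5, 9), seed=1))
records = interface_residues(complex_, "A", ["R"])
bonds = hydrogen_bonds(complex_, ["A"], ["R"])
print([r.residue_number for r in records if r.is_interface])
print(hbonds_per_residue(bonds, "A"))
print(estimate_pathogenic_maf(5e-6, 7e-6, 0.25))
```

prints

```
[5, 9, 14]
{5: 1, 9: 1}
(6.25e-07, 8.75e-07)
```

— the three planted contact residues are recovered as the interface, the two
planted hydrogen bonds are found at residues 5 and 9, and the estimated
allele-frequency band for pathogenic RPS19 mutations (disease prevalence 5–7
per million × 25% of cases ÷ 2 alleles under dominant inheritance) is
6.25×10⁻⁷ – 8.75×10⁻⁷, the bound used to screen population variants when
building a neutral set.

The `examples/` directory has one short script per capability (interface
analysis, ensemble flexibility, group statistics, SVM training + saturation
scan, mutation curation); each prints what it computes and what the numbers
mean. A thin CLI mirrors the stages:
`rps19struct sasa|interface|flex|classify|compare|train|scan|simulate|run`.

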