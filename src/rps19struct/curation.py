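"""Mutation notation parsing and dataset curation rules.

Implements the curation protocol for an RPS19 mutation dataset: positive
(disease) mutations must be multiply observed in patients, annotated
Pathogenic/Likely pathogenic, or functionally confirmed; negative (neutral)
variants come from population data with allele frequencies at least an order
of magnitude above the estimated pathogenic-allele frequency, after removing
anything ever recorded as a disease mutation.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .structures import AA1_TO_3, AA3_TO_1

__all__ = [
    "MutationRecord",
    "MutationParseError",
    "parse_protein_mutation",
    "format_protein_mutation",
    "estimate_pathogenic_maf",
    "select_positives",
    "select_negatives",
    "load_mutation_table",
]


class MutationParseError(ValueError):
    pass


@dataclass
class MutationRecord:
    position: int                  # 1-based on the canonical 145-residue sequence
    wt: str                        # one-letter
    mut: str                       # one-letter
    label: str = "unlabeled"       # dba | neutral | unlabeled
    patient_count: int | None = None
    clinvar_significance: str | None = None
    functional_evidence: bool | None = None
    allele_frequency: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.wt == self.mut:
            raise MutationParseError(f"synonymous change {self.wt}{self.position}")
        if self.position < 1:
            raise MutationParseError(f"position {self.position} must be >= 1")
        if self.label not in ("dba", "neutral", "unlabeled"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def name(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


_THREE = re.compile(r"^([A-Za-z]{3})(\d+)([A-Za-z]{3})$")
_ONE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")


def parse_protein_mutation(text: str) -> tuple[int, str, str]:
    """Parse ``Gly127Arg`` or ``G127R`` into (position, wt, mut) one-letter codes."""
    text = text.strip()
    m = _THREE.match(text)
    if m:
        wt3, pos, mut3 = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        if wt3 not in AA3_TO_1 or mut3 not in AA3_TO_1:
            raise MutationParseError(f"unknown residue name in {text!r}")
        wt, mut = AA3_TO_1[wt3], AA3_TO_1[mut3]
    else:
        m = _ONE.match(text)
        if not m:
            raise MutationParseError(f"cannot parse mutation {text!r}")
        wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
        if wt not in AA1_TO_3 or mut not in AA1_TO_3:
            raise MutationParseError(f"unknown residue code in {text!r}")
    if wt == mut:
        raise MutationParseError(f"synonymous change {text!r}")
    return pos, wt, mut


def format_protein_mutation(position: int, wt: str, mut: str,
                            style: str = "three") -> str:
    if style == "three":
        return f"{AA1_TO_3[wt].capitalize()}{position}{AA1_TO_3[mut].capitalize()}"
    return f"{wt}{position}{mut}"


def estimate_pathogenic_maf(prevalence_low: float, prevalence_high: float,
                            gene_fraction: float,
                            inheritance: str = "dominant") -> tuple[float, float]:
    """Bounds on the allele frequency of pathogenic alleles in one gene.

    For an autosomal-dominant disease with prevalence p (per individual) and a
    fraction f of cases attributable to the gene, each affected individual
    carries one pathogenic allele out of two, so MAF = p * f / 2.  With DBA
    prevalence 5-7 per million and RPS19 causing ~25% of cases this gives
    6.25e-7 to 8.75e-7.
    """
    if inheritance != "dominant":
        raise NotImplementedError("only autosomal-dominant inheritance is modelled")
    if prevalence_low < 0 or prevalence_high < prevalence_low:
        raise ValueError("need 0 <= prevalence_low <= prevalence_high")
    if not 0 <= gene_fraction <= 1:
        raise ValueError("gene_fraction must be within [0, 1]")
    return (prevalence_low * gene_fraction / 2.0,
            prevalence_high * gene_fraction / 2.0)


def _is_positive(rec: MutationRecord) -> bool:
    if rec.patient_count is not None and rec.patient_count > 1:
        return True
    sig = (rec.clinvar_significance or "").strip().lower()
    if sig in ("pathogenic", "likely pathogenic"):
        return True
    if rec.functional_evidence:
        return True
    return False


def select_positives(records: list[MutationRecord]) -> list[MutationRecord]:
    """Disease mutations meeting at least one positive-evidence criterion.

    Criteria: observed in more than one patient; ClinVar Pathogenic or Likely
    pathogenic; or experimentally confirmed to affect RPS19 function.
    """
    return [r for r in records if _is_positive(r)]


def select_negatives(variants: list[MutationRecord], maf_upper: float,
                     exclusion_list: set[str] | None = None,
                     orders_of_magnitude: int = 1) -> list[MutationRecord]:
    """Population variants safe to treat as neutral.

    Keeps variants whose allele frequency is at least ``10^orders_of_magnitude``
    times the upper bound of the pathogenic MAF estimate, excluding any variant
    name on the exclusion list (protein-level names, e.g. ``R62W``).
    """
    exclusion = exclusion_list or set()
    threshold = maf_upper * 10.0 ** orders_of_magnitude
    out = []
    for v in variants:
        if v.allele_frequency is None or v.allele_frequency < threshold:
            continue
        if v.name in exclusion or format_protein_mutation(
                v.position, v.wt, v.mut) in exclusion:
            continue
        out.append(v)
    return out


_COLUMNS = ("position", "wt", "mut", "label", "patient_count", "clinvar",
            "functional", "af")


def load_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read the package's mutation TSV dialect.

    Columns: position, wt, mut, label, patient_count, clinvar, functional, af
    (all but the first three optional; empty cells allowed).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"position", "wt", "mut"} - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(MutationRecord(
            position=int(row["position"]),
            wt=row["wt"].strip(),
            mut=row["mut"].strip(),
            label=(row.get("label", "") or "unlabeled").strip() or "unlabeled",
            patient_count=int(row["patient_count"]) if row.get("patient_count") else None,
            clinvar_significance=row.get("clinvar") or None,
            functional_evidence=(row.get("functional", "").strip().lower()
                                 in ("1", "true", "yes"))
                                if row.get("functional") else None,
            allele_frequency=float(row["af"]) if row.get("af") else None,
        ))
    return records
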