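"""Residue property tables and per-mutation delta computations.

Tables (volume, hydrophobicity, formal charge, helix propensity, disorder
propensity, max SASA) ship as a versioned YAML constant inside the package and
can be overridden by loading a user YAML of the same shape.  The BLOSUM62
substitution matrix comes from biopython's standard matrices.

Volumes are Zamyatnin residue volumes; Gly 60.1, Arg 173.4 and Glu 138.4 A^3,
so a Gly->Arg substitution is a +188.52% volume change and Gly->Glu +130.28%.
Hydrophobicity defaults to the Kyte-Doolittle hydropathy index; helix
propensity to Pace-Scholtz; disorder propensity to TOP-IDP.  All scales are
swappable without touching the delta logic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "PropertyTables",
    "load_default_tables",
    "volume_change_pct",
    "hydrophobicity_change_pct",
    "charge_change",
    "helix_propensity_change",
    "disorder_propensity_change",
    "blosum_score",
]

_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def _blosum62() -> dict[tuple[str, str], int]:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    out = {}
    for a in AA_ORDER:
        for b in AA_ORDER:
            out[(a, b)] = int(m[a, b])
    return out


@dataclass
class PropertyTables:
    volume: dict[str, float]
    hydrophobicity: dict[str, float]
    formal_charge: dict[str, float]
    helix_propensity: dict[str, float]
    disorder_propensity: dict[str, float]
    max_sasa: dict[str, float]
    blosum62: dict[tuple[str, str], int] = field(default_factory=_blosum62)
    version: int = 1

    def __post_init__(self) -> None:
        for name in ("volume", "helix_propensity", "disorder_propensity",
                     "hydrophobicity", "max_sasa"):
            table = getattr(self, name)
            missing = set(AA_ORDER) - set(table)
            if missing:
                raise ValueError(f"{name} table missing residues {sorted(missing)}")
        if any(v <= 0 for v in self.volume.values()):
            raise ValueError("residue volumes must be positive")
        if any(v <= 0 for v in self.max_sasa.values()):
            raise ValueError("max-SASA values must be positive")

    def to_one_letter(self, residue: str) -> str:
        residue = residue.strip().upper()
        if len(residue) == 1:
            if residue not in AA_ORDER:
                raise KeyError(f"unknown residue code {residue!r}")
            return residue
        try:
            return _AA3[residue]
        except KeyError:
            raise KeyError(f"unknown residue name {residue!r}") from None

    def charge(self, residue: str) -> float:
        return self.formal_charge.get(self.to_one_letter(residue), 0.0)

    def _get(self, table: dict[str, float], residue: str) -> float:
        aa = self.to_one_letter(residue)
        if aa not in table:
            raise KeyError(f"no table entry for residue {residue!r}")
        return table[aa]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PropertyTables":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            volume=data["volume"],
            hydrophobicity=data["hydrophobicity"],
            formal_charge={k: float(v) for k, v in data["formal_charge"].items()},
            helix_propensity=data["helix_propensity"],
            disorder_propensity=data["disorder_propensity"],
            max_sasa=data["max_sasa"],
            version=int(data.get("version", 1)),
        )


_DEFAULT: PropertyTables | None = None


def load_default_tables() -> PropertyTables:
    """The packaged version-1 tables (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        with resources.as_file(
                resources.files("rps19struct.data") / "tables.yaml") as p:
            _DEFAULT = PropertyTables.from_yaml(p)
    return _DEFAULT


def volume_change_pct(wt: str, mut: str, tables: PropertyTables | None = None) -> float:
    """Signed percent volume change, 100 * (V_mut - V_wt) / V_wt."""
    t = tables or load_default_tables()
    v_wt = t._get(t.volume, wt)
    v_mut = t._get(t.volume, mut)
    return 100.0 * (v_mut - v_wt) / v_wt


def hydrophobicity_change_pct(wt: str, mut: str,
                              tables: PropertyTables | None = None) -> float:
    """Signed percent hydrophobicity change on the configured scale.

    The Kyte-Doolittle scale spans negative values, so the percent change is
    taken relative to |h_wt|; the sign always reports whether hydrophobicity
    increased or decreased.
    """
    t = tables or load_default_tables()
    h_wt = t._get(t.hydrophobicity, wt)
    h_mut = t._get(t.hydrophobicity, mut)
    denom = abs(h_wt)
    if denom == 0:
        raise ValueError(f"wild-type {wt!r} has zero hydrophobicity on this "
                         "scale; percent change undefined")
    return 100.0 * (h_mut - h_wt) / denom


def charge_change(wt: str, mut: str, tables: PropertyTables | None = None) -> float:
    """formal_charge(mut) - formal_charge(wt)."""
    t = tables or load_default_tables()
    t.to_one_letter(wt), t.to_one_letter(mut)  # validate names
    return t.charge(mut) - t.charge(wt)


def helix_propensity_change(wt: str, mut: str,
                            tables: PropertyTables | None = None) -> float:
    t = tables or load_default_tables()
    return t._get(t.helix_propensity, mut) - t._get(t.helix_propensity, wt)


def disorder_propensity_change(wt: str, mut: str,
                               tables: PropertyTables | None = None) -> float:
    t = tables or load_default_tables()
    return t._get(t.disorder_propensity, mut) - t._get(t.disorder_propensity, wt)


def blosum_score(wt: str, mut: str, tables: PropertyTables | None = None) -> int:
    t = tables or load_default_tables()
    return t.blosum62[(t.to_one_letter(wt), t.to_one_letter(mut))]
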