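"""Per-mutation feature assembly.

Combines interface geometry (BSA, rBSA, hydrogen-bond counts), residue
property deltas, externally supplied folding stability changes (DDG,
kcal/mol, e.g. FoldX PositionScan output) and per-site conservation scores
into the named feature vector used by the rule engine, the group statistics
and the SVM predictor.

The eight core features are BSA, rBSA, HB_Num, Dcharge, DDG, Dhelix,
BLOSUM62 and Ddisorder; a registry of 18 candidate features (the core eight
plus ten structural/conservation extras) feeds the exhaustive feature
selection.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import properties as props
from .curation import MutationRecord, parse_protein_mutation
from .interface import InterfaceRecord, assign_patch
from .properties import PropertyTables, load_default_tables

__all__ = [
    "FeatureVector",
    "DdgTable",
    "CORE_FEATURES",
    "FEATURE_REGISTRY",
    "load_ddg_table",
    "extract_features",
    "features_to_row",
    "surrogate_ddg",
]

CORE_FEATURES = ("bsa", "rbsa", "hb_num", "d_charge", "ddg", "d_helix",
                 "blosum62", "d_disorder")
EXTENDED_FEATURES = ("rsasa", "d_volume_pct", "d_hydrophobicity_pct",
                     "conservation", "in_patch", "is_proline_sub",
                     "d_volume", "wt_hydrophobicity", "mut_charge",
                     "wt_is_hydrophobic")
# The 18-candidate pool for exhaustive feature selection.
FEATURE_REGISTRY = CORE_FEATURES + EXTENDED_FEATURES


@dataclass
class FeatureVector:
    bsa: float
    rbsa: float
    hb_num: int
    d_charge: float
    ddg: float | None
    d_helix: float
    blosum62: int
    d_disorder: float
    extended: dict[str, float] = field(default_factory=dict)

    def get(self, name: str) -> float:
        if name in CORE_FEATURES:
            value = getattr(self, name)
            if value is None:
                raise KeyError(f"feature {name!r} unavailable for this mutation")
            return float(value)
        if name in self.extended:
            return float(self.extended[name])
        raise KeyError(f"unknown feature {name!r}")


class DdgTable:
    """Map (position, mutant residue) -> folding free-energy change (kcal/mol)."""

    def __init__(self, entries: dict[tuple[int, str], float]):
        self.entries = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, position: int, mut: str) -> float | None:
        return self.entries.get((position, mut))

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self.entries


def load_ddg_table(path: str | Path) -> DdgTable:
    """Read a DDG table in either supported dialect.

    Accepted formats, one entry per line:

    * the package's TSV with header ``position  wt  mut  ddg``;
    * a two-column PositionScan-style file: a mutation token (``G127R`` or
      ``GLY127ARG``) and a DDG value, tab- or space-separated, no header.

    Duplicate (position, mutant) entries: the last one wins with a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    entries: dict[tuple[int, str], float] = {}

    def put(pos: int, mut: str, value: float, lineno: int) -> None:
        if (pos, mut) in entries:
            warnings.warn(f"{path.name}:{lineno}: duplicate DDG entry for "
                          f"position {pos} mutant {mut}; last wins")
        entries[(pos, mut)] = value

    header = lines[0].lower().split("\t") if lines else []
    if "position" in header and "ddg" in header:
        cols = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            try:
                pos = int(parts[cols["position"]])
                mut = parts[cols["mut"]].strip().upper()
                value = float(parts[cols["ddg"]])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path.name}:{lineno}: malformed row: {exc}") from exc
            put(pos, mut, value, lineno)
    else:
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path.name}:{lineno}: expected "
                                 f"'<mutation> <ddg>', got {line!r}")
            try:
                pos, _wt, mut = parse_protein_mutation(parts[0])
                value = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: malformed row: {exc}") from exc
            put(pos, mut, value, lineno)
    return DdgTable(entries)


def extract_features(mutation: MutationRecord,
                     interface: list[InterfaceRecord],
                     hbond_counts: dict[int, int],
                     rsasa_by_position: dict[int, float],
                     tables: PropertyTables | None = None,
                     ddg: DdgTable | None = None,
                     conservation: dict[int, float] | None = None,
                     ) -> FeatureVector:
    """Assemble the feature vector for one mutation.

    ``interface`` and ``hbond_counts`` describe the wild-type residue's place
    in the complex; a mutation at a non-interface residue gets
    bsa = rbsa = hb_num = 0.  Missing DDG or conservation entries are kept as
    None / absent, never silently zeroed.
    """
    tables = tables or load_default_tables()
    by_number = {r.residue_number: r for r in interface}
    rec = by_number.get(mutation.position)
    if rec is None and mutation.position not in rsasa_by_position:
        raise KeyError(f"mutation position {mutation.position} not resolvable "
                       "in the structure")
    bsa = rec.bsa if rec is not None and rec.is_interface else 0.0
    rbsa = rec.rbsa if rec is not None and rec.is_interface else 0.0
    hb_num = hbond_counts.get(mutation.position, 0)

    wt, mut = mutation.wt, mutation.mut
    ddg_value = ddg.get(mutation.position, mut) if ddg is not None else None
    extended = {
        "rsasa": rsasa_by_position.get(mutation.position, 0.0),
        "d_volume_pct": props.volume_change_pct(wt, mut, tables),
        "d_hydrophobicity_pct": props.hydrophobicity_change_pct(wt, mut, tables),
        "in_patch": 1.0 if assign_patch(mutation.position) else 0.0,
        "is_proline_sub": 1.0 if mut == "P" else 0.0,
        "d_volume": tables.volume[mut] - tables.volume[wt],
        "wt_hydrophobicity": tables.hydrophobicity[wt],
        "mut_charge": tables.charge(mut),
        "wt_is_hydrophobic": 1.0 if wt in "LWVFIM" else 0.0,
    }
    if conservation is not None and mutation.position in conservation:
        extended["conservation"] = conservation[mutation.position]

    return FeatureVector(
        bsa=bsa,
        rbsa=rbsa,
        hb_num=hb_num,
        d_charge=props.charge_change(wt, mut, tables),
        ddg=ddg_value,
        d_helix=props.helix_propensity_change(wt, mut, tables),
        blosum62=props.blosum_score(wt, mut, tables),
        d_disorder=props.disorder_propensity_change(wt, mut, tables),
        extended=extended,
    )


def features_to_row(fv: FeatureVector, names: tuple[str, ...] = FEATURE_REGISTRY,
                    ) -> dict[str, float]:
    """Flatten a FeatureVector into a name -> value mapping for a table row."""
    row = {}
    for name in names:
        try:
            row[name] = fv.get(name)
        except KeyError:
            row[name] = float("nan")
    return row


def surrogate_ddg(wt: str, mut: str, rsasa: float,
                  tables: PropertyTables | None = None) -> float:
    """Synthetic stability-change estimator for tests and demos only.

    NOT a physical energy function and NOT comparable to FoldX values: a
    smooth score combining burial-weighted hydrophobicity loss, a volume-clash
    term, and a proline penalty, used by the synthetic generators so the whole
    pipeline can run download-free.
    """
    tables = tables or load_default_tables()
    burial = max(0.0, 1.0 - rsasa)
    dh = tables.hydrophobicity[mut] - tables.hydrophobicity[wt]
    dv = props.volume_change_pct(wt, mut, tables)
    ddg = 0.35 * burial * max(0.0, -dh)
    ddg += 2.0 * burial * max(0.0, dv - 30.0) / 100.0
    if mut == "P":
        ddg += 1.5
    return ddg
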