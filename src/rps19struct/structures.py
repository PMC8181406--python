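"""Macromolecular coordinate model: chains, residues, atoms.

A thin, uniform in-memory model for protein--RNA complexes, read from PDB or
mmCIF files (via gemmi) or built programmatically by the synthetic generators.
Residue numbering follows the author numbering of the source file; hydrogens
are kept when present but never required; for alternate conformations only the
highest-occupancy conformer is retained.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "Ensemble",
    "StructureError",
    "read_structure",
    "write_pdb",
    "extract_chain",
    "sequence_of",
]


class StructureError(ValueError):
    """Raised for unparseable files, missing chains, or empty structures."""


AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
RNA_NAMES = {"A", "C", "G", "U", "I"}
BACKBONE_ATOMS = ("N", "CA", "C", "O")


def residue_kind(name: str) -> str:
    name = name.strip().upper()
    if name in AA3_TO_1:
        return "protein"
    if name in RNA_NAMES:
        return "rna"
    return "other"


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) in Angstroms

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name}: empty element")


@dataclass
class Residue:
    chain_id: str
    number: int
    name: str
    atoms: list[Atom]
    insertion_code: str = ""
    kind: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"residue {self.name}{self.number}: no atoms")
        if not self.kind:
            self.kind = residue_kind(self.name)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name.upper(), "X")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]


@dataclass
class StructureModel:
    chains: list[Chain]
    model_id: int = 1

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for res in self.residues():
            if res.key in seen:
                raise StructureError(f"duplicate residue {res.key}")
            seen.add(res.key)

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise StructureError(f"chain {chain_id!r} not found (have {self.chain_ids()})")

    def residues(self, chain_id: str | None = None) -> Iterator[Residue]:
        for c in self.chains:
            if chain_id is None or c.chain_id == chain_id:
                yield from c.residues

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues():
            for atom in res.atoms:
                yield res, atom

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for _, a in self.atoms()], dtype=float)


@dataclass
class Ensemble:
    models: list[StructureModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.models:
            topo = _topology(self.models[0])
            for m in self.models[1:]:
                if _topology(m) != topo:
                    raise StructureError("ensemble models have mismatched topology")

    def __len__(self) -> int:
        return len(self.models)


def _topology(model: StructureModel) -> list[tuple]:
    return [
        (res.chain_id, res.number, res.insertion_code, res.name,
         tuple(a.name for a in res.atoms))
        for res in model.residues()
    ]


# ---------------------------------------------------------------------------
# I/O


def read_structure(path: str | Path, format: str | None = None):
    """Read a PDB or mmCIF file into a :class:`StructureModel` or :class:`Ensemble`.

    Format is inferred from the extension unless given explicitly
    (``"pdb"`` or ``"mmcif"``). Multi-model files yield an :class:`Ensemble`.
    Only the highest-occupancy alternate conformer is kept. Waters are dropped.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, IndexError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    st.remove_alternative_conformations()
    st.remove_waters()

    models = []
    for gm in st:
        chains = []
        for gc in gm:
            residues = []
            for gr in gc:
                atoms = [
                    Atom(a.name, a.element.name.upper() or a.name[0], np.array(
                        [a.pos.x, a.pos.y, a.pos.z]))
                    for a in gr
                ]
                if not atoms:
                    continue
                residues.append(Residue(
                    chain_id=gc.name,
                    number=gr.seqid.num,
                    insertion_code=(gr.seqid.icode or "").strip(),
                    name=gr.name,
                    atoms=atoms,
                ))
            if residues:
                chains.append(Chain(gc.name, residues))
        if chains:
            models.append(StructureModel(chains=chains, model_id=len(models) + 1))

    if not models:
        raise StructureError(f"{path}: no polymer atoms found")
    if len(models) == 1:
        return models[0]
    return Ensemble(models=models)


def write_pdb(obj: StructureModel | Ensemble, path: str | Path) -> None:
    """Write a model or ensemble in fixed-width PDB v3.3 format."""
    models = obj.models if isinstance(obj, Ensemble) else [obj]
    lines: list[str] = []
    multi = len(models) > 1
    for model in models:
        if multi:
            lines.append(f"MODEL     {model.model_id:4d}")
        serial = 1
        for chain in model.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    name = atom.name
                    # columns 13-16: element right-justified in 13-14 for 1-2 char names
                    if len(name) < 4 and len(atom.element) == 1:
                        name_f = f" {name:<3s}"
                    else:
                        name_f = f"{name:<4s}"
                    x, y, z = atom.position
                    lines.append(
                        f"ATOM  {serial:5d} {name_f} {res.name:>3s} "
                        f"{chain.chain_id[:1]}{res.number:4d}{res.insertion_code or ' ':1s}"
                        f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2s}"
                    )
                    serial += 1
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Chain operations


def extract_chain(model: StructureModel, chain_id: str) -> StructureModel:
    """Return a single-chain model with coordinates unchanged."""
    chain = model.chain(chain_id)
    return StructureModel(chains=[chain], model_id=model.model_id)


def extract_chains(model: StructureModel, chain_ids: list[str]) -> StructureModel:
    chains = [model.chain(cid) for cid in chain_ids]
    return StructureModel(chains=chains, model_id=model.model_id)


def sequence_of(model: StructureModel, chain_id: str) -> str:
    """One-letter sequence of a protein chain; nonstandard residues become X."""
    chain = model.chain(chain_id)
    kinds = {r.kind for r in chain.residues}
    if "protein" not in kinds:
        raise StructureError(f"chain {chain_id!r} is not a protein chain")
    if kinds - {"protein", "other"}:
        raise StructureError(f"chain {chain_id!r} mixes protein and nucleic residues")
    return "".join(r.one_letter() for r in chain.residues)
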