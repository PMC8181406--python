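"""Protein--RNA interface analysis.

Interface residues are defined by the buried-surface-area (Delta-SASA)
criterion: a residue is interfacial when its SASA computed for the subject
chain alone exceeds its SASA in the subject+partner complex by more than a
small threshold.  Inter-molecular hydrogen bonds are detected geometrically
from heavy-atom donor/acceptor typing (cryo-EM models usually lack hydrogens;
when explicit hydrogens are present a D-H...A angle test is applied as well).
Interface residues of RPS19 map onto five conserved, positively charged
surface patches (I-V), each contacting a specific 18S rRNA secondary-structure
element; the patch definitions ship as a versioned YAML constant.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .structures import Residue, StructureModel, extract_chains
from .surface import SasaResult, shrake_rupley

__all__ = [
    "InterfaceRecord",
    "HBond",
    "PatchDefinition",
    "load_patch_definitions",
    "interface_residues",
    "interface_fraction",
    "hydrogen_bonds",
    "hbonds_per_residue",
    "assign_patch",
]


# ---------------------------------------------------------------------------
# Donor / acceptor typing (heavy atoms only; no energy function)

PROTEIN_SC_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}
PROTEIN_SC_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
}
# RNA: phosphate and ribose oxygens plus base donors/acceptors.
RNA_COMMON_ACCEPTORS = {"OP1", "OP2", "O1P", "O2P", "O5'", "O3'", "O4'", "O2'"}
RNA_COMMON_DONORS = {"O2'"}
RNA_BASE_DONORS = {
    "A": {"N6"}, "G": {"N1", "N2"}, "C": {"N4"}, "U": {"N3"},
}
RNA_BASE_ACCEPTORS = {
    "A": {"N1", "N3", "N7"}, "G": {"O6", "N3", "N7"},
    "C": {"O2", "N3"}, "U": {"O2", "O4"},
}


def _donor_acceptor_atoms(res: Residue) -> tuple[list, list]:
    """(donors, acceptors) heavy atoms of one residue, by typing tables."""
    name = res.name.upper()
    donors: list = []
    acceptors: list = []
    if res.kind == "protein":
        d_names = PROTEIN_SC_DONORS.get(name, set()) | {"N"}
        a_names = PROTEIN_SC_ACCEPTORS.get(name, set()) | {"O", "OXT"}
        if name == "PRO":
            d_names -= {"N"}
    elif res.kind == "rna":
        d_names = RNA_COMMON_DONORS | RNA_BASE_DONORS.get(name, set())
        a_names = RNA_COMMON_ACCEPTORS | RNA_BASE_ACCEPTORS.get(name, set())
    else:
        warnings.warn(f"unknown residue {res.name!r}: skipped in hydrogen-bond "
                      "typing", stacklevel=3)
        return [], []
    for atom in res.atoms:
        if atom.name in d_names:
            donors.append(atom)
        if atom.name in a_names:
            acceptors.append(atom)
    return donors, acceptors


def _attached_hydrogens(res: Residue, donor, d_hx: float = 1.3) -> list:
    return [a for a in res.atoms
            if a.element.upper() == "H"
            and float(np.linalg.norm(a.position - donor.position)) <= d_hx]


# ---------------------------------------------------------------------------
# Records


@dataclass
class InterfaceRecord:
    chain_id: str
    residue_number: int
    residue_name: str
    sasa_isolated: float      # A^2, subject chain alone
    sasa_complexed: float     # A^2, in subject+partners complex
    bsa: float                # buried surface area, isolated - complexed
    rbsa: float               # bsa / sasa_isolated (0 when isolated SASA is 0)
    is_interface: bool
    partner_chain_ids: tuple[str, ...]

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass
class HBond:
    donor_chain: str
    donor_residue: int
    donor_residue_name: str
    donor_atom: str
    acceptor_chain: str
    acceptor_residue: int
    acceptor_residue_name: str
    acceptor_atom: str
    distance: float
    angle: float | None = None  # D-H...A, degrees; None when no hydrogens


@dataclass
class PatchDefinition:
    patch_id: str
    protein_residue_numbers: frozenset[int]
    rna_element_name: str
    rna_nucleotide_ranges: tuple[tuple[int, int], ...]


_PATCHES: dict[str, PatchDefinition] | None = None


def load_patch_definitions(path: str | Path | None = None) -> dict[str, PatchDefinition]:
    """The five RPS19 surface-patch definitions (patch id -> definition)."""
    global _PATCHES
    if path is None and _PATCHES is not None:
        return _PATCHES
    if path is None:
        ref = resources.files("rps19struct.data") / "patches.yaml"
        with resources.as_file(ref) as p:
            data = yaml.safe_load(Path(p).read_text())
    else:
        data = yaml.safe_load(Path(path).read_text())
    patches = {}
    for pid, spec in data["patches"].items():
        patches[pid] = PatchDefinition(
            patch_id=pid,
            protein_residue_numbers=frozenset(spec["protein_residues"]),
            rna_element_name=spec["rna_element"],
            rna_nucleotide_ranges=tuple((int(a), int(b))
                                        for a, b in spec["rna_nucleotide_ranges"]),
        )
    if path is None:
        _PATCHES = patches
    return patches


# ---------------------------------------------------------------------------
# Operations


def interface_residues(complex_model: StructureModel, subject_chain: str,
                       partner_chains: list[str], bsa_threshold: float = 0.1,
                       probe: float = 1.4, n_points: int = 960,
                       ) -> list[InterfaceRecord]:
    """Per-residue buried surface area of the subject chain against partners."""
    if subject_chain in partner_chains:
        raise ValueError("subject chain cannot be one of the partner chains")
    alone = extract_chains(complex_model, [subject_chain])
    together = extract_chains(complex_model, [subject_chain] + list(partner_chains))
    sasa_alone = shrake_rupley(alone, probe=probe, n_points=n_points)
    sasa_cplx = shrake_rupley(together, probe=probe, n_points=n_points)

    records = []
    for res in complex_model.residues(subject_chain):
        s_alone = sasa_alone.per_residue[res.key]
        s_cplx = sasa_cplx.per_residue[res.key]
        bsa = max(0.0, s_alone - s_cplx)
        rbsa = bsa / s_alone if s_alone > 0 else 0.0
        records.append(InterfaceRecord(
            chain_id=res.chain_id,
            residue_number=res.number,
            residue_name=res.name,
            sasa_isolated=s_alone,
            sasa_complexed=s_cplx,
            bsa=bsa,
            rbsa=rbsa,
            is_interface=bsa > bsa_threshold,
            partner_chain_ids=tuple(partner_chains),
        ))
    return records


def interface_fraction(records: list[InterfaceRecord], chain_length: int) -> float:
    """Percent of the chain that is interfacial: 100 * n_interface / length."""
    if chain_length <= 0:
        raise ValueError("chain_length must be positive")
    n = sum(1 for r in records if r.is_interface)
    return 100.0 * n / chain_length


def hydrogen_bonds(complex_model: StructureModel, group_a_chains: list[str],
                   group_b_chains: list[str], d_max: float = 3.5,
                   angle_min: float = 120.0) -> list[HBond]:
    """All inter-molecular donor-acceptor pairs between two chain groups.

    A bond requires heavy-atom donor-acceptor distance <= ``d_max``; when the
    donor carries explicit hydrogens, at least one D-H...A angle must reach
    ``angle_min`` degrees.
    """
    if set(group_a_chains) & set(group_b_chains):
        raise ValueError("chain groups overlap")

    def collect(chains):
        donors, acceptors = [], []
        for cid in chains:
            for res in complex_model.residues(cid):
                d, a = _donor_acceptor_atoms(res)
                donors += [(res, atom) for atom in d]
                acceptors += [(res, atom) for atom in a]
        return donors, acceptors

    don_a, acc_a = collect(group_a_chains)
    don_b, acc_b = collect(group_b_chains)

    bonds = []
    seen: set[frozenset] = set()  # one bond per unordered atom pair
    for donors, acceptors in ((don_a, acc_b), (don_b, acc_a)):
        if not donors or not acceptors:
            continue
        acc_pos = np.array([a.position for _, a in acceptors])
        tree = cKDTree(acc_pos)
        for res_d, atom_d in donors:
            for j in tree.query_ball_point(atom_d.position, d_max):
                res_a, atom_a = acceptors[j]
                dist = float(np.linalg.norm(atom_a.position - atom_d.position))
                angle = None
                hydrogens = _attached_hydrogens(res_d, atom_d)
                if hydrogens:
                    angle = max(_angle(h.position, atom_d.position, atom_a.position)
                                for h in hydrogens)
                    if angle < angle_min:
                        continue
                pair = frozenset([(res_d.chain_id, res_d.number, atom_d.name),
                                  (res_a.chain_id, res_a.number, atom_a.name)])
                if pair in seen:
                    continue
                seen.add(pair)
                bonds.append(HBond(
                    donor_chain=res_d.chain_id, donor_residue=res_d.number,
                    donor_residue_name=res_d.name, donor_atom=atom_d.name,
                    acceptor_chain=res_a.chain_id, acceptor_residue=res_a.number,
                    acceptor_residue_name=res_a.name, acceptor_atom=atom_a.name,
                    distance=dist, angle=angle,
                ))
    bonds.sort(key=lambda b: (b.donor_chain, b.donor_residue, b.donor_atom,
                              b.acceptor_chain, b.acceptor_residue, b.acceptor_atom))
    return bonds


def _angle(h: np.ndarray, d: np.ndarray, a: np.ndarray) -> float:
    """D-H...A angle in degrees (vertex at H)."""
    v1 = d - h
    v2 = a - h
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbonds_per_residue(bonds: list[HBond], subject_chain: str) -> dict[int, int]:
    """Residue number -> number of inter-molecular bonds it participates in."""
    counts: dict[int, int] = {}
    for b in bonds:
        if b.donor_chain == subject_chain:
            counts[b.donor_residue] = counts.get(b.donor_residue, 0) + 1
        if b.acceptor_chain == subject_chain:
            counts[b.acceptor_residue] = counts.get(b.acceptor_residue, 0) + 1
    return counts


def assign_patch(residue_number: int,
                 patches: dict[str, PatchDefinition] | None = None) -> str | None:
    """Patch id (I-V) containing the residue number, or None."""
    patches = patches or load_patch_definitions()
    for pid, patch in patches.items():
        if residue_number in patch.protein_residue_numbers:
            return pid
    return None
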