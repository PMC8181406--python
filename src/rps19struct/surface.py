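"""Solvent-accessible surface area (Shrake-Rupley) and relative SASA.

The sphere points come from a deterministic golden-spiral generator, so SASA
values are bit-reproducible for a fixed point count without any seed.  Relative
SASA divides a residue's SASA by the maximum SASA of that residue type in an
extended Gly-X-Gly tripeptide (Tien et al. theoretical values, shipped as a
constant table).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .properties import PropertyTables, load_default_tables
from .structures import StructureModel

__all__ = [
    "VDW_RADII",
    "SasaResult",
    "sphere_points",
    "shrake_rupley",
    "relative_sasa",
]

# van der Waals radii (A), Bondi-style set; configurable via `radii=` argument.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "ZN": 1.39, "FE": 1.40, "NA": 2.27, "K": 2.75, "CA": 2.31,
}
DEFAULT_RADIUS = 1.70


@dataclass
class SasaResult:
    per_atom: np.ndarray              # A^2, aligned with model.atoms() order
    per_residue: dict[tuple, float]   # residue key -> A^2
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def sphere_points(n: int) -> np.ndarray:
    """n points quasi-uniform on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _atom_radii(model: StructureModel, radii: dict[str, float],
                strict: bool) -> np.ndarray:
    out = []
    for res, atom in model.atoms():
        el = atom.element.upper()
        r = radii.get(el)
        if r is None:
            if strict:
                raise KeyError(f"no van der Waals radius for element {el!r} "
                               f"(atom {atom.name} in {res.name}{res.number})")
            warnings.warn(f"unknown element {el!r}: using default radius "
                          f"{DEFAULT_RADIUS} A", stacklevel=3)
            r = DEFAULT_RADIUS
        out.append(r)
    return np.array(out, dtype=float)


def shrake_rupley(model: StructureModel, probe: float = 1.4,
                  n_points: int = 960, radii: dict[str, float] | None = None,
                  strict_elements: bool = True) -> SasaResult:
    """Per-atom and per-residue SASA by the Shrake-Rupley rolling-probe method.

    Each atom is covered with ``n_points`` golden-spiral points on its expanded
    sphere (vdW radius + probe); a point is exposed when outside every
    neighbouring expanded sphere; per-atom SASA is
    ``(exposed / n_points) * 4 pi (r + probe)^2``.
    """
    radii = radii if radii is not None else VDW_RADII
    centers = model.coordinates()
    if centers.size == 0:
        raise ValueError("empty structure")
    rads = _atom_radii(model, radii, strict_elements) + probe
    unit = sphere_points(n_points)

    tree = cKDTree(centers)
    max_r = rads.max()
    per_atom = np.empty(len(centers))
    for i, (c, r) in enumerate(zip(centers, rads)):
        pts = c + r * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(c, r + max_r):
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - centers[j], pts - centers[j])
            exposed &= d2 > rads[j] ** 2
        per_atom[i] = exposed.sum() / n_points * 4.0 * np.pi * r * r

    per_residue: dict[tuple, float] = {}
    idx = 0
    for res in model.residues():
        n = len(res.atoms)
        per_residue[res.key] = float(per_atom[idx:idx + n].sum())
        idx += n
    return SasaResult(per_atom=per_atom, per_residue=per_residue,
                      probe_radius=probe, n_sphere_points=n_points)


def relative_sasa(residue_sasa: float, residue_name: str,
                  tables: PropertyTables | None = None,
                  clamp: bool = False) -> float:
    """SASA divided by the residue type's Gly-X-Gly maximum SASA.

    ``residue_name`` may be one- or three-letter.  Values slightly above 1 can
    occur for exposed termini and are kept unless ``clamp`` is set.
    """
    tables = tables or load_default_tables()
    aa = tables.to_one_letter(residue_name)
    if aa not in tables.max_sasa:
        raise KeyError(f"no max-SASA entry for residue {residue_name!r}")
    value = residue_sasa / tables.max_sasa[aa]
    if value < 0:
        raise ValueError("negative SASA")
    return min(value, 1.0) if clamp else value
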