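"""Ensemble flexibility analysis: RMSF, disorder calling, clustering.

Backbone RMSF is computed after least-squares (Kabsch) superposition of every
model onto the ensemble-average conformation; residues in the middle of the
chain whose RMSF exceeds a threshold (default 2 A) are called intrinsically
disordered.  Conformations are grouped by density-based clustering (DBSCAN) on
the pairwise backbone-RMSD matrix, with the medoid of each cluster as its
representative.  Eight-state secondary-structure strings simplify to
helix/sheet/coil.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import BACKBONE_ATOMS, Ensemble, StructureModel

__all__ = [
    "FlexibilityProfile",
    "IdrCall",
    "ClusterResult",
    "backbone_rmsf",
    "call_idrs",
    "cluster_conformations",
    "pairwise_backbone_rmsd",
    "simplify_ss",
]


@dataclass
class FlexibilityProfile:
    residue_numbers: list[int]
    rmsf: np.ndarray                  # A, per residue
    reference: np.ndarray             # average backbone conformation, (n_atoms, 3)

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if len(self.residue_numbers) != len(self.rmsf):
            raise ValueError("rmsf length does not match residue count")


@dataclass
class IdrCall:
    intervals: list[tuple[int, int]]  # closed residue-number intervals
    threshold: float


@dataclass
class ClusterResult:
    labels: np.ndarray                # per model; -1 = noise
    representatives: dict[int, int]   # cluster label -> medoid model index
    occupancies: dict[int, float]     # cluster label -> fraction of models


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal least-squares superposition of mobile onto target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    p = mobile - mc
    q = target - tc
    v, s, wt = np.linalg.svd(p.T @ q)
    d = np.sign(np.linalg.det(v @ wt))
    rot = v @ np.diag([1.0, 1.0, d]) @ wt
    return p @ rot + tc


def _backbone_coords(model: StructureModel) -> tuple[np.ndarray, list[int], list[int]]:
    """(coords, residue number per backbone atom index, residue numbers)."""
    coords, owner, numbers = [], [], []
    for i, res in enumerate(model.residues()):
        numbers.append(res.number)
        for name in BACKBONE_ATOMS:
            atom = res.atom(name)
            if atom is not None:
                coords.append(atom.position)
                owner.append(i)
    if not coords:
        raise ValueError("no backbone atoms (N, CA, C, O) found")
    return np.array(coords), owner, numbers


def backbone_rmsf(ensemble: Ensemble, n_iter: int = 3) -> FlexibilityProfile:
    """Per-residue backbone RMSF about the ensemble-average conformation.

    The average reference is self-consistent: models are superposed onto the
    running average and the average recomputed for ``n_iter`` rounds.
    """
    if len(ensemble) < 2:
        raise ValueError("RMSF needs at least 2 models")
    stacks = []
    owner = numbers = None
    for model in ensemble.models:
        c, o, nums = _backbone_coords(model)
        if owner is None:
            owner, numbers = o, nums
        stacks.append(c)
    coords = np.array(stacks)                       # (n_models, n_atoms, 3)

    reference = coords[0]
    for _ in range(n_iter):
        aligned = np.array([_kabsch(c, reference) for c in coords])
        reference = aligned.mean(axis=0)
    aligned = np.array([_kabsch(c, reference) for c in coords])

    sq = ((aligned - reference) ** 2).sum(axis=2)   # (n_models, n_atoms)
    owner = np.asarray(owner)
    n_res = len(numbers)
    rmsf = np.empty(n_res)
    for i in range(n_res):
        rmsf[i] = np.sqrt(sq[:, owner == i].mean())
    return FlexibilityProfile(residue_numbers=numbers, rmsf=rmsf,
                              reference=reference)


def call_idrs(profile: FlexibilityProfile, threshold: float = 2.0) -> IdrCall:
    """Maximal runs of mid-chain residues with RMSF above the threshold.

    The first and last residues of the chain are never part of an interval:
    terminal fraying is not evidence of intrinsic disorder.
    """
    nums = profile.residue_numbers
    flags = profile.rmsf > threshold
    if len(nums) > 0:
        flags = flags.copy()
        flags[0] = flags[-1] = False
    intervals: list[tuple[int, int]] = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            intervals.append((nums[start], nums[i - 1]))
            start = None
    if start is not None:
        intervals.append((nums[start], nums[len(nums) - 1]))
    return IdrCall(intervals=intervals, threshold=threshold)


def pairwise_backbone_rmsd(ensemble: Ensemble) -> np.ndarray:
    """Symmetric matrix of pairwise backbone RMSD after per-pair superposition."""
    coords = [_backbone_coords(m)[0] for m in ensemble.models]
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aligned = _kabsch(coords[i], coords[j])
            rmsd = float(np.sqrt(((aligned - coords[j]) ** 2).sum(axis=1).mean()))
            mat[i, j] = mat[j, i] = rmsd
    return mat


def cluster_conformations(ensemble: Ensemble, rmsd_cutoff: float = 2.0,
                          min_points: int = 4) -> ClusterResult:
    """DBSCAN on the pairwise backbone-RMSD matrix; medoid representatives."""
    from sklearn.cluster import DBSCAN

    if len(ensemble) < 2:
        raise ValueError("clustering needs at least 2 models")
    mat = pairwise_backbone_rmsd(ensemble)
    labels = DBSCAN(eps=rmsd_cutoff, min_samples=min_points,
                    metric="precomputed").fit_predict(mat)
    n = len(labels)
    representatives: dict[int, int] = {}
    occupancies: dict[int, float] = {}
    for label in sorted(set(labels)):
        if label == -1:
            continue
        members = np.flatnonzero(labels == label)
        sub = mat[np.ix_(members, members)]
        representatives[int(label)] = int(members[np.argmin(sub.sum(axis=1))])
        occupancies[int(label)] = len(members) / n
    return ClusterResult(labels=labels, representatives=representatives,
                         occupancies=occupancies)


_SS_MAP = {"G": "H", "H": "H", "I": "H", "B": "E", "E": "E",
           "T": "C", "S": "C", "C": "C", " ": "C", "-": "C"}


def simplify_ss(ss8: str) -> str:
    """Collapse 8-state secondary structure to 3 states.

    Helix (G, H, I) -> H; sheet (B, E) -> E; coil (T, S, C, blank) -> C.
    """
    try:
        return "".join(_SS_MAP[c] for c in ss8)
    except KeyError as exc:
        raise ValueError(f"unknown secondary-structure state {exc.args[0]!r}") from None
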