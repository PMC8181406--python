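"""Rule engine for the structural basis of a missense mutation.

Each mutation gets a multi-label classification along two axes:

* destabilization (DDG above a cutoff, default 1 kcal/mol) via the approaches
  hydrophobic-core loss, steric clash in the core, or helix breaking by an
  introduced proline;
* interaction disruption at the protein-rRNA interface via the avenues
  hydrogen-bond loss, surface electrostatic alteration, or steric clash at
  the interface.

Flags are independent: one mutation may act through several approaches.  A
proline introduced into a helix is always flagged as helix-breaking even when
the supplied DDG is small, because empirical stability estimators are known
to be unreliable for proline substitutions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .curation import MutationRecord
from .features import FeatureVector
from .interface import assign_patch

__all__ = [
    "RuleConfig",
    "MutationContext",
    "StructuralBasis",
    "SIDECHAIN_REACH_BONDS",
    "classify_mutation",
    "summarize_basis",
]

APPROACHES = ("hydrophobic_core_loss", "steric_core_clash", "helix_break_proline")
AVENUES = ("hbond_loss", "electrostatic_alteration", "steric_interface_clash")

# Side-chain reach: bond-path length from CA to the side chain's terminal
# functional atom.  A reach change of >= 2 bonds moves a bonding group by
# several Angstroms, so an otherwise donor/acceptor-capable substitution can
# still leave the partner atom out of range (e.g. Lys NZ at 5 bonds vs Asn
# ND2 at 3).
SIDECHAIN_REACH_BONDS = {
    "G": 0, "A": 1, "S": 2, "C": 2, "T": 2, "V": 2, "P": 2,
    "D": 3, "N": 3, "I": 3, "L": 3, "H": 4, "M": 4, "E": 4, "Q": 4,
    "F": 4, "W": 4, "K": 5, "R": 6, "Y": 6,
}
SC_DONOR_CAPABLE = set("RKHWNQSTYC")
SC_ACCEPTOR_CAPABLE = set("DENQHSTYM")


@dataclass
class RuleConfig:
    ddg_cutoff: float = 1.0          # kcal/mol; destabilization threshold
    buried_threshold: float = 0.2    # rSASA below which a residue is "buried"
    steric_threshold: float = 30.0   # % volume increase counting as a clash
    reach_change: int = 2            # side-chain reach change (bonds) that
                                     # breaks a hydrogen bond's geometry


@dataclass
class MutationContext:
    rsasa: float
    in_helix: bool
    is_interface: bool
    wt_hbond_roles: frozenset[str] = frozenset()   # subset of {"donor","acceptor","backbone"}


@dataclass
class StructuralBasis:
    mutation: str
    destabilizing: bool | None       # None when DDG unavailable
    approaches: set[str] = field(default_factory=set)
    interaction_disrupting: bool = False
    avenues: set[str] = field(default_factory=set)
    patch: str | None = None
    notes: str = ""


def _loses_hbond(wt: str, mut: str, roles: frozenset[str],
                 config: RuleConfig) -> bool:
    """Whether the mutant side chain can no longer make the wild-type bonds."""
    side_roles = roles - {"backbone"}
    if not side_roles:
        return False  # backbone-mediated bonds survive any substitution
    if "donor" in side_roles and mut not in SC_DONOR_CAPABLE:
        return True
    if "acceptor" in side_roles and mut not in SC_ACCEPTOR_CAPABLE:
        return True
    reach = abs(SIDECHAIN_REACH_BONDS[wt] - SIDECHAIN_REACH_BONDS[mut])
    return reach >= config.reach_change


def classify_mutation(mutation: MutationRecord, features: FeatureVector,
                      context: MutationContext,
                      config: RuleConfig | None = None) -> StructuralBasis:
    """Assign destabilization approaches and interaction-disruption avenues."""
    config = config or RuleConfig()
    wt, mut = mutation.wt, mutation.mut
    patch = assign_patch(mutation.position)
    notes: list[str] = []

    ddg = features.ddg
    destabilizing = None if ddg is None else ddg > config.ddg_cutoff
    if ddg is None:
        notes.append("DDG unavailable; destabilization call skipped")

    approaches: set[str] = set()
    buried = context.rsasa < config.buried_threshold
    d_hydro = features.extended.get("d_hydrophobicity_pct", 0.0)
    d_vol = features.extended.get("d_volume_pct", 0.0)
    if buried and wt in "LWVF" and d_hydro < 0:
        approaches.add("hydrophobic_core_loss")
    if buried and wt in "GA" and d_vol >= config.steric_threshold:
        approaches.add("steric_core_clash")
    if mut == "P" and context.in_helix:
        approaches.add("helix_break_proline")
        if destabilizing is False:
            notes.append("proline in helix kept as helix-breaking despite "
                         f"DDG <= {config.ddg_cutoff} kcal/mol")

    avenues: set[str] = set()
    at_interface = context.is_interface or patch is not None
    if at_interface:
        if features.hb_num >= 1 and _loses_hbond(wt, mut,
                                                 context.wt_hbond_roles, config):
            avenues.add("hbond_loss")
        if patch is not None and features.d_charge <= -1:
            avenues.add("electrostatic_alteration")
        if context.is_interface and d_vol >= config.steric_threshold:
            avenues.add("steric_interface_clash")

    if not approaches and not avenues and not destabilizing:
        notes.append("no structural basis identified by the rule set")

    return StructuralBasis(
        mutation=mutation.name,
        destabilizing=destabilizing,
        approaches=approaches,
        interaction_disrupting=bool(avenues),
        avenues=avenues,
        patch=patch,
        notes="; ".join(notes),
    )


def summarize_basis(bases: list[StructuralBasis]) -> dict:
    """Category counts and multi-mechanism overlap fractions."""
    counts = {name: 0 for name in APPROACHES + AVENUES}
    n_destab = n_disrupt = n_both = 0
    destab_multi = disrupt_multi = 0
    for b in bases:
        for a in b.approaches:
            counts[a] += 1
        for a in b.avenues:
            counts[a] += 1
        destab = bool(b.destabilizing) or bool(b.approaches)
        if destab:
            n_destab += 1
            if len(b.approaches) + len(b.avenues) > 1:
                destab_multi += 1
        if b.interaction_disrupting:
            n_disrupt += 1
            if len(b.approaches) + len(b.avenues) > 1:
                disrupt_multi += 1
        if destab and b.interaction_disrupting:
            n_both += 1
    return {
        "n": len(bases),
        "counts": counts,
        "n_destabilizing": n_destab,
        "n_interaction_disrupting": n_disrupt,
        "n_both": n_both,
        "destabilizing_multi_fraction": (destab_multi / n_destab
                                         if n_destab else 0.0),
        "disrupting_multi_fraction": (disrupt_multi / n_disrupt
                                      if n_disrupt else 0.0),
    }
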