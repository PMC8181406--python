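import pytest

from rps19struct.basis import (MutationContext, RuleConfig, classify_mutation,
                               summarize_basis)
from rps19struct.curation import MutationRecord
from rps19struct.features import FeatureVector


def make_features(bsa=0.0, rbsa=0.0, hb_num=0, d_charge=0.0, ddg=None,
                  d_volume_pct=0.0, d_hydrophobicity_pct=0.0):
    return FeatureVector(
        bsa=bsa, rbsa=rbsa, hb_num=hb_num, d_charge=d_charge, ddg=ddg,
        d_helix=0.0, blosum62=0, d_disorder=0.0,
        extended={"d_volume_pct": d_volume_pct,
                  "d_hydrophobicity_pct": d_hydrophobicity_pct})


def test_buried_glycine_to_arginine_is_double_core_damage():
    """A fully buried Gly->Arg: steric clash plus hydrophilic intrusion."""
    mutation = MutationRecord(position=127, wt="G", mut="R", label="dba")
    features = make_features(ddg=18.72, d_charge=1.0, d_volume_pct=188.52,
                             d_hydrophobicity_pct=-1025.0)
    context = MutationContext(rsasa=0.0, in_helix=True, is_interface=False)
    basis = classify_mutation(mutation, features, context)
    assert basis.destabilizing is True
    assert "steric_core_clash" in basis.approaches
    assert not basis.interaction_disrupting
    assert basis.patch is None  # 127 is not in any surface patch


def test_patch_serine_to_phenylalanine_clashes_and_breaks_bond():
    """Ser59Phe-like: interface steric clash and hydrogen-bond donor loss."""
    mutation = MutationRecord(position=59, wt="S", mut="F", label="dba")
    features = make_features(bsa=25.0, rbsa=0.4, hb_num=1, ddg=0.8,
                             d_volume_pct=113.4)
    context = MutationContext(rsasa=0.5, in_helix=True, is_interface=True,
                              wt_hbond_roles=frozenset({"donor"}))
    basis = classify_mutation(mutation, features, context)
    assert basis.avenues == {"steric_interface_clash", "hbond_loss"}
    assert basis.interaction_disrupting
    assert basis.patch == "II"


def test_buried_hydrophobic_loss():
    """Trp52Arg-like: buried Trp replaced by charged Arg."""
    mutation = MutationRecord(position=52, wt="W", mut="R", label="dba")
    features = make_features(ddg=4.35, d_charge=1.0, d_volume_pct=-23.9,
                             d_hydrophobicity_pct=-400.0)
    context = MutationContext(rsasa=0.067, in_helix=False, is_interface=False)
    basis = classify_mutation(mutation, features, context)
    assert basis.destabilizing is True
    assert "hydrophobic_core_loss" in basis.approaches
    assert "steric_core_clash" not in basis.approaches


def test_benign_surface_mutation_has_empty_basis():
    mutation = MutationRecord(position=50, wt="T", mut="A", label="neutral")
    features = make_features(ddg=0.1)
    context = MutationContext(rsasa=0.7, in_helix=False, is_interface=False)
    basis = classify_mutation(mutation, features, context)
    assert basis.destabilizing is False
    assert basis.approaches == set()
    assert basis.avenues == set()
    assert "no structural basis" in basis.notes


def test_proline_in_helix_overrides_small_ddg():
    mutation = MutationRecord(position=64, wt="L", mut="P", label="dba")
    features = make_features(ddg=0.3, d_volume_pct=-32.4,
                             d_hydrophobicity_pct=-142.0)
    context = MutationContext(rsasa=0.1, in_helix=True, is_interface=False)
    basis = classify_mutation(mutation, features, context)
    assert "helix_break_proline" in basis.approaches
    assert basis.destabilizing is False          # honest DDG call
    assert "helix-breaking" in basis.notes
    # outside a helix the proline rule does not fire
    context2 = MutationContext(rsasa=0.1, in_helix=False, is_interface=False)
    assert "helix_break_proline" not in classify_mutation(
        mutation, features, context2).approaches


def test_electrostatic_alteration_requires_patch_and_charge_loss():
    mutation = MutationRecord(position=62, wt="R", mut="W", label="dba")
    features = make_features(bsa=10.0, rbsa=0.2, d_charge=-1.0)
    context = MutationContext(rsasa=0.4, in_helix=True, is_interface=True)
    basis = classify_mutation(mutation, features, context)
    assert "electrostatic_alteration" in basis.avenues
    # same change off-patch: no electrostatic avenue
    off_patch = MutationRecord(position=50, wt="R", mut="W", label="dba")
    basis2 = classify_mutation(off_patch, features, context)
    assert "electrostatic_alteration" not in basis2.avenues


def test_avenues_require_interface_or_patch():
    mutation = MutationRecord(position=110, wt="S", mut="F", label="dba")
    features = make_features(hb_num=2, d_charge=-1.0, d_volume_pct=113.0)
    context = MutationContext(rsasa=0.5, in_helix=False, is_interface=False,
                              wt_hbond_roles=frozenset({"donor"}))
    basis = classify_mutation(mutation, features, context)
    assert basis.avenues == set()


def test_backbone_only_hbonds_survive_substitution():
    mutation = MutationRecord(position=38, wt="K", mut="N", label="dba")
    features = make_features(bsa=20.0, rbsa=0.3, hb_num=1)
    backbone = MutationContext(rsasa=0.5, in_helix=False, is_interface=True,
                               wt_hbond_roles=frozenset({"backbone"}))
    assert "hbond_loss" not in classify_mutation(
        mutation, features, backbone).avenues
    # side-chain donor with a big reach change (Lys -> Asn): bond lost
    sidechain = MutationContext(rsasa=0.5, in_helix=False, is_interface=True,
                                wt_hbond_roles=frozenset({"donor"}))
    assert "hbond_loss" in classify_mutation(
        mutation, features, sidechain).avenues


def test_missing_ddg_leaves_destabilization_unknown():
    mutation = MutationRecord(position=10, wt="L", mut="R", label="dba")
    features = make_features(ddg=None, d_hydrophobicity_pct=-218.0)
    context = MutationContext(rsasa=0.05, in_helix=True, is_interface=False)
    basis = classify_mutation(mutation, features, context)
    assert basis.destabilizing is None
    assert "DDG unavailable" in basis.notes
    assert "hydrophobic_core_loss" in basis.approaches  # rules still run


def test_destabilizing_flag_monotone_in_ddg():
    mutation = MutationRecord(position=10, wt="L", mut="R", label="dba")
    context = MutationContext(rsasa=0.05, in_helix=False, is_interface=False)
    flagged = [classify_mutation(mutation, make_features(ddg=d), context
                                 ).destabilizing
               for d in (0.5, 0.99, 1.01, 5.0, 20.0)]
    assert flagged == [False, False, True, True, True]


def test_summarize_counts_on_planted_set():
    from rps19struct.basis import StructuralBasis

    bases = []
    # 2 destabilizing, one with two approaches
    bases.append(StructuralBasis("A1V", True,
                                 {"hydrophobic_core_loss", "steric_core_clash"}))
    bases.append(StructuralBasis("L2P", True, {"helix_break_proline"}))
    # 1 interaction-disrupting only
    bases.append(StructuralBasis("S3F", False, set(), True,
                                 {"steric_interface_clash"}))
    summary = summarize_basis(bases)
    assert summary["n"] == 3
    assert summary["n_destabilizing"] == 2
    assert summary["n_interaction_disrupting"] == 1
    assert summary["n_both"] == 0
    assert summary["destabilizing_multi_fraction"] == pytest.approx(0.5)
    assert summary["counts"]["helix_break_proline"] == 1
    empty = summarize_basis([])
    assert empty["n"] == 0
    assert empty["n_destabilizing"] == 0
    assert empty["destabilizing_multi_fraction"] == 0.0
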