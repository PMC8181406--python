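import numpy as np
import pytest

from rps19struct.flexibility import (FlexibilityProfile, backbone_rmsf,
                                     call_idrs, cluster_conformations,
                                     pairwise_backbone_rmsd, simplify_ss)
from rps19struct.structures import Atom, Chain, Ensemble, Residue, StructureModel
from rps19struct.synthetic import make_ensemble


def _copy_model(model, transform=None, model_id=1):
    chains = []
    for chain in model.chains:
        residues = []
        for r in chain.residues:
            atoms = []
            for a in r.atoms:
                pos = a.position if transform is None else transform(a.position)
                atoms.append(Atom(a.name, a.element, np.array(pos)))
            residues.append(Residue(r.chain_id, r.number, r.name, atoms))
        chains.append(Chain(chain.chain_id, residues))
    return StructureModel(chains=chains, model_id=model_id)


def test_identical_models_have_zero_rmsf():
    base = make_ensemble(2, 10, seed=0).models[0]
    ens = Ensemble(models=[_copy_model(base, model_id=i + 1) for i in range(5)])
    profile = backbone_rmsf(ens)
    np.testing.assert_allclose(profile.rmsf, 0.0, atol=1e-9)


def test_rmsf_matches_planted_sigma(floppy_ensemble):
    profile = backbone_rmsf(floppy_ensemble)
    rmsf = profile.rmsf
    floppy = rmsf[14:25]   # residues 15-25
    rigid = np.concatenate([rmsf[2:12], rmsf[27:38]])
    assert floppy.mean() == pytest.approx(2.5 * np.sqrt(3), rel=0.10)
    assert rigid.mean() < 1.0
    assert floppy.min() > rigid.max()


def test_rmsf_invariant_under_global_rigid_transform(floppy_ensemble):
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0],
                    [0, 0, 1]])
    shift = np.array([11.0, -4.0, 7.0])
    moved = Ensemble(models=[
        _copy_model(m, transform=lambda p: rot @ p + shift, model_id=m.model_id)
        for m in floppy_ensemble.models])
    a = backbone_rmsf(floppy_ensemble).rmsf
    b = backbone_rmsf(moved).rmsf
    np.testing.assert_allclose(a, b, atol=1e-6)


def test_idr_recovery_is_exact(floppy_ensemble):
    profile = backbone_rmsf(floppy_ensemble)
    call = call_idrs(profile, threshold=2.0)
    assert call.intervals == [(15, 25)]


def test_idr_three_planted_regions():
    ens = make_ensemble(n_models=250, n_residues=60,
                        floppy_intervals=((10, 18), (30, 40), (50, 54)),
                        seed=4)
    call = call_idrs(backbone_rmsf(ens))
    assert call.intervals == [(10, 18), (30, 40), (50, 54)]


def test_idrs_exclude_chain_termini():
    profile = FlexibilityProfile(residue_numbers=list(range(1, 11)),
                                 rmsf=np.full(10, 5.0),
                                 reference=np.zeros((40, 3)))
    call = call_idrs(profile)
    assert call.intervals == [(2, 9)]
    quiet = FlexibilityProfile(residue_numbers=list(range(1, 11)),
                               rmsf=np.full(10, 1.0),
                               reference=np.zeros((40, 3)))
    assert call_idrs(quiet).intervals == []


def test_two_conformer_clustering():
    a = make_ensemble(2, 15, seed=0).models[0]
    b = _copy_model(a)
    # bend conformer B: displace the second half far away
    for chain in b.chains:
        for r in chain.residues:
            if r.number > 7:
                for at in r.atoms:
                    at.position = at.position + np.array([20.0, 0.0, 0.0])
    models = []
    for i in range(20):
        models.append(_copy_model(a, model_id=len(models) + 1))
    for i in range(20):
        models.append(_copy_model(b, model_id=len(models) + 1))
    result = cluster_conformations(Ensemble(models=models), rmsd_cutoff=2.0,
                                   min_points=4)
    occ = sorted(result.occupancies.values())
    assert occ == [0.5, 0.5]
    assert len(result.representatives) == 2
    for label, rep in result.representatives.items():
        assert result.labels[rep] == label


def test_identical_ensemble_is_one_cluster():
    base = make_ensemble(2, 10, seed=0).models[0]
    ens = Ensemble(models=[_copy_model(base, model_id=i + 1) for i in range(6)])
    result = cluster_conformations(ens)
    assert list(result.occupancies.values()) == [1.0]


def test_clustering_independent_of_model_order():
    ens = make_ensemble(n_models=24, n_residues=12,
                        floppy_intervals=((4, 8),), sigma_floppy=0.5, seed=9)
    result1 = cluster_conformations(ens)
    reversed_ens = Ensemble(models=[_copy_model(m, model_id=i + 1)
                                    for i, m in enumerate(reversed(ens.models))])
    result2 = cluster_conformations(reversed_ens)
    assert sorted(result1.occupancies.values()) == sorted(
        result2.occupancies.values())


def test_pairwise_rmsd_matches_per_pair_superposition_oracle():
    from scipy.spatial.transform import Rotation

    ens = make_ensemble(n_models=6, n_residues=10, sigma_rigid=0.8, seed=5)
    mat = pairwise_backbone_rmsd(ens)
    coords = [np.array([a.position for _, a in m.atoms()]) for m in ens.models]
    for i in range(6):
        assert mat[i, i] == 0.0
        for j in range(i + 1, 6):
            x = coords[i] - coords[i].mean(axis=0)
            y = coords[j] - coords[j].mean(axis=0)
            rot, rssd = Rotation.align_vectors(y, x)
            oracle = rssd / np.sqrt(len(x))
            assert mat[i, j] == pytest.approx(oracle, abs=1e-6)
            assert mat[j, i] == mat[i, j]


@pytest.mark.parametrize("ss8,expected", [
    ("HHHGGG", "HHHHHH"),
    ("BETS", "EECC"),
    ("", ""),
    ("GHIBETSC -", "HHHEECCCCC"),
])
def test_simplify_ss_mapping(ss8, expected):
    assert simplify_ss(ss8) == expected


def test_simplify_ss_rejects_unknown_state():
    with pytest.raises(ValueError):
        simplify_ss("HXZ")


def test_rmsf_requires_two_models():
    single = Ensemble(models=[make_ensemble(2, 5, seed=0).models[0]])
    with pytest.raises(ValueError):
        backbone_rmsf(single)
    with pytest.raises(ValueError):
        cluster_conformations(single)
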