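import numpy as np
import pytest

from rps19struct.structures import Atom, Chain, Residue, StructureModel
from rps19struct.synthetic import (FeatureTableSpec, ToyComplexSpec,
                                   make_ensemble, make_feature_table,
                                   make_toy_complex)


@pytest.fixture(scope="session")
def toy_complex():
    """Helical protein + pseudo-RNA with contacts at 5, 9, 14; H-bonds at 5, 9."""
    spec = ToyComplexSpec(n_protein_residues=20, contact_positions=(5, 9, 14),
                          hbond_positions=(5, 9), seed=1)
    return make_toy_complex(spec)


@pytest.fixture(scope="session")
def floppy_ensemble():
    """300-model ensemble, residues 15-25 floppy (sigma 2.5 A), rest rigid."""
    return make_ensemble(n_models=300, n_residues=40,
                         floppy_intervals=((15, 25),), seed=2)


@pytest.fixture(scope="session")
def feature_table():
    """Default disease/neutral feature table (51 + 30 rows)."""
    return make_feature_table(FeatureTableSpec(seed=3))


def simple_protein(coords_by_residue, chain_id="A", resname="GLY"):
    """Build a minimal protein model from {resnum: {atom_name: xyz}}."""
    residues = []
    for number, atoms in sorted(coords_by_residue.items()):
        residues.append(Residue(chain_id, number, resname, [
            Atom(name, name[0], np.asarray(xyz, dtype=float))
            for name, xyz in atoms.items()
        ]))
    return StructureModel(chains=[Chain(chain_id, residues)])
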