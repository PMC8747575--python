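import numpy as np
import pytest

from vapsol import load_fixtures, parse_smiles
from vapsol.molgraph import MolecularGraph, Atom, Bond


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def re_graphs(fixtures):
    """The sixteen polymer repeating elements as molecular graphs."""
    return [
        parse_smiles(row.re_smiles, row.re_name)
        for row in fixtures.repeating_elements.itertuples()
    ]


def permute_graph(g: MolecularGraph, perm) -> MolecularGraph:
    """Relabel atoms of a graph by a permutation (old index -> new index)."""
    inv = {old: new for new, old in enumerate(perm)}
    atoms = [g.atoms[old] for old in perm]
    bonds = [Bond(inv[b.i], inv[b.j], b.order) for b in g.bonds]
    return MolecularGraph(atoms=atoms, bonds=bonds, name=g.name)


@pytest.fixture
def rng():
    return np.random.default_rng(20240061)
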