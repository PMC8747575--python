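"""E-state values, descriptor sums, counts, and the quantum block.

Frozen expected values are hand calculations from the intrinsic-state and
perturbation formulas, written as exact fractions; the independent oracle
check against RDKit's published E-state implementation lives at the bottom.
"""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem.EState import EStateIndices

from vapsol.descriptors import (
    DESCRIPTOR_ORDER,
    DescriptorError,
    DescriptorVector,
    QuantumInput,
    compute_descriptors,
    count_descriptors,
    descriptor_table,
    estate_sums,
    estate_values,
    hydrogen_estate_values,
    intrinsic_state,
    intrinsic_states,
    quantum_block,
)
from vapsol.molgraph import parse_smiles
from conftest import permute_graph


@pytest.mark.parametrize(
    "element, n_h, degree, expected",
    [
        ("C", 3, 1, 2.0),        # methyl carbon
        ("C", 2, 2, 1.5),        # methylene carbon
        ("O", 1, 1, 6.0),        # hydroxyl oxygen
        ("O", 0, 2, 3.5),        # ether oxygen
        ("N", 2, 1, 4.0),        # primary amine nitrogen
        ("Cl", 0, 1, 37.0 / 9),  # chlorine: N=3, dv=7
    ],
)
def test_intrinsic_state_values(element, n_h, degree, expected):
    assert intrinsic_state(element, n_h, degree) == pytest.approx(expected, abs=1e-12)


def test_intrinsic_state_degree_zero_needs_single_atom_convention():
    with pytest.raises(DescriptorError):
        intrinsic_state("C", 4, 0)
    assert intrinsic_state("C", 4, 0, single_atom=True) == pytest.approx(1.0)


class TestEStateValues:
    def test_ethane_no_perturbation(self):
        assert estate_values(parse_smiles("CC")) == pytest.approx([2.0, 2.0])

    def test_dimethyl_ether(self):
        S = estate_values(parse_smiles("COC"))
        assert S == pytest.approx([1.625, 4.25, 1.625], abs=1e-12)

    def test_ethanol(self):
        S = estate_values(parse_smiles("CCO"))
        expected = [
            2 + (2 - 1.5) / 4 + (2 - 6) / 9,
            1.5 + (1.5 - 2) / 4 + (1.5 - 6) / 4,
            6 + (6 - 1.5) / 4 + (6 - 2) / 9,
        ]
        assert S == pytest.approx(expected, abs=1e-12)

    def test_single_heavy_atom_is_intrinsic_state(self):
        g = parse_smiles("C")
        assert estate_values(g) == pytest.approx(intrinsic_states(g))

    def test_propanoic_acid_hand_values(self):
        # atoms in SMILES order CCC(=O)O: sCH3, ssCH2, dssC, dO, sOH
        # I = 2, 3/2, 5/3, 7, 6
        S = estate_values(parse_smiles("CCC(=O)O"))
        expected = [
            2 + (1 / 2) / 4 + (1 / 3) / 9 - 5 / 16 - 4 / 16,
            3 / 2 - (1 / 2) / 4 - (1 / 6) / 4 - (11 / 2) / 9 - (9 / 2) / 9,
            5 / 3 - (1 / 3) / 9 + (1 / 6) / 4 - (16 / 3) / 4 - (13 / 3) / 4,
            7 + 5 / 16 + (11 / 2) / 9 + (16 / 3) / 4 + 1 / 9,
            6 + 4 / 16 + (9 / 2) / 9 + (13 / 3) / 4 - 1 / 9,
        ]
        assert S == pytest.approx(expected, abs=1e-9)

    def test_benzene_symmetry(self):
        assert estate_values(parse_smiles("c1ccccc1")) == pytest.approx([2.0] * 6)


def test_global_estate_conservation(re_graphs):
    """Perturbation terms cancel pairwise, so sum(S) == sum(I)."""
    for g in re_graphs + [parse_smiles("c1ccccc1"), parse_smiles("CCC(=O)O")]:
        assert estate_values(g).sum() == pytest.approx(
            intrinsic_states(g).sum(), abs=1e-10
        )


class TestEStateSums:
    def test_ethane(self):
        sums = estate_sums(parse_smiles("CC"))
        assert sums["SsCH3"] == pytest.approx(4.0)
        assert all(v == 0.0 for k, v in sums.items() if k != "SsCH3")

    def test_dimethyl_ether(self):
        sums = estate_sums(parse_smiles("COC"))
        assert sums["SssO"] == pytest.approx(4.25)
        assert sums["SsCH3"] == pytest.approx(3.25)
        assert sums["SHBa"] == pytest.approx(4.25)  # ether O is an acceptor
        assert sums["SHBd"] == 0.0  # no H on N/O

    def test_methane_has_no_typed_groups(self):
        assert all(v == 0.0 for v in estate_sums(parse_smiles("C")).values())

    def test_plain_alkane_reduces_to_ch3_ch2_types(self):
        sums = estate_sums(parse_smiles("CCCC"))
        assert sums["SsCH3"] > 0 and sums["SssCH2"] > 0
        assert all(
            v == 0.0 for k, v in sums.items() if k not in ("SsCH3", "SssCH2")
        )

    def test_ethanol_donor_sum_from_hydrogen_estate(self):
        # lone OH hydrogen: I_H = 5, perturbed by O (d=1), CH2 (d=2), CH3 (d=3)
        expected = 5 + (5 - 6) / 4 + (5 - 1.5) / 9 + (5 - 2) / 16
        sums = estate_sums(parse_smiles("CCO"))
        assert sums["SHBd"] == pytest.approx(expected, abs=1e-12)
        assert sums["SsOH"] == pytest.approx(6 + 4.5 / 4 + 4 / 9, abs=1e-12)

    def test_shdsch_on_polyisoprene_re(self):
        # H on the =CH- carbon of 2-methyl-2-butene
        expected = 5 + 3 / 4 + 1 / 3 + (10 / 3) / 9 + 2 * (3 / 16)
        sums = estate_sums(parse_smiles("CC=C(C)C"))
        assert sums["SHdsCH"] == pytest.approx(expected, abs=1e-12)


def test_hydrogen_estate_count_matches_hydrogens():
    g = parse_smiles("CCO")
    assert len(hydrogen_estate_values(g)) == g.n_hydrogens


@pytest.mark.parametrize(
    "smiles, narombond, nheavy, nacid",
    [
        ("c1ccccc1", 6, 6, 0),
        ("CCC(=O)O", 0, 5, 1),
        ("C", 0, 1, 0),
        ("CCc1ccccc1", 6, 8, 0),
        ("CC(=O)OCC", 0, 6, 0),  # ester is not an acid
    ],
)
def test_count_descriptors(smiles, narombond, nheavy, nacid):
    counts = count_descriptors(parse_smiles(smiles))
    assert counts == {"nAromBond": narombond, "nHeavyAtom": nheavy, "nAcid": nacid}


class TestQuantumBlock:
    def test_hardness_and_electronegativity(self):
        q = QuantumInput(EHOMO=-0.3, ELUMO=-0.1, Qxx=1, Qyy=1, Qzz=1, AE=-2.0)
        block = quantum_block(q)
        assert block["eta"] == pytest.approx(0.2)
        assert block["chi"] == pytest.approx(0.2)
        assert block["QM"] == pytest.approx(1.0)
        assert block["AE"] == -2.0

    def test_isotropic_tensor_passes_through(self):
        q = QuantumInput(EHOMO=-0.3, ELUMO=-0.1, Qxx=7.5, Qyy=7.5, Qzz=7.5, AE=0.5)
        assert quantum_block(q)["QM"] == pytest.approx(7.5)

    def test_degenerate_frontier_orbitals_give_zero_hardness(self):
        q = QuantumInput(EHOMO=-0.2, ELUMO=-0.2, Qxx=0, Qyy=0, Qzz=0, AE=1.0)
        assert quantum_block(q)["eta"] == 0.0

    def test_missing_field_named(self):
        with pytest.raises(DescriptorError, match="AE"):
            QuantumInput(EHOMO=-0.3, ELUMO=-0.1, Qxx=1, Qyy=1, Qzz=1, AE=float("nan"))

    def test_inverted_orbital_ordering_warns(self):
        with pytest.warns(UserWarning, match="ELUMO"):
            QuantumInput(EHOMO=-0.1, ELUMO=-0.3, Qxx=1, Qyy=1, Qzz=1, AE=1.0)


def test_descriptor_vector_canonical_order():
    vec = compute_descriptors(parse_smiles("CC"))
    assert tuple(vec.as_dict()) == DESCRIPTOR_ORDER
    with pytest.raises(DescriptorError, match="missing"):
        DescriptorVector.from_mapping({"AE": 1.0})


def test_descriptors_invariant_under_atom_reordering(re_graphs, rng):
    for g in re_graphs:
        perm = list(rng.permutation(g.n_heavy))
        a = compute_descriptors(g).as_array()
        b = compute_descriptors(permute_graph(g, perm)).as_array()
        np.testing.assert_allclose(a[2:], b[2:], atol=1e-10)  # skip NaN AE/QM slots
        assert np.isnan(a[:2]).all() and np.isnan(b[:2]).all()


def test_descriptor_table_joins_quantum_by_name():
    graphs = [parse_smiles("CC", "ethane"), parse_smiles("CCO", "ethanol")]
    qtab = pd.DataFrame(
        [{"name": "ethane", "EHOMO": -0.35, "ELUMO": 0.05,
          "Qxx": -20.0, "Qyy": -20.0, "Qzz": -21.0, "AE": -1.2}]
    )
    table = descriptor_table(graphs, qtab)
    assert list(table.columns) == ["name", *DESCRIPTOR_ORDER]
    assert table.loc[0, "eta"] == pytest.approx(0.4)
    assert np.isnan(table.loc[1, "AE"])  # no quantum row for ethanol


def test_estate_oracle_equivalence(fixtures):
    """Independent-oracle check: heavy-atom E-states against RDKit's
    published E-state implementation on the 16-molecule RE fixture set."""
    smiles = list(fixtures.repeating_elements["re_smiles"])
    assert len(smiles) >= 10
    for smi in smiles:
        mine = estate_values(parse_smiles(smi))
        ref = np.asarray(EStateIndices(Chem.MolFromSmiles(smi)), dtype=float)
        np.testing.assert_allclose(mine, ref, atol=1e-6)
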