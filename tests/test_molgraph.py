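"""Featurization and pair-table I/O tests."""

import logging

import networkx as nx
import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import Descriptors

from hypersolv.errors import ConfigError, FormatError, InputError
from hypersolv.molgraph import (ATOM_FEATURE_DIM, BOND_FEATURE_DIM,
                                FeatureProjector, MolecularGraph, PairExample,
                                featurize_molecule, read_pair_table,
                                standardize_feature_lengths, write_pair_table)
from hypersolv.synthetic import SyntheticSpec, generate_molecules

AROMATIC_COL = 14


def test_benzene_ring_topology():
    g = featurize_molecule("c1ccccc1")
    assert g.n_atoms == 6 and g.n_bonds == 6
    assert np.all(g.atom_features[:, AROMATIC_COL] == 1.0)


def test_ethanol_counts_and_weight():
    g = featurize_molecule("CCO")
    assert g.n_atoms == 3 and g.n_bonds == 2
    expected_mw = Descriptors.MolWt(Chem.MolFromSmiles("CCO"))
    assert g.global_features[2] == pytest.approx(expected_mw)
    assert g.global_features[2] == pytest.approx(46.07, abs=0.01)


def test_water_single_heavy_atom_with_two_hydrogens():
    g = featurize_molecule("O")
    assert g.n_atoms == 1 and g.n_bonds == 0
    assert g.atom_features[0, 11] == 2.0  # bonded-H count


@pytest.mark.parametrize("bad", ["not_a_smiles", "C(((", ""])
def test_unparsable_smiles_raises_naming_input(bad):
    with pytest.raises(InputError):
        featurize_molecule(bad)


def test_featurization_is_deterministic():
    a = featurize_molecule("CC(=O)OC1=CC=CC=C1C(=O)O")
    b = featurize_molecule("CC(=O)OC1=CC=CC=C1C(=O)O")
    np.testing.assert_array_equal(a.atom_features, b.atom_features)
    np.testing.assert_array_equal(a.bond_features, b.bond_features)
    np.testing.assert_array_equal(a.bond_index, b.bond_index)


def _feature_graph(g: MolecularGraph) -> nx.Graph:
    gr = nx.Graph()
    for i in range(g.n_atoms):
        gr.add_node(i, row=tuple(np.round(g.atom_features[i], 6)))
    for (p, q), feat in zip(g.bond_index, g.bond_features):
        gr.add_edge(int(p), int(q), row=tuple(np.round(feat, 6)))
    return gr


@pytest.mark.parametrize("smiles", ["CCO", "c1ccncc1", "CC(C)C(=O)O", "FC(F)CO"])
def test_rerooted_smiles_isomorphic_features(smiles):
    """Featurizing a re-rooted SMILES yields the same graph up to permutation."""
    mol = Chem.MolFromSmiles(smiles)
    base = featurize_molecule(smiles)
    for root in range(min(mol.GetNumAtoms(), 4)):
        alt_smiles = Chem.MolToSmiles(mol, rootedAtAtom=root, canonical=False)
        alt = featurize_molecule(alt_smiles)
        gm = nx.algorithms.isomorphism.GraphMatcher(
            _feature_graph(base), _feature_graph(alt),
            node_match=lambda a, b: a["row"] == b["row"],
            edge_match=lambda a, b: a["row"] == b["row"],
        )
        assert gm.is_isomorphic()


def test_structural_counts_on_random_molecules():
    spec = SyntheticSpec(seed=7, size_range=(3, 10))
    for smi in generate_molecules(spec, 100):
        g = featurize_molecule(smi)
        mol = Chem.MolFromSmiles(smi)
        assert g.n_atoms == mol.GetNumAtoms()
        assert g.n_bonds == mol.GetNumBonds()
        assert g.global_features[0] == g.n_atoms
        assert g.global_features[1] == g.n_bonds
        # one-hot blocks each sum to exactly 1
        np.testing.assert_allclose(g.atom_features[:, 0:10].sum(axis=1), 1.0)
        np.testing.assert_allclose(g.atom_features[:, 15:19].sum(axis=1), 1.0)
        if g.n_bonds:
            np.testing.assert_allclose(g.bond_features[:, 0:4].sum(axis=1), 1.0)
            np.testing.assert_allclose(g.bond_features[:, 5:12].sum(axis=1), 1.0)
            np.testing.assert_allclose(g.bond_features[:, 12:16].sum(axis=1), 1.0)


def test_bond_list_triplets():
    g = featurize_molecule("CCO")
    triplets = g.bond_list
    assert len(triplets) == g.n_bonds
    for feat, p, q in triplets:
        assert feat.shape == (BOND_FEATURE_DIM,)
        assert 0 <= p < g.n_atoms and 0 <= q < g.n_atoms


def test_stereo_bond_feature():
    trans = featurize_molecule("C/C=C/C")
    cis = featurize_molecule(r"C/C=C\C")
    plain = featurize_molecule("CC=CC")
    double = lambda g: g.bond_features[[o == "DOUBLE" for o in g.bond_orders]][0]
    assert double(trans)[13] == 1.0  # E
    assert double(cis)[14] == 1.0    # Z
    assert double(plain)[12] == 1.0  # none


# -- pair tables ----------------------------------------------------------

def _write(tmp_path, text, name="pairs.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


def test_read_pair_table_roundtrip(tmp_path):
    path = _write(tmp_path, "solute_smiles,solvent_smiles,dg_solv\n"
                            "CCO,O,-5.0\nCCN,O,-4.5\nCCC,CCO,1.2\n")
    pairs = read_pair_table(path)
    assert len(pairs) == 3
    assert pairs[0].label == -5.0
    assert pairs[2].solvent.smiles == "CCO"
    out = tmp_path / "echo.csv"
    write_pair_table(pairs, out)
    assert len(read_pair_table(out)) == 3


def test_read_pair_table_skips_bad_rows(tmp_path, caplog):
    path = _write(tmp_path, "solute_smiles,solvent_smiles,dg_solv\n"
                            "CCO,O,-5.0\nXXX(,O,-4.5\nCCC,O,1.2\n")
    with caplog.at_level(logging.WARNING):
        pairs = read_pair_table(path)
    assert len(pairs) == 2
    assert any("line 3" in rec.message for rec in caplog.records)
    with pytest.raises(InputError):
        read_pair_table(path, strict=True)


def test_read_pair_table_missing_columns(tmp_path):
    path = _write(tmp_path, "solute,solvent\nCCO,O\n")
    with pytest.raises(FormatError, match="solute_smiles"):
        read_pair_table(path)


def test_read_pair_table_header_only_warns(tmp_path):
    path = _write(tmp_path, "solute_smiles,solvent_smiles,dg_solv\n")
    with pytest.warns(UserWarning):
        assert read_pair_table(path) == []


def test_read_pair_table_tsv_autodetect(tmp_path):
    path = _write(tmp_path, "solute_smiles\tsolvent_smiles\nCCO\tO\n", "pairs.tsv")
    pairs = read_pair_table(path)
    assert len(pairs) == 1 and pairs[0].label is None


def test_pair_example_rejects_nonfinite_label():
    g = featurize_molecule("C")
    with pytest.raises(InputError):
        PairExample(g, g, float("nan"))


# -- feature standardization ----------------------------------------------

def test_projector_standardizes_widths(rng):
    proj = FeatureProjector(300, rng)
    atoms, bonds, glob = standardize_feature_lengths(featurize_molecule("CCO"), proj)
    assert atoms.shape == (3, 300)
    assert bonds.shape == (2, 300)
    assert glob.shape == (1, 300)


def test_identity_projector_preserves_atom_features(rng):
    proj = FeatureProjector(ATOM_FEATURE_DIM, rng, identity=True)
    g = featurize_molecule("CCO")
    atoms, _, _ = proj.project(g)
    np.testing.assert_allclose(atoms.data, g.atom_features)


def test_projector_width_mismatch_is_config_error(rng):
    proj = FeatureProjector(16, rng)
    g = featurize_molecule("CCO")
    bad = g.__class__(**{**g.__dict__, "atom_features": g.atom_features[:, :5]})
    with pytest.raises(ConfigError):
        standardize_feature_lengths(bad, proj)
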