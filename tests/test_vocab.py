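"""Vocabulary mining, decomposition, and canonical-key tests."""

import numpy as np
import pytest

from hypersolv.errors import ConfigError, InputError
from hypersolv.molgraph import featurize_molecule
from hypersolv.synthetic import SyntheticSpec, generate_molecules
from hypersolv.vocab import (DEFAULT_PRIOR_PATTERNS, Fragment,
                             SubgraphVocabulary, canonical_key, contains,
                             decompose, fragment_from_pattern,
                             init_vocabulary, mine_vocabulary)

from _oracles import canonical_form, graph_from_molgraph


def F(smiles):
    return featurize_molecule(smiles)


# -- initialization -------------------------------------------------------

def test_init_vocabulary_species_enumeration():
    vocab = init_vocabulary([F("CCO"), F("CCN")])
    assert {f.canonical_form for f in vocab.fragments} == {"C", "N", "O"}


def test_init_vocabulary_single_molecule():
    vocab = init_vocabulary([F("CC")])
    (frag,) = vocab.fragments
    assert frag.canonical_form == "C" and frag.frequency == 1


def test_init_vocabulary_molecule_level_counts():
    vocab = init_vocabulary([F("CCO"), F("CO"), F("O")])
    by_key = {f.canonical_form: f.frequency for f in vocab.fragments}
    assert by_key == {"C": 2, "O": 3}


def test_init_vocabulary_empty_corpus():
    with pytest.raises(InputError):
        init_vocabulary([])


# -- canonical keys -------------------------------------------------------

def test_canonical_key_direction_independent():
    g = F("CCO")
    assert canonical_key({0, 1, 2}, g) == canonical_key([2, 1, 0], g)


def test_canonical_key_distinguishes_heteroatoms():
    assert canonical_key({1, 2}, F("CCO")) != canonical_key({1, 2}, F("CCN"))


def test_canonical_key_crosses_parents():
    assert canonical_key({0, 1}, F("CCO")) == canonical_key({1, 2}, F("CCC"))


def test_canonical_key_disconnected_raises():
    with pytest.raises(ValueError):
        canonical_key({0, 2}, F("CCO"))


def test_canonical_key_agrees_with_bruteforce_canonicalization():
    """Package keys and the oracle's permutation-min canonical form induce the
    same fragment equivalence classes on random molecules."""
    spec = SyntheticSpec(seed=5, size_range=(3, 7))
    seen: dict[str, str] = {}
    for smi in generate_molecules(spec, 40):
        g = F(smi)
        elements, edges = graph_from_molgraph(g)
        # all connected pairs + a few triples
        for (p, q), _ in zip(g.bond_index, g.bond_orders):
            key = canonical_key({int(p), int(q)}, g)
            from _oracles import induced_fragment
            form = canonical_form(*induced_fragment(elements, edges, (int(p), int(q))))
            if key in seen:
                assert seen[key] == form
            else:
                assert form not in seen.values()
                seen[key] = form


# -- mining ---------------------------------------------------------------

def test_first_merge_is_most_frequent(tiny_corpus):
    vocab = mine_vocabulary(tiny_corpus, capacity=4, priors=None)
    merged = [f for f in vocab.fragments if f.size > 1]
    assert merged and merged[0].canonical_form == "CC"
    assert merged[0].frequency == 3


def test_capacity_at_species_count_means_no_merges(tiny_corpus):
    vocab = mine_vocabulary(tiny_corpus, capacity=3, priors=None)
    assert all(f.size == 1 for f in vocab.fragments)


def test_single_atom_corpus():
    vocab = mine_vocabulary([F("O")], capacity=5, priors=None)
    assert [f.canonical_form for f in vocab.fragments] == ["O"]


def test_capacity_below_forced_entries_is_config_error(tiny_corpus):
    with pytest.raises(ConfigError):
        mine_vocabulary(tiny_corpus, capacity=2, priors=None)


def test_priors_are_present_and_flagged(tiny_corpus):
    vocab = mine_vocabulary(tiny_corpus, capacity=10,
                            priors=DEFAULT_PRIOR_PATTERNS)
    prior_keys = {f.canonical_form for f in vocab.prior_fragments}
    assert {"O", "N", "F", "O=CO"} <= prior_keys


def test_mining_determinism(tiny_corpus):
    a = mine_vocabulary(tiny_corpus, capacity=6, priors=None)
    b = mine_vocabulary(tiny_corpus, capacity=6, priors=None)
    assert [(f.canonical_form, f.size, f.frequency, f.rank) for f in a.fragments] \
        == [(f.canonical_form, f.size, f.frequency, f.rank) for f in b.fragments]


def test_frequency_monotone_under_containment():
    """A fragment is at least as frequent as any fragment containing it."""
    corpus = [F(s) for s in ("CCO", "CCCO", "CCN", "OCCO", "CCC")]
    vocab = mine_vocabulary(corpus, capacity=12, priors=None)
    for small in vocab.fragments:
        for big in vocab.fragments:
            if big.size <= small.size:
                continue
            big_graph = F(big.canonical_form) if big.size > 1 else None
            if big_graph is not None and contains(small, big_graph):
                assert small.frequency >= big.frequency


# -- decomposition --------------------------------------------------------

def test_decompose_prefers_larger_fragment(tiny_corpus):
    vocab = mine_vocabulary(tiny_corpus, capacity=4, priors=None)  # has C-C
    hg = decompose(F("CCO"), vocab)
    assert set(map(frozenset, hg.hypernodes)) == {frozenset({0, 1}), frozenset({2})}
    assert hg.fragment_keys[hg.atom_to_hypernode[2]] == "O"


def test_decompose_singleton_vocabulary(tiny_corpus):
    vocab = init_vocabulary(tiny_corpus)
    hg = decompose(F("CCO"), vocab)
    assert hg.n_hypernodes == 3
    assert all(len(h) == 1 for h in hg.hypernodes)


def test_decompose_whole_molecule_fragment():
    corpus = [F("CCO"), F("CCO")]
    vocab = mine_vocabulary(corpus, capacity=6, priors=None)
    assert "CCO" in vocab
    hg = decompose(F("CCO"), vocab)
    assert hg.n_hypernodes == 1 and len(hg.hypernodes[0]) == 3


def test_decompose_unknown_species_falls_back_to_singletons(tiny_corpus):
    vocab = init_vocabulary(tiny_corpus)  # no S
    hg = decompose(F("CS"), vocab)
    hg.validate(F("CS"))
    assert None in hg.fragment_keys  # sulfur marked as fallback


def test_partition_invariant_on_random_molecules():
    spec = SyntheticSpec(seed=17, size_range=(3, 10))
    molecules = [F(s) for s in generate_molecules(spec, 60)]
    vocab = mine_vocabulary(molecules[:25], capacity=20)
    for g in molecules:
        hg = decompose(g, vocab)
        hg.validate(g)  # raises on any partition/connectivity violation
        assert sum(len(h) for h in hg.hypernodes) == g.n_atoms


# -- persistence ----------------------------------------------------------

def test_vocabulary_roundtrip_bit_exact(tmp_path, tiny_corpus):
    vocab = mine_vocabulary(tiny_corpus, capacity=8)
    p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
    vocab.save(p1)
    SubgraphVocabulary.load(p1).save(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_fragment_pattern_roundtrip():
    frag = fragment_from_pattern("OC=O")
    assert frag.size == 3
    assert contains(frag, F("CC(=O)O"))
    assert not contains(frag, F("CCO"))
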