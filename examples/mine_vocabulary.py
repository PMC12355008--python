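"""Mine a fragment vocabulary from a small corpus and decompose a molecule.

Builds molecular graphs for a handful of small organics, mines the
principal-subgraph vocabulary (single atoms first, then iteratively the most
frequent merge of two bond-adjacent fragments), and shows how a molecule is
partitioned into hypernodes.
"""

from hypersolv import featurize_molecule, mine_vocabulary, decompose

corpus = [featurize_molecule(s)
          for s in ("CCO", "CCCO", "CCN", "CC(=O)O", "OCCO", "CCC")]

vocab = mine_vocabulary(corpus, capacity=12)
print(f"{len(vocab)} fragments (rank: key, size, frequency, prior):")
for frag in vocab.fragments:
    star = "*" if frag.is_prior else " "
    print(f"  {frag.rank:2d}: {frag.canonical_form:6s} size={frag.size} "
          f"freq={frag.frequency} {star}")

mol = featurize_molecule("OCC(=O)O")  # glycolic acid
hg = decompose(mol, vocab)
print(f"\n{mol.smiles} -> {hg.n_hypernodes} hypernodes:")
for atoms, key in zip(hg.hypernodes, hg.fragment_keys):
    print(f"  atoms {list(atoms)} = fragment {key}")
# Larger mined fragments claim atoms first; leftovers become single atoms.
# Frequencies count molecules containing the fragment, not occurrences.
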