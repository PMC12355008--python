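"""Principal-subgraph vocabulary mining and hypergraph decomposition.

The vocabulary starts from all single-atom species present in the corpus.
Mining then repeats: decompose every corpus molecule into current-vocabulary
fragments, enumerate every merge of two fragments adjacent through at least
one bond, and append the merged candidate contained in the most molecules
(molecule-level indicator counting, not occurrence counting).  Mining stops at
the capacity or when no candidate is contained in at least two molecules.

Fragment identity is defined over heavy-atom elements and bond orders; the
canonical key of a multi-atom fragment is its environment-independent
canonical SMILES, and occurrences/containment are node-induced subgraph
isomorphisms on (element, bond-order) labelled graphs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from networkx.algorithms.isomorphism import GraphMatcher, categorical_edge_match, categorical_node_match
from rdkit import Chem

from .errors import ConfigError, FormatError, InputError
from .molgraph import MolecularGraph

log = logging.getLogger(__name__)

#: Prior-knowledge fragment patterns guaranteed in every mined vocabulary:
#: hydroxyl/ether oxygen, amine nitrogen, fluorine, and the carboxyl group.
#: Hydrogens are implicit in heavy-atom graphs, so H-only patterns have no
#: fragment representation and hydroxyl collapses onto the oxygen atom.
DEFAULT_PRIOR_PATTERNS = ("O", "N", "F", "OC=O")

_NODE_MATCH = categorical_node_match("element", None)
_EDGE_MATCH = categorical_edge_match("order", None)

# caches keyed by SMILES (graphs rebuilt from identical SMILES are identical)
_nx_cache: dict[str, nx.Graph] = {}
_mol_cache: dict[str, Chem.Mol] = {}
_occ_cache: dict[tuple[str, str], tuple[frozenset, ...]] = {}
_key_cache: dict[tuple[str, frozenset], str] = {}


def clear_caches() -> None:
    _nx_cache.clear()
    _mol_cache.clear()
    _occ_cache.clear()
    _key_cache.clear()


def _as_nx(graph: MolecularGraph) -> nx.Graph:
    g = _nx_cache.get(graph.smiles)
    if g is None:
        g = nx.Graph()
        for i, el in enumerate(graph.elements):
            g.add_node(i, element=el)
        for (p, q), order in zip(graph.bond_index, graph.bond_orders):
            g.add_edge(int(p), int(q), order=order)
        _nx_cache[graph.smiles] = g
    return g


def _as_mol(graph: MolecularGraph) -> Chem.Mol:
    mol = _mol_cache.get(graph.smiles)
    if mol is None:
        mol = Chem.MolFromSmiles(graph.smiles)
        if mol is None:  # cannot happen for graphs built by featurize_molecule
            raise InputError(f"unparsable SMILES: {graph.smiles!r}")
        _mol_cache[graph.smiles] = mol
    return mol


def canonical_key(atom_set: Iterable[int], graph: MolecularGraph) -> str:
    """Canonical text key of a connected fragment of ``graph``.

    Isomorphic labelled fragments (same elements, same bond orders) map to the
    same key regardless of the parent molecule or atom enumeration order.
    Single atoms map to their bare element symbol.
    """
    atoms = frozenset(int(a) for a in atom_set)
    cached = _key_cache.get((graph.smiles, atoms))
    if cached is not None:
        return cached
    if not atoms:
        raise ValueError("empty atom set")
    sub = _as_nx(graph).subgraph(atoms)
    if not nx.is_connected(sub):
        raise ValueError(f"atom set {sorted(atoms)} is not connected in {graph.smiles}")
    if len(atoms) == 1:
        key = graph.elements[next(iter(atoms))]
    else:
        mol = _as_mol(graph)
        bonds = [
            b.GetIdx()
            for b in mol.GetBonds()
            if b.GetBeginAtomIdx() in atoms and b.GetEndAtomIdx() in atoms
        ]
        frag = Chem.MolFragmentToSmiles(
            mol, atomsToUse=sorted(atoms), bondsToUse=bonds,
            canonical=True, isomericSmiles=False,
        )
        # re-canonicalize so the key is independent of the parent environment
        key = Chem.MolToSmiles(Chem.MolFromSmiles(frag, sanitize=False))
    _key_cache[(graph.smiles, atoms)] = key
    return key


@dataclass(frozen=True)
class Fragment:
    """A connected fragment with its corpus frequency."""

    canonical_form: str
    size: int
    frequency: int
    is_prior: bool = False
    rank: int = 0  # mining/insertion order

    def pattern_graph(self) -> nx.Graph:
        """Labelled graph used for occurrence matching."""
        g = nx.Graph()
        if self.size == 1 and self.canonical_form.isalpha():
            g.add_node(0, element=self.canonical_form)
            return g
        mol = Chem.MolFromSmiles(self.canonical_form, sanitize=False)
        if mol is None:
            raise FormatError(f"bad fragment pattern: {self.canonical_form!r}")
        for atom in mol.GetAtoms():
            g.add_node(atom.GetIdx(), element=atom.GetSymbol())
        for bond in mol.GetBonds():
            g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
                       order=str(bond.GetBondType()))
        return g


def fragment_from_pattern(pattern: str, frequency: int = 0,
                          is_prior: bool = False, rank: int = 0) -> Fragment:
    """Build a :class:`Fragment` from a SMILES-like pattern, canonicalized."""
    mol = Chem.MolFromSmiles(pattern, sanitize=False)
    if mol is None or mol.GetNumAtoms() == 0:
        raise InputError(f"unparsable fragment pattern: {pattern!r}")
    if mol.GetNumAtoms() == 1:
        key = mol.GetAtomWithIdx(0).GetSymbol()
    else:
        key = Chem.MolToSmiles(mol)
    return Fragment(key, mol.GetNumAtoms(), frequency, is_prior, rank)


def find_occurrences(fragment: Fragment, graph: MolecularGraph) -> tuple[frozenset, ...]:
    """All distinct atom sets of ``graph`` inducing a copy of ``fragment``.

    Results are cached per (molecule, fragment) and sorted for determinism.
    """
    cache_key = (graph.smiles, fragment.canonical_form)
    occ = _occ_cache.get(cache_key)
    if occ is not None:
        return occ
    if fragment.size > graph.n_atoms:
        occ = ()
    elif fragment.size == 1:
        el = fragment.canonical_form
        occ = tuple(frozenset([i]) for i, e in enumerate(graph.elements) if e == el)
    else:
        matcher = GraphMatcher(_as_nx(graph), fragment.pattern_graph(),
                               node_match=_NODE_MATCH, edge_match=_EDGE_MATCH)
        sets = {frozenset(m) for m in matcher.subgraph_isomorphisms_iter()}
        occ = tuple(sorted(sets, key=lambda s: sorted(s)))
    _occ_cache[cache_key] = occ
    return occ


def contains(fragment: Fragment, graph: MolecularGraph) -> bool:
    return len(find_occurrences(fragment, graph)) > 0


@dataclass
class SubgraphVocabulary:
    """Ordered fragment collection; insertion order is the mining order."""

    fragments: list[Fragment] = field(default_factory=list)
    capacity: int = 0
    mining_log: list = field(default_factory=list)  # one record per iteration

    def __post_init__(self):
        self._keys = {f.canonical_form for f in self.fragments}

    def __len__(self) -> int:
        return len(self.fragments)

    def __contains__(self, key: str) -> bool:
        return key in self._keys

    @property
    def prior_fragments(self) -> list[Fragment]:
        return [f for f in self.fragments if f.is_prior]

    def add(self, fragment: Fragment) -> None:
        if fragment.canonical_form in self._keys:
            raise ValueError(f"duplicate fragment {fragment.canonical_form!r}")
        self.fragments.append(replace(fragment, rank=len(self.fragments)))
        self._keys.add(fragment.canonical_form)

    def get(self, key: str) -> Fragment | None:
        for f in self.fragments:
            if f.canonical_form == key:
                return f
        return None

    def mark_prior(self, key: str) -> None:
        for i, f in enumerate(self.fragments):
            if f.canonical_form == key:
                self.fragments[i] = replace(f, is_prior=True)
                return
        raise KeyError(key)

    def decomposition_order(self) -> list[Fragment]:
        """Greedy matching order: larger first, then more frequent, then rank."""
        return sorted(self.fragments,
                      key=lambda f: (-f.size, -f.frequency, f.rank))

    # -- persistence (JSON lines; bit-exact round trip) --------------------
    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in self.fragments:
                fh.write(json.dumps(
                    {"canonical_form": f.canonical_form, "size": f.size,
                     "frequency": f.frequency, "is_prior": f.is_prior,
                     "rank": f.rank}, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SubgraphVocabulary":
        fragments = []
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                    fragments.append(Fragment(
                        rec["canonical_form"], int(rec["size"]),
                        int(rec["frequency"]), bool(rec["is_prior"]),
                        int(rec["rank"]),
                    ))
                except (KeyError, ValueError, json.JSONDecodeError) as exc:
                    raise FormatError(f"{path} line {line_no}: {exc}") from exc
        vocab = cls(fragments, capacity=max(len(fragments), 1))
        return vocab


@dataclass(frozen=True)
class Hypergraph:
    """A partition of a molecule's atoms into connected vocabulary fragments."""

    hypernodes: tuple[tuple[int, ...], ...]  # sorted atom tuples
    fragment_keys: tuple[str | None, ...]    # None marks fallback singletons
    atom_to_hypernode: np.ndarray
    is_prior: np.ndarray  # bool per hypernode

    @property
    def n_hypernodes(self) -> int:
        return len(self.hypernodes)

    def validate(self, graph: MolecularGraph) -> None:
        """Assert the partition and connectivity invariants."""
        seen: set[int] = set()
        for node in self.hypernodes:
            atoms = set(node)
            if atoms & seen:
                raise AssertionError("hypernodes overlap")
            seen |= atoms
            if len(atoms) > 1 and not nx.is_connected(_as_nx(graph).subgraph(atoms)):
                raise AssertionError("hypernode induces a disconnected subgraph")
        if seen != set(range(graph.n_atoms)):
            raise AssertionError("hypernodes do not cover all atoms")
        for i in range(graph.n_atoms):
            if i not in self.hypernodes[self.atom_to_hypernode[i]]:
                raise AssertionError("atom_to_hypernode inconsistent")


def init_vocabulary(corpus: Sequence[MolecularGraph]) -> SubgraphVocabulary:
    """Single-atom species vocabulary with molecule-level frequencies."""
    if not corpus:
        raise InputError("empty corpus")
    freq: dict[str, int] = {}
    for graph in corpus:
        for el in set(graph.elements):
            freq[el] = freq.get(el, 0) + 1
    vocab = SubgraphVocabulary(capacity=len(freq))
    for el in sorted(freq):
        vocab.add(Fragment(el, 1, freq[el]))
    return vocab


def decompose(graph: MolecularGraph, vocab: SubgraphVocabulary) -> Hypergraph:
    """Greedy non-overlapping partition of ``graph`` into vocabulary fragments.

    Fragments are scanned largest first (ties: higher frequency, then mining
    order); every unclaimed occurrence is claimed.  Leftover atoms become
    singleton hypernodes (logged fallback when their species is missing from
    the vocabulary).
    """
    claimed: set[int] = set()
    nodes: list[tuple[frozenset, str | None]] = []
    for frag in vocab.decomposition_order():
        if frag.size > graph.n_atoms - len(claimed):
            continue
        for occ in find_occurrences(frag, graph):
            if not (occ & claimed):
                claimed |= occ
                nodes.append((occ, frag.canonical_form))
        if len(claimed) == graph.n_atoms:
            break
    for i in range(graph.n_atoms):
        if i not in claimed:
            el = graph.elements[i]
            if el in vocab:
                nodes.append((frozenset([i]), el))
            else:
                log.info("species %s of %s missing from vocabulary; "
                         "singleton fallback", el, graph.smiles)
                nodes.append((frozenset([i]), None))
    nodes.sort(key=lambda item: min(item[0]))
    atom_to_hyper = np.empty(graph.n_atoms, dtype=np.intp)
    prior_keys = {f.canonical_form for f in vocab.prior_fragments}
    is_prior = np.zeros(len(nodes), dtype=bool)
    hypernodes, keys = [], []
    for h, (atoms, key) in enumerate(nodes):
        hypernodes.append(tuple(sorted(atoms)))
        keys.append(key)
        is_prior[h] = key in prior_keys
        for a in atoms:
            atom_to_hyper[a] = h
    return Hypergraph(tuple(hypernodes), tuple(keys), atom_to_hyper, is_prior)


def _merge_candidates(graph: MolecularGraph, hg: Hypergraph) -> set[str]:
    """Canonical keys of all merges of bond-adjacent hypernode pairs."""
    adjacent: set[tuple[int, int]] = set()
    for p, q in graph.bond_index:
        hp, hq = int(hg.atom_to_hypernode[p]), int(hg.atom_to_hypernode[q])
        if hp != hq:
            adjacent.add((min(hp, hq), max(hp, hq)))
    keys: set[str] = set()
    for hp, hq in adjacent:
        atoms = frozenset(hg.hypernodes[hp]) | frozenset(hg.hypernodes[hq])
        keys.add(canonical_key(atoms, graph))
    return keys


def mine_vocabulary(
    corpus: Sequence[MolecularGraph],
    capacity: int = 300,
    priors: Sequence[str] | None = DEFAULT_PRIOR_PATTERNS,
) -> SubgraphVocabulary:
    """Mine the principal-subgraph vocabulary from a molecule corpus.

    ``priors`` are SMILES-like fragment patterns force-inserted (and flagged)
    before mining starts.  Mining appends the most frequent merged candidate
    per iteration until ``capacity`` fragments exist or no candidate occurs in
    at least two molecules.  Frequencies are molecule-level indicator counts.
    """
    vocab = init_vocabulary(corpus)
    rep_cache: dict[str, tuple[MolecularGraph, frozenset]] = {}

    for pattern in priors or ():
        frag = fragment_from_pattern(pattern, is_prior=True)
        if frag.canonical_form in vocab:
            vocab.mark_prior(frag.canonical_form)
            continue
        freq = sum(contains(frag, g) for g in corpus)
        vocab.add(replace(frag, frequency=freq))
    if capacity < len(vocab):
        raise ConfigError(
            f"capacity {capacity} is smaller than the {len(vocab)} forced "
            "entries (species + priors)"
        )
    vocab.capacity = capacity

    while len(vocab) < capacity:
        candidate_keys: set[str] = set()
        for graph in corpus:
            hg = decompose(graph, vocab)
            for key in _merge_candidates(graph, hg):
                if key not in vocab:
                    candidate_keys.add(key)
                    if key not in rep_cache:
                        rep_cache[key] = graph  # any molecule producing it
        if not candidate_keys:
            break
        scored: list[tuple[int, int, str]] = []
        for key in candidate_keys:
            frag = fragment_from_pattern(key)
            freq = sum(contains(frag, g) for g in corpus)
            scored.append((freq, frag.size, key))
        # highest frequency, then larger fragment, then lexicographic key
        freq, size, key = min(scored, key=lambda t: (-t[0], -t[1], t[2]))
        if freq < 2:
            break
        vocab.add(fragment_from_pattern(key, frequency=freq))
        vocab.mining_log.append({"iteration": len(vocab.mining_log) + 1,
                                 "n_candidates": len(candidate_keys),
                                 "chosen": key, "size": size,
                                 "frequency": freq})
        log.debug("mined fragment %r (size %d, frequency %d); %d candidates",
                  key, size, freq, len(candidate_keys))
    return vocab
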