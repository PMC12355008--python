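"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package internals: molecules are
plain (elements, edges) structures, fragment canonical forms are computed by
exhaustive permutation minimization, and containment is a hand-rolled
backtracking induced-subgraph-isomorphism search.  Feasible only for the tiny
corpora the tests use (<= ~8 heavy atoms).
"""

from __future__ import annotations

from itertools import combinations, permutations


def graph_from_molgraph(graph) -> tuple[tuple[str, ...], dict]:
    """Convert a package MolecularGraph to the oracle's plain representation."""
    edges = {}
    for (p, q), order in zip(graph.bond_index, graph.bond_orders):
        edges[frozenset((int(p), int(q)))] = order
    return tuple(graph.elements), edges


def induced_fragment(elements, edges, atom_set):
    """Plain (elements, edges) of the induced subgraph on ``atom_set``."""
    atoms = sorted(atom_set)
    relabel = {a: i for i, a in enumerate(atoms)}
    sub_elements = tuple(elements[a] for a in atoms)
    sub_edges = {}
    for pair, order in edges.items():
        p, q = tuple(pair)
        if p in relabel and q in relabel:
            sub_edges[frozenset((relabel[p], relabel[q]))] = order
    return sub_elements, sub_edges


def is_connected(elements, edges) -> bool:
    n = len(elements)
    if n == 0:
        return False
    adj = {i: set() for i in range(n)}
    for pair in edges:
        p, q = tuple(pair)
        adj[p].add(q)
        adj[q].add(p)
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n


def canonical_form(elements, edges) -> str:
    """Exhaustive canonical serialization: min over all atom permutations."""
    n = len(elements)
    best = None
    for perm in permutations(range(n)):
        inv = {old: new for new, old in enumerate(perm)}
        labels = tuple(elements[old] for old in perm)
        edge_list = tuple(sorted(
            (min(inv[p], inv[q]), max(inv[p], inv[q]), order)
            for pair, order in edges.items()
            for p, q in [tuple(pair)]
        ))
        cand = (labels, edge_list)
        if best is None or cand < best:
            best = cand
    return repr(best)


def contains_fragment(mol_elements, mol_edges, frag_elements, frag_edges) -> bool:
    """Backtracking induced-subgraph-isomorphism test (fragment into molecule)."""
    nf, nm = len(frag_elements), len(mol_elements)
    if nf > nm:
        return False

    def compatible(mapping):
        used = set(mapping.values())
        f = len(mapping)
        for cand in range(nm):
            if cand in used or mol_elements[cand] != frag_elements[f]:
                continue
            ok = True
            for fi, mi in mapping.items():
                frag_order = frag_edges.get(frozenset((fi, f)))
                mol_order = mol_edges.get(frozenset((mi, cand)))
                if frag_order != mol_order:  # induced: absence must match too
                    ok = False
                    break
            if ok:
                yield cand

    def backtrack(mapping):
        if len(mapping) == nf:
            return True
        f = len(mapping)
        for cand in compatible(mapping):
            mapping[f] = cand
            if backtrack(mapping):
                return True
            del mapping[f]
        return False

    return backtrack({})


def greedy_decompose(elements, edges, vocab_entries):
    """Greedy partition mirroring the published procedure, independently coded.

    ``vocab_entries``: list of (canonical_form, size, frequency, rank) in
    mining order.  Returns a list of frozensets (the hypernode atom sets).
    """
    n = len(elements)
    order = sorted(vocab_entries, key=lambda e: (-e[1], -e[2], e[3]))
    claimed: set[int] = set()
    nodes: list[frozenset] = []
    for form, size, _freq, _rank in order:
        if size > n - len(claimed):
            continue
        occs = sorted(
            (frozenset(c) for c in combinations(range(n), size)
             if _occurrence_matches(elements, edges, c, form)),
            key=lambda s: sorted(s),
        )
        for occ in occs:
            if not occ & claimed:
                claimed |= occ
                nodes.append(occ)
    for i in range(n):
        if i not in claimed:
            nodes.append(frozenset([i]))
    return sorted(nodes, key=min)


def _occurrence_matches(elements, edges, atom_tuple, form) -> bool:
    sub_el, sub_ed = induced_fragment(elements, edges, atom_tuple)
    return is_connected(sub_el, sub_ed) and canonical_form(sub_el, sub_ed) == form


def species_frequencies(corpus):
    """Single-atom species -> molecule-level frequency."""
    species: dict[str, int] = {}
    for elements, _ in corpus:
        for el in set(elements):
            species[el] = species.get(el, 0) + 1
    return species


def candidate_scores(corpus, entries, known_forms):
    """One brute-force mining step: all merge candidates with frequencies.

    ``entries`` is the current vocabulary as (form, size, freq, rank) tuples;
    ``known_forms`` the set of forms already in the vocabulary.  Returns
    {form: (freq, size)} for every connected 2-fragment merge not yet in the
    vocabulary, with molecule-level indicator frequencies computed by
    brute-force induced-subgraph-isomorphism testing.
    """
    candidates: dict[str, tuple] = {}
    for elements, edges in corpus:
        nodes = greedy_decompose(elements, edges, entries)
        node_of = {}
        for h, atoms in enumerate(nodes):
            for a in atoms:
                node_of[a] = h
        adjacent = set()
        for pair in edges:
            p, q = tuple(pair)
            if node_of[p] != node_of[q]:
                adjacent.add((min(node_of[p], node_of[q]),
                              max(node_of[p], node_of[q])))
        for hp, hq in adjacent:
            atoms = nodes[hp] | nodes[hq]
            sub_el, sub_ed = induced_fragment(elements, edges, atoms)
            form = canonical_form(sub_el, sub_ed)
            if form not in known_forms and form not in candidates:
                candidates[form] = (sub_el, sub_ed)
    scored: dict[str, tuple[int, int]] = {}
    for form, (sub_el, sub_ed) in candidates.items():
        freq = sum(contains_fragment(el, ed, sub_el, sub_ed)
                   for el, ed in corpus)
        scored[form] = (freq, len(sub_el))
    return scored
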