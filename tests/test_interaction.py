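"""Message-passing engine tests, including an independent hand-computed trace
of the intramolecular update on a 3-atom path with 2-dimensional weights."""

import numpy as np
import pytest

from hypersolv.autodiff import Tensor, constant
from hypersolv.errors import ConfigError, InputError
from hypersolv.interaction import (InteractionParams, NetConfig,
                                   PackedMolecules, PairState,
                                   broadcast_update, cross_attention,
                                   edge_gates, intra_step, pack_molecules,
                                   pool_hypernodes, run_rounds)
from hypersolv.molgraph import FeatureProjector, featurize_molecule
from hypersolv.nn import Linear
from hypersolv.vocab import decompose, init_vocabulary


def _packed(atom_x, bond_pairs, edge_x_per_bond, u, hyper_sets, prior=None):
    """Hand-build one packed molecule (batch of one graph)."""
    atom_x = np.asarray(atom_x, dtype=float)
    n = len(atom_x)
    src, dst, edge_rows = [], [], []
    for (p, q), e in zip(bond_pairs, edge_x_per_bond):
        for a, b in ((p, q), (q, p)):
            src.append(a)
            dst.append(b)
            edge_rows.append(e)
    hyper_of_atom = np.empty(n, dtype=np.intp)
    for h, atoms in enumerate(hyper_sets):
        for a in atoms:
            hyper_of_atom[a] = h
    edge_arr = (np.asarray(edge_rows, dtype=float)
                if edge_rows else np.zeros((0, atom_x.shape[1])))
    return PackedMolecules(
        atoms=Tensor(atom_x), edges=Tensor(edge_arr),
        u=Tensor(np.atleast_2d(u)),
        src=np.array(src, dtype=np.intp), dst=np.array(dst, dtype=np.intp),
        atom_graph=np.zeros(n, dtype=np.intp),
        edge_graph=np.zeros(len(src), dtype=np.intp),
        hyper_of_atom=hyper_of_atom,
        hyper_graph=np.zeros(len(hyper_sets), dtype=np.intp),
        hyper_prior=np.array(prior if prior is not None
                             else [False] * len(hyper_sets)),
        hypernode_atoms=tuple(tuple(h) for h in hyper_sets),
        n_graphs=1,
    )


def _linear(W, b):
    lin = Linear(len(W), len(W[0]), np.random.default_rng(0))
    lin.W.data = np.asarray(W, dtype=float)
    lin.b.data = np.asarray(b, dtype=float)
    return lin


def _zero_params(d=2):
    return {name: _linear(np.zeros((d, d)), np.zeros(d))
            for name in InteractionParams.NAMES}


HAND_WEIGHTS = {
    "edge_nodes": ([[0.2, -0.1], [0.05, 0.3]], [0.01, -0.02]),
    "edge_edge": ([[-0.3, 0.1], [0.2, 0.15]], [0.0, 0.05]),
    "edge_global": ([[0.1, 0.0], [0.0, -0.2]], [0.03, 0.0]),
    "node_self": ([[0.25, 0.1], [-0.15, 0.2]], [0.0, 0.01]),
    "node_neigh": ([[0.3, -0.2], [0.1, 0.4]], [-0.01, 0.02]),
    "node_global": ([[0.0, 0.12], [0.2, 0.0]], [0.005, 0.0]),
}

ATOMS = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, -0.5]])
EDGES = [np.array([0.1, 0.2]), np.array([-0.1, 0.3])]  # bonds 0-1, 1-2
GLOBAL = np.array([0.4, -0.3])
EPS = 1e-8


def _leaky(x, slope=0.01):
    return np.where(x > 0, x, slope * x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _hand_trace():
    """Independent scalar-style evaluation of the intramolecular update."""
    W = {k: (np.asarray(w), np.asarray(b)) for k, (w, b) in HAND_WEIGHTS.items()}

    def fc(name, x):
        w, b = W[name]
        return x @ w + b

    bonds = [(0, 1), (1, 2)]
    e_new = {}
    for k, (p, q) in enumerate(bonds):
        for i, j in ((p, q), (q, p)):
            pre = (fc("edge_nodes", ATOMS[i] + ATOMS[j])
                   + fc("edge_edge", EDGES[k]) + fc("edge_global", GLOBAL))
            e_new[(i, j)] = EDGES[k] + _leaky(pre)
    v_new = np.empty_like(ATOMS)
    for i in range(3):
        neigh = np.zeros(2)
        incoming = [j for j in range(3) if (j, i) in e_new]
        denom = sum(_sigmoid(e_new[(j, i)]) for j in incoming) + EPS
        for j in incoming:
            gate = _sigmoid(e_new[(j, i)]) / denom
            neigh += gate * fc("node_neigh", ATOMS[j])
        v_new[i] = ATOMS[i] + _leaky(
            fc("node_self", ATOMS[i]) + neigh + fc("node_global", GLOBAL))
    return v_new, e_new


def _hand_state():
    side = _packed(ATOMS, [(0, 1), (1, 2)], EDGES, GLOBAL, [(0,), (1,), (2,)])
    other = _packed([[0.0, 0.0]], [], [], [0.0, 0.0], [(0,)])
    return PairState(solute=side, solvent=other)


def test_three_atom_path_matches_hand_trace():
    cfg = NetConfig(L=1, d=2, eps=EPS)
    params = {name: _linear(*HAND_WEIGHTS[name])
              for name in InteractionParams.NAMES}
    out = intra_step(_hand_state(), "solute", params, cfg)
    v_expect, e_expect = _hand_trace()
    np.testing.assert_allclose(out.solute.atoms.data, v_expect, atol=1e-10)
    for k, (i, j) in enumerate(zip(out.solute.src, out.solute.dst)):
        np.testing.assert_allclose(out.solute.edges.data[k],
                                   e_expect[(int(i), int(j))], atol=1e-10)


def test_zero_maps_make_update_identity():
    cfg = NetConfig(L=1, d=2)
    out = intra_step(_hand_state(), "solute", _zero_params(), cfg)
    np.testing.assert_array_equal(out.solute.atoms.data, ATOMS)
    # leaky(0) = 0 so edges keep their residual value exactly
    assert np.allclose(out.solute.edges.data[0], EDGES[0])


def test_isolated_atom_has_empty_neighbor_sum():
    cfg = NetConfig(L=1, d=2)
    params = {name: _linear(*HAND_WEIGHTS[name])
              for name in InteractionParams.NAMES}
    side = _packed([[1.0, 2.0]], [], [], GLOBAL, [(0,)])
    state = PairState(solute=side, solvent=_hand_state().solvent)
    out = intra_step(state, "solute", params, cfg)
    w, b = (np.asarray(a) for a in HAND_WEIGHTS["node_self"])
    wg, bg = (np.asarray(a) for a in HAND_WEIGHTS["node_global"])
    expect = np.array([1.0, 2.0]) + _leaky(
        np.array([1.0, 2.0]) @ w + b + GLOBAL @ wg + bg)
    np.testing.assert_allclose(out.solute.atoms.data, [expect], atol=1e-12)


# -- pooling --------------------------------------------------------------

def test_pooling_rules():
    side = _packed([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]], [(0, 1), (1, 2)],
                   [np.zeros(2)] * 2, [0, 0], [(0, 1), (2,)])
    state = PairState(solute=side, solvent=side)
    pooled = pool_hypernodes(state, NetConfig(L=1, d=2)).solute_hyper.data
    np.testing.assert_allclose(pooled, [[0.5, 0.5], [2.0, 2.0]])
    pooled_sum = pool_hypernodes(state, NetConfig(L=1, d=2, pooling="sum")).solute_hyper.data
    np.testing.assert_allclose(pooled_sum, [[1.0, 1.0], [2.0, 2.0]])
    pooled_max = pool_hypernodes(state, NetConfig(L=1, d=2, pooling="max")).solute_hyper.data
    np.testing.assert_allclose(pooled_max, [[1.0, 1.0], [2.0, 2.0]])


# -- attention ------------------------------------------------------------

def _attn_state(h1, h2, prior1=None, prior2=None):
    n1, n2 = len(h1), len(h2)
    solute = _packed(np.zeros((n1, 2)), [], [], [0, 0],
                     [(i,) for i in range(n1)], prior1)
    solvent = _packed(np.zeros((n2, 2)), [], [], [0, 0],
                      [(i,) for i in range(n2)], prior2)
    return PairState(solute=solute, solvent=solvent,
                     solute_hyper=Tensor(np.asarray(h1, dtype=float)),
                     solvent_hyper=Tensor(np.asarray(h2, dtype=float)))


def test_uniform_solvent_embeddings_give_uniform_rows():
    state = cross_attention(_attn_state([[1.0, 2.0], [0.5, -1.0]],
                                        [[3.0, 1.0]] * 3), NetConfig(L=1, d=2))
    np.testing.assert_allclose(state.attention.data, 1.0 / 3.0)


def test_single_hypernodes_attend_fully():
    state = cross_attention(_attn_state([[1.0, 2.0]], [[-5.0, 0.3]]),
                            NetConfig(L=1, d=2))
    np.testing.assert_allclose(state.attention.data, [[1.0]])
    np.testing.assert_allclose(state.solute_msg.data, [[-5.0, 0.3]])
    np.testing.assert_allclose(state.solvent_msg.data, [[1.0, 2.0]])


def test_two_by_two_attention_matches_direct_softmax():
    h1 = np.array([[1.0, 0.5], [-0.5, 2.0]])
    h2 = np.array([[0.3, -1.0], [1.5, 0.2]])
    state = cross_attention(_attn_state(h1, h2), NetConfig(L=1, d=2))
    scores = h1 @ h2.T
    expect_row = np.exp(scores) / np.exp(scores).sum(axis=1, keepdims=True)
    expect_col = np.exp(scores) / np.exp(scores).sum(axis=0, keepdims=True)
    np.testing.assert_allclose(state.attention.data, expect_row, atol=1e-12)
    np.testing.assert_allclose(state.attention_rev.data, expect_col, atol=1e-12)
    np.testing.assert_allclose(state.solute_msg.data, expect_row @ h2, atol=1e-12)
    np.testing.assert_allclose(state.solvent_msg.data, expect_col.T @ h1, atol=1e-12)


def test_attention_rows_sum_to_one_random(rng):
    h1 = rng.normal(size=(5, 2))
    h2 = rng.normal(size=(4, 2))
    state = cross_attention(_attn_state(h1, h2), NetConfig(L=1, d=2))
    np.testing.assert_allclose(state.attention.data.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_allclose(state.attention_rev.data.sum(axis=0), 1.0, atol=1e-6)


def test_prior_bias_shifts_attention():
    h1, h2 = [[0.1, 0.1]], [[0.1, 0.1], [0.1, 0.1]]
    cfg = NetConfig(L=1, d=2, prior_bias=2.0)
    state = cross_attention(
        _attn_state(h1, h2, prior1=[True], prior2=[True, False]), cfg)
    alpha = state.attention.data[0]
    assert alpha[0] > alpha[1]  # biased toward the prior-prior pairing


# -- edge gates -----------------------------------------------------------

def test_gate_sums_below_one_and_approach_one(rng):
    e = Tensor(rng.normal(size=(6, 3)))
    dst = np.array([0, 0, 0, 1, 1, 2])
    sums = lambda eps: np.add.reduceat(
        edge_gates(e, dst, 3, eps).data, [0, 3, 5], axis=0)
    assert np.all(sums(1e-2) < 1.0)
    assert np.all(sums(1e-8) < 1.0)
    np.testing.assert_allclose(sums(1e-12), 1.0, atol=1e-9)


# -- broadcast ------------------------------------------------------------

def _broadcast_state(gamma_msg):
    side = _packed([[2.0, 0.0], [0.0, 2.0]], [(0, 1)], [np.zeros(2)],
                   [0, 0], [(0, 1)])
    msg = Tensor(np.asarray(gamma_msg, dtype=float))
    return PairState(solute=side, solvent=side, solute_msg=msg, solvent_msg=msg)


def test_broadcast_gamma_zero_is_bitexact_identity():
    state = _broadcast_state([[9.0, 9.0]])
    out = broadcast_update(state, NetConfig(L=1, d=2, gamma=0.0))
    assert out.solute.atoms is state.solute.atoms  # untouched object


def test_broadcast_gamma_one_overwrites():
    out = broadcast_update(_broadcast_state([[0.0, 2.0]]),
                           NetConfig(L=1, d=2, gamma=1.0))
    np.testing.assert_allclose(out.solute.atoms.data, [[0.0, 2.0], [0.0, 2.0]])


def test_broadcast_convex_combination():
    out = broadcast_update(_broadcast_state([[0.0, 2.0]]),
                           NetConfig(L=1, d=2, gamma=0.5))
    np.testing.assert_allclose(out.solute.atoms.data, [[1.0, 1.0], [0.0, 2.0]])


# -- full rounds ----------------------------------------------------------

def _real_pair_state(solute_smiles="CCO", solvent_smiles="O", d=8, seed=0):
    graphs = [featurize_molecule(solute_smiles), featurize_molecule(solvent_smiles)]
    vocab = init_vocabulary(graphs)
    rng = np.random.default_rng(seed)
    proj = FeatureProjector(d, rng)
    hgs = [decompose(g, vocab) for g in graphs]
    solute = pack_molecules([graphs[0]], [hgs[0]], proj)
    solvent = pack_molecules([graphs[1]], [hgs[1]], proj)
    return PairState(solute=solute, solvent=solvent), rng


def test_run_rounds_zero_rounds_is_identity():
    state, rng = _real_pair_state()
    params = InteractionParams(8, 0, rng)
    out = run_rounds(state, params, NetConfig(L=0, d=8))
    assert out.round == 0
    np.testing.assert_array_equal(out.solute.atoms.data, state.solute.atoms.data)


def test_run_rounds_counts_and_retains_attention():
    state, rng = _real_pair_state()
    params = InteractionParams(8, 4, rng)
    out = run_rounds(state, params, NetConfig(L=4, d=8, gamma=0.2))
    assert out.round == 4
    assert out.attention is not None
    np.testing.assert_allclose(out.attention.data.sum(axis=1), 1.0, atol=1e-6)


def test_gamma_zero_equals_pure_intra_stack():
    state, rng = _real_pair_state()
    params = InteractionParams(8, 3, rng)
    cfg = NetConfig(L=3, d=8, gamma=0.0)
    full = run_rounds(state, params, cfg)
    solo = state
    for layer in range(3):
        solo = intra_step(solo, "solute", params.rounds[layer], cfg)
    np.testing.assert_array_equal(full.solute.atoms.data, solo.solute.atoms.data)


def test_permutation_equivariance():
    """Relabeling atoms permutes embeddings; attention is permutation-invariant
    up to the induced hypernode permutation."""
    state, rng = _real_pair_state("CCO", "O", d=6)
    params = InteractionParams(6, 2, rng)
    cfg = NetConfig(L=2, d=6, gamma=0.3)
    out = run_rounds(state, params, cfg)

    perm = np.array([2, 0, 1])  # new position of each original atom
    side = state.solute
    inv = np.argsort(perm)
    perm_side = PackedMolecules(
        atoms=Tensor(side.atoms.data[inv]), edges=side.edges,
        u=side.u, src=perm[side.src], dst=perm[side.dst],
        atom_graph=side.atom_graph, edge_graph=side.edge_graph,
        hyper_of_atom=side.hyper_of_atom[inv],
        hyper_graph=side.hyper_graph, hyper_prior=side.hyper_prior,
        hypernode_atoms=tuple(tuple(perm[a] for a in h)
                              for h in side.hypernode_atoms),
        n_graphs=1,
    )
    out_p = run_rounds(PairState(solute=perm_side, solvent=state.solvent),
                       params, cfg)
    np.testing.assert_allclose(out_p.solute.atoms.data,
                               out.solute.atoms.data[inv], atol=1e-10)
    np.testing.assert_allclose(out_p.attention.data, out.attention.data,
                               atol=1e-10)


def test_cross_attention_requires_pooling():
    state, _ = _real_pair_state()
    with pytest.raises(InputError):
        cross_attention(state, NetConfig(L=1, d=8))


def test_config_validation():
    with pytest.raises(ConfigError):
        NetConfig(gamma=1.5)
    with pytest.raises(ConfigError):
        NetConfig(eps=0.0)
    with pytest.raises(ConfigError):
        NetConfig(pooling="median")
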