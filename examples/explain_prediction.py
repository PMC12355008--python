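"""Extract the core interacting substructures behind one prediction.

Trains a small model on synthetic pairs with planted hydroxyl/carboxyl
interaction rules, then explains a held-out pair: each hypernode's
transmission probability says how much of it the information bottleneck keeps;
atoms scoring above their molecule's mean form the predicted core.  On this
data the planted motif atoms should rank above the rest.
"""

from hypersolv import (GibConfig, ModelConfig, NetConfig, SyntheticSpec,
                       TrainConfig, explain, generate_pairs, mine_vocabulary,
                       recovery_metrics, split_dataset, train)

spec = SyntheticSpec(n_pairs=1000, seed=3)
pairs, annotations = generate_pairs(spec)
corpus, seen = [], set()
for p in pairs:
    for g in (p.solute, p.solvent):
        if g.smiles not in seen:
            seen.add(g.smiles)
            corpus.append(g)
vocab = mine_vocabulary(corpus, capacity=30)
train_set, valid_set, test_set = split_dataset(pairs, "random", seed=3)

model, _ = train(
    train_set, vocab,
    ModelConfig(net=NetConfig(L=2, d=32, gamma=0.2), gib=GibConfig(beta=1e-2),
                readout_steps=2, ffn_width=64, seed=0),
    TrainConfig(batch_size=128, lr_init=1e-3, patience=60, max_epochs=60,
                seed=0),
    valid_pairs=valid_set)

by_key = {(a.solute_smiles, a.solvent_smiles): a for a in annotations}
pair = next(p for p in test_set
            if by_key[(p.solute.smiles, p.solvent.smiles)].active_rules)
truth = by_key[(pair.solute.smiles, pair.solvent.smiles)]

result = explain(pair, model)
print(f"solute {pair.solute.smiles} in solvent {pair.solvent.smiles} "
      f"(label {pair.label:+.2f} kcal/mol)")
for name, mol, motif_atoms in (("solute", result.solute, truth.solute_motif_atoms),
                               ("solvent", result.solvent, truth.solvent_motif_atoms)):
    print(f" {name}: core atoms {list(mol.core_atoms)} "
          f"(planted motif atoms {list(motif_atoms)})")
    print(f"   atom scores: "
          + " ".join(f"{s:.2f}" for s in mol.atom_scores))

annos = [by_key[(p.solute.smiles, p.solvent.smiles)] for p in test_set[:40]]
for mode in ("blend", "gates"):
    metrics = recovery_metrics([explain(p, model, mode=mode)
                                for p in test_set[:40]], annos)
    print(f"recovery over 40 test pairs ({mode}): "
          f"ranking AUC {metrics['auc_mean']:.2f}, "
          f"core recall {metrics['core_recall']:.2f}")
# AUC 1.0 would mean every planted motif atom outranks every other atom.
# Resolution is limited by hypernode granularity (all atoms of a hypernode
# share one score) and grows with dataset size and training length; see
# docs/methods.md for what the gates can and cannot separate.
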