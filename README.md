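# hypersolv

Explainable prediction of solvation Gibbs free energies (ΔG_solv, kcal/mol)
for solute–solvent pairs, from SMILES strings alone.

Predicting how much free energy a molecule gains by dissolving requires
modelling the *pair*: dissolution replaces intramolecular contacts with
solute–solvent interactions such as hydrogen bonds, so neither molecule's
embedding alone suffices.  `hypersolv` encodes each molecule as a
**hypergraph of mined fragments** (hydroxyls, carboxyls, backbone pieces …
found by frequency-based merging over the training corpus), exchanges
information between the two molecules through **co-attention between
hypernodes**, and passes the result through a **graph information
bottleneck** that keeps only the substructures that matter — so every
prediction comes with per-atom contribution scores.

## Model

For a pair (G₁, G₂) with label Y, each of L rounds performs:

- intramolecular updates (residual, gated):
  e′ᵢⱼ = eᵢⱼ + τ(FC(vᵢ+vⱼ) + FC(eᵢⱼ) + FC(u)),
  êᵢⱼ = σ(e′ᵢⱼ) / (Σ_{j′∈N(i)} σ(e′ᵢⱼ′) + ε),
  v′ᵢ = vᵢ + τ(FC(vᵢ) + Σⱼ êᵢⱼ ⊙ FC(vⱼ) + FC(u));
- pooling of atoms into hypernode embeddings H_sub;
- co-attention αᵢⱼ = softmaxⱼ(H₁ᵢ · H₂ⱼ) with attended messages in both
  directions;
- broadcast v ← (1−γ) v + γ · (hypernode message), where γ is the
  intermolecular update rate (γ = 0 turns exchange off).

The final hypernode embeddings are gated by learned transmission
probabilities pᵢ = σ(FC(Hᵢ)) with a concrete (Gumbel-sigmoid) relaxation and
moment-matched Gaussian noise, zᵢ = λᵢHᵢ + (1−λᵢ)εᵢ, trained with

    L = MSE(ŷ, Y) + β · (I-bound(H₁) + I-bound(H₂)),

where the analytic bound −½log A + A/2m + ‖B‖²/2m penalizes transmitted
information.  The prediction head reads set2set summaries of the gated
hypernodes (solute first — the order encodes the asymmetric roles).
`docs/methods.md` has the full account, defaults, and limitations.

## Worked example

Real solvation benchmarks need external data, so the package ships a
synthetic generator whose labels follow planted motif-interaction rules
(hydroxyl×hydroxyl −3.0, carboxyl×amine −2.5, fluoro×hydroxyl +1.8 kcal/mol,
plus 0.3 kcal/mol noise) — ground truth for both accuracy and explanations.

```bash
python examples/train_and_predict.py
```

prints (a few minutes on one core):

```
1000 pairs; label sd = 1.97 kcal/mol
vocabulary: 30 fragments from 159 molecules
trained 60 epochs; best valid MAE 0.830 kcal/mol
test: MAE 0.771  RMSE 0.953 kcal/mol  R^2 0.765  (n=100)
```

The model recovers most of the planted signal (label sd 1.97 kcal/mol vs a
0.3 kcal/mol noise floor); the residual gap is the deliberately short
training budget of the example — the study-scale run in
`scripts/acceptance.py` (2,000 pairs) reaches R² ≈ 0.9.  Other
examples: `examples/mine_vocabulary.py` (fragment mining and hypergraph
decomposition) and `examples/explain_prediction.py` (per-atom contribution
scores against planted ground truth).

The same pipeline is exposed as a thin CLI:

```bash
hypersolv simulate -o data/            # pair table + ground truth
hypersolv mine-vocab -d data/pairs.csv -o vocab.jsonl
hypersolv train -d data/pairs.csv --vocab vocab.jsonl -o run/
hypersolv explain -d data/pairs.csv --vocab vocab.jsonl \
    --checkpoint run/checkpoint.npz -o explanations/
```

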