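# molhgt

Pharmacophore-aware heterogeneous graph transformer for molecular property
prediction.

## The problem

Most molecular graph neural networks treat a molecule as a homogeneous graph
of atoms and bonds. That view misses two kinds of chemistry that often drive
a property: the *functional substructures* (pharmacophores) a molecule is
built from, and the *reaction chemistry* that links them. `molhgt`
implements a multi-view heterogeneous graph representation and a typed
attention message-passing network over it, for people benchmarking
property-prediction models on MoleculeNet-style CSV task tables (one SMILES
column, one column per task, blanks for missing labels).

## The representation and model

Each molecule (SMILES, canonicalized so any spelling yields the same graph)
becomes three coupled views:

* **atom view** G^α — atoms with bond edges (every bond appears as two
  directed edges);
* **pharm view** G^β — BRICS fragments as nodes; each cleaved BRICS bond
  becomes a pair of directed *reaction* edges whose features are the ordered
  one-hot pair of the 16 BRICS link-rule classes;
* **junction view** G^γ — atoms and fragments together, with membership
  edges between each atom and its owning fragment
  (N^γ = N^α + N^β, M^γ = 2·N^α).

Each view is processed independently:

1. **Typed attention embedding.** With per-type projections
   [Q, K, V] = X·[W^Q, W^K, W^V] and a learnable type-mixing matrix Ω^p per
   head, a query's context is scored as
   `Attention(Q,K,V) = Σ_p Ω^p σ(Q^p K^pT / √d_k) V^p`
   (σ = softmax over the keys of each type). Nodes attend over themselves
   and their incoming edges; edges over themselves and their endpoints.
   Heads are concatenated into hidden matrices H(X_V), H(X_E) of width d.
2. **Message passing** of depth T with residual updates
   H^t = H^{t-1} + M^t. The first step seeds node messages with the sum of
   incoming edge hiddens (M_V^1 = Σ H(X_e)) and edge messages with the
   source-node hidden. Later steps attend each node's query over its
   incoming edge messages, and update edge messages through
   `Linear(M_E^1 + H^t(source) − H^{t-1}(reverse edge))`.
3. **Readout and fusion.** A GRU consumes each view's node hiddens in
   canonical order; its final state is the view vector Z_p. Views fuse
   through a scalar attention gate
   `ReadOutAttention(X, Y) = σ(X·Y^T/√d_k)·X`: first
   Z_γβ = ReadOutAttention(Z_γ, Z_β), then Z = ReadOutAttention(Z_α, Z_γβ),
   and a linear head maps Z to one score per task. Seven ablation variants
   (α, β, γ, βα, γα, βγ, γαβ) restrict the views/fusion order.

Evaluation follows the standard benchmark protocol: 0.8/0.1/0.1
train/valid/test splits, random or Bemis–Murcko scaffold based, k-fold
cross-validation realized as independently seeded splits with replicate
training runs; ROC-AUC (%) for classification, RMSE for regression.

No deep-learning framework is required: the network (typed attention, GRU,
Adam) runs on NumPy via a small reverse-mode autodiff engine included in the
package; chemistry goes through RDKit.

## Worked example

```python
from molhgt import HGTRegressor, generate_toy_dataset, rmse

table = generate_toy_dataset(32, seed=7)          # synthetic, BRICS-cleavable
est = HGTRegressor(hidden_dim=16, num_heads=2, depth=2, dropout=0.0,
                   learning_rate=5e-3, batch_size=8, max_epochs=30,
                   random_state=0)
est.fit(table.smiles, table.labels[:, 0])
pred = est.predict(table.smiles)
print(f"train RMSE: {rmse(pred, table.labels[:, 0]):.3f}")
print(f"first/last epoch loss: {est.loss_history_[0]:.3f} "
      f"/ {est.loss_history_[-1]:.3f}")
```

prints (labels are `#cleaved BRICS bonds + 0.1 × #aromatic rings`, so the
model is learning a deterministic structural count):

```
train RMSE: 1.144
first/last epoch loss: 1.084 / 0.217
```

i.e. after 30 epochs the mean standardized squared error has dropped from
1.08 (roughly predicting the mean) to 0.22, an RMSE of 1.14 label units on
labels spanning roughly 1–9; longer schedules drive it much lower (the
acceptance script's memorization run reaches train RMSE below 0.05).

The same estimators drive the CLI:

```bash
molhgt toydata --n 100 --seed 0 --out toy.csv
molhgt cv --data toy.csv --task-type regression --split scaffold \
       --folds 5 --replicates 1 --seed 0 --out runs/cv
molhgt featurize --input toy.csv --output graphs.jsonl
```

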