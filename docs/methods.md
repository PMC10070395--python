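# Methods

## Graph construction

A SMILES string is parsed with RDKit, reduced to its largest covalent
component if it contains dots (salts and solvents are not the pharmacophore
carrier; a warning is logged), and round-tripped through canonical SMILES so
that atom indices are canonical: any spelling of one structure produces a
bit-identical graph. Hydrogens stay implicit.

BRICS decomposition breaks all retrosynthetically cleavable bonds
simultaneously; the fragments (connected components of the remaining bond
graph) become pharm-view nodes, ordered by their smallest member-atom index.
Each cleaved bond records the BRICS link-rule class (1–16) on both sides;
RDKit's `7a`/`7b` sub-labels both map to class 7. A molecule with no
cleavable bond has one fragment and an edgeless pharm view, which the model
tolerates (empty attention contexts contribute zero messages).

Features follow the de-facto standard of directed-bond message-passing
models: atoms — element one-hot over {B,C,N,O,F,Si,P,S,Cl,Br,I,other},
heavy-degree 0–5, formal charge {−2..2,other}, chiral tag, H-count 0–4,
hybridization, aromaticity flag, mass/100 (41 dims); bonds — order one-hot,
conjugation, ring, stereo (12 dims). A fragment's feature is the sum of its
member-atom vectors plus two counts (member atoms, internal bonds);
permutation-invariant and dimension-stable. Reaction edges carry the ordered
pair of 16-way rule one-hots (the reverse edge swaps the halves). Junction
edges carry a constant one-slot type vector; junction node features are the
atom/fragment vectors zero-padded to a common width.

Junction membership links *every* atom to its owning fragment by default,
which keeps the junction view informative for single-fragment molecules; a
`junction_membership="cleavage"` option restricts to cleavage-site atoms.

## Model

Widths: hidden size d, n heads, d_k = d/n. For each view, the initial
embedding gives every node the typed-attention mixture of itself and its
incoming edges, and every edge the mixture of itself and its two endpoints.
Per head and context type p there are projections W^Q, W^K, W^V and a
type-mixing matrix Ω^p (d_k × d_k); scores are scaled by 1/√d_k and
normalized by softmax *within* each type's key set, so a singleton context
(a node's self, or an endpoint whose type is unique on that edge) receives
weight 1 and needs no score. The concatenated heads pass through one output
matrix per stack (W_V^o for nodes, W_E^o for edges); two consecutive linear
maps collapse into one, so no separate per-head output matrix is kept.

Message passing runs T steps with residual updates H^t = H^{t-1} + M^t for
both nodes and edges. Step 1 seeds M_V with the sum of incoming edge hiddens
and M_E with the source-node hidden (stored as M_E^1). Steps t > 1 score
each node's query H^{t-1}W^Q against its incoming edge messages M_E^{t-1}W^K;
the value operand defaults to the node's own hidden state H^{t-1}W^V
(`value_source="node"`, the literal reading of the update rule — under
softmax the weights then sum to 1 and the message reduces to H^{t-1}W^V·Ω
wherever a node has incoming edges, and to 0 where it has none). The
documented alternative `value_source="message"` attends over the edge
messages themselves. Edge messages update as
Linear(M_E^1 + H^t(source) − H^{t-1}(reverse edge)); subtracting the
reverse direction prevents immediate echo, as in directed-bond MPNNs.

Readout is a GRU over the view's node hiddens in canonical node order
(atoms by canonical index; fragments by smallest member atom; junction:
atoms then fragments); the final hidden state — not a pooling of outputs —
is the view vector. Fusion uses the scalar gate σ(X·Y^T/√d_k)·X with σ the
logistic sigmoid: a softmax over a single scalar would be constantly 1 and
reduce the gate to the identity, so the sigmoid is the non-degenerate
reading. The full model computes Z_γβ = gate(Z_γ, Z_β) then
Z = gate(Z_α, Z_γβ); the seven ablation variants either pass one view
through or apply the gate in the stated order ("x aggregated to y" =
gate(Z_y, Z_x)). A single linear layer maps Z to one raw score per task;
classification probabilities apply a sigmoid at evaluation time.

## Training

Parameters initialize reproducibly from a seed: Glorot-uniform projections,
orthogonal GRU recurrent matrices, zero biases. Adam (default lr 1e-3,
optional cosine decay) minimizes the masked multi-task loss — mean
binary cross-entropy on raw scores, or mean squared error, over observed
entries only; fully-masked batches contribute zero. Gradients are clipped to
global norm 5. Regression targets are standardized per task during training
and mapped back at prediction, so reported RMSE is on the label scale.
Dropout applies to hidden states and messages during training only. With a
validation set, training early-stops on the validation metric (macro
ROC-AUC / negative RMSE) with configurable patience and restores the best
parameters. An optional `tol` stops training once the epoch loss falls
below it.

All tensor computation runs on a small reverse-mode autodiff engine over
float64 NumPy arrays written for this package (elementwise ops, matmul,
reductions, gather/segment-sum, the pointwise nonlinearities), verified
against finite differences in the test suite. Attention over a graph is
evaluated with segment operations; a per-segment max is subtracted before
exponentiation for numerical stability.

## Evaluation protocol

Splits are 0.8/0.1/0.1 with quotas ⌊0.8n⌋/⌊0.1n⌋/rest. Random splits
shuffle with a seeded generator and cut contiguously. Scaffold splits group
by Bemis–Murcko scaffold SMILES (atom types kept, chirality dropped), order
groups largest-first with seeded tie-breaking, and fill train, then valid,
then test without dividing a group; an indivisible dominant group can leave
valid/test empty, which is flagged as degenerate rather than an error.
Because scaffold groups are not natural folds, "k-fold" cross-validation is
realized as k independently seeded splits (seed + fold index), each trained
`replicates` times from distinct initialization seeds; test metrics
aggregate as mean ± sample standard deviation. Classification reports the
macro-average ROC-AUC (Mann–Whitney pair statistic; tasks with a
single observed class in a fold are skipped with a warning) in percent;
regression reports RMSE.

## Synthetic benchmark

`generate_toy_dataset` assembles each molecule from 2–4 building blocks
(ethyl/propyl/isobutyl, phenyl, benzyl, ethoxymethyl) joined by couplings
that BRICS reliably cleaves (amide, ester, ether, sulfonamide), so every
generated molecule has a multi-fragment pharm view. The regression label is
`#cleaved BRICS bonds + 0.1 × #aromatic rings`; the classification label is
amide presence — both recomputed from the assembled structure, so they are
deterministic functions of the graph that a correct model can in principle
learn exactly. What the generator does *not* emulate: real assay noise,
activity cliffs, heavy-atom diversity beyond C/N/O/S, charged species,
stereochemistry-dependent labels, or label imbalance; passing tests on it
demonstrates that the pipeline is implemented correctly and can learn
structure-determined signals, not that it reaches benchmark accuracy on
experimental data.

## Numerical and scale choices

Acceptance-style checks compare against independent oracles at 1e-6 (scalar
unrollings on ≤4-node/width-≤4 instances) or exactly (bit-identity for
canonicalization, determinism and view isolation). The memorization check
trains the full fusion model on the 32-molecule synthetic regression set
with `value_source="message"` — under the literal node-valued update, nodes
receive no neighbor information after the first step and training stalls
around a saturation plateau well above exact memorization, whereas the
conventional attention values memorize the set to numerical zero. Widths
around 16–32 with minibatches of 8 are the stable optimization regime for
this architecture: the scalar fusion gate is a sigmoid of a dot product
that grows with d, so large widths saturate the gate early and can stall
training; a warmup/hold/decay learning-rate schedule avoids the early and
late instabilities. Cross-validation runs in the acceptance script use 96 molecules,
3 folds, and ~12 epochs at width 16: large enough for a clearly
above-chance ROC-AUC and sub-label-scale RMSE, small enough to run on one
CPU in minutes. Exact reproducibility holds for fixed seeds because all
randomness (init, shuffling, dropout) derives from seeded generators and
the engine is float64 throughout.

## Known limitations

* The literal `value_source="node"` update makes node states independent of
  neighbors after the first propagation step (information still flows
  through edge states and the readout); the `"message"` option is the
  conventional alternative.
* Attention contexts cover incoming edges and edge endpoints only — there
  is no node–node attention within a view.
* The GRU readout imposes an arbitrary (if canonical) sequence order on an
  unordered node set.
* Multi-component SMILES keep only the largest component; organometallic
  and isotopically labelled species reduce to the "other" feature slots.
* Training is CPU-bound Python/NumPy; it is meant for method study and
  desk-scale benchmarks, not for full MoleculeNet sweeps.
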