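# Methods

## Problem and model

`rsmanet` predicts the binding affinity of an RNA–small-molecule pair as
pKd, the negative base-10 logarithm of the dissociation constant in molar.
Input is an RNA sequence over {A, C, G, U} with p nucleotides and a SMILES
string with q heavy atoms; output is a single real ŷ.

Each entity is encoded from two complementary views at fine granularity
(per nucleotide, per atom):

- **RNA graph view.** The contact graph connects nucleotide pairs whose
  nearest heavy atoms lie within 8 Å (supplied by an external secondary
  structure/contact predictor through a provider interface; see below).
  Nucleotides are embedded into R^d and updated by a multi-head graph
  attention network (GAT). For node i with neighbourhood N(i), the
  attention logit against n ∈ N(i) ∪ {i} is
  LeakyReLU(aᵀ[W_d h_i, W_d h_n]); softmax over that support gives α_in,
  and the update is ReLU(Σ_n α_in W_a h_n). Self-loops are required because
  the update references α_ii. Head outputs are averaged so width stays d.
- **RNA sequence view.** Per position the nucleotide embedding is averaged
  with a linear projection of a pretrained RNA-language-model embedding;
  three same-padded 1-D convolutions (kernel sizes 7, 11, 15) run over the
  result and are averaged into E, followed by
  R^s = ReLU(W_c2 ReLU(W_c1 E)). Zero padding keeps length p for every
  branch.
- **Molecule graph view.** Standard GCN over the heavy-atom graph with
  self-connected adjacency Ã:
  M^{g,l} = ReLU(D̃^{-1/2} Ã D̃^{-1/2} M^{g,l-1} W_e^l), starting from
  per-atom chemical features (element, degree, charge, radicals,
  hybridization, aromaticity, hydrogen count; 30 dimensions).
- **Molecule sequence view.** Atomic-level SMILES tokens (bracket atoms and
  two-letter elements as single tokens) with learned positional embeddings
  pass through L Transformer blocks (multi-head scaled dot-product
  attention, residual + layernorm, position-wise FFN, residual +
  layernorm). The atom mask then selects the q heavy-atom rows, so M^s is
  exactly q × d and pooling averages atom rows only.

**Cross-fusion.** Graph- and sequence-view token matrices are stacked with
learned segment embeddings, R^c = [R^g + S^g; R^s + S^s] (2p × d) and
M^c = [M^g + S^g; M^s + S^s] (2q × d). Each fusion block runs two
perspectives *in parallel from the block's inputs*: RNA queries against
molecule keys/values (score matrix 2p × 2q, containing the four view-pair
blocks [gg, gs; sg, ss]) and the reverse (2q × 2p), each followed by head
concatenation, residual + layernorm, FFN, residual + layernorm. After L
blocks, segment-wise means give R̄^{c,g}, R̄^{c,s}, M̄^{c,g}, M̄^{c,s}; all
post-softmax score matrices are kept for interpretability.

**Prediction head.** R = MLP([mean(R̄^g, R̄^{c,g}), mean(R̄^s, R̄^{c,s})]),
M analogous, ŷ = MLP([R, M]); each MLP is two layers with ReLU and dropout
after the first. Training minimizes mean squared error with Adam.

## Tunable parameters

| parameter | default | note |
|---|---|---|
| hidden width d | 128 | published setting; desk-scale runs use 32 |
| learning rate | 5e-4 | published setting (Adam) |
| batch size | 16 | published setting |
| dropout | 0.2 | published setting; in the head MLPs |
| weight decay | 1e-7 | published setting (L2 inside Adam) |
| CNN kernels | 7, 11, 15 | published setting; odd so length is preserved |
| GAT layers / heads | 2 / 4 | unstated upstream; package default |
| LeakyReLU slope | 0.2 | customary for this architecture family |
| GCN layers | 2 | package default |
| Transformer blocks / heads | 2 / 4 | package default |
| fusion blocks / heads | 1 / 4 | package default, kept small |
| epochs / patience | 100 / 20 | early stop on validation MSE when a validation set is given |
| classification threshold | 4.0 pKd | binder / non-binder cut |
| leakage thresholds | 0.8 / 0.8 | Tanimoto and RNA identity; assumptions, see below |

## Design choices where the design was open

- **No deep-learning framework dependency.** The network runs on a small
  reverse-mode autodiff core over NumPy float64 (`rsmanet._tensor`),
  giving bit-reproducible CPU results and exact control over every
  operation the tests oracle-check.
- **Per-sample batching.** Variable-length RNAs and molecules are processed
  one pair at a time with the minibatch loss averaged before a single
  backward pass. Predictions are therefore exactly batch-size independent;
  key-side attention masks exist at the op level and are tested, but the
  training path never needs padding.
- **Transformer details.** The per-head scaling is 1/sqrt(d_head); the
  position-wise FFN uses two distinct affine maps with ReLU between;
  residual connections and layer normalization are kept in both the
  self-attention and cross-fusion blocks (post-norm). Positional
  information enters through a learned position table (SMILES order
  matters).
- **Head averaging in the GAT** (rather than concatenation) keeps every
  layer's width at d. Layer/head counts are configuration, not claims.
- **Parallel perspective updates in fusion.** Both perspectives read the
  block's inputs; sequential updating would leak one perspective's update
  into the other. Perspectives have separate parameter sets.
- **Pooling M^s over atom tokens only** is one consistent reading of a
  q × d sequence embedding; non-atom tokens still participate in attention.
- **Dimension reconciliation.** The pretrained-embedding width d_pre is
  provider-defined; a learned linear map brings it to d before the
  position-wise average with the nucleotide embedding.
- **Attention collapsing for interpretability** averages post-softmax
  scores over blocks, heads, key positions, and the two view segments
  (graph-view row j and sequence-view row p + j). This flat mean is the
  single interpretation implemented; rankings are invariant to uniform
  rescaling and ties break by ascending position.
- **Stratified CV on a continuous target** uses 10 quantile bins dealt
  round-robin. The all-blind mode keeps only pairs whose RNA and molecule
  fall in the same fold; excluded pairs are marked fold −1.
- **Leakage filtering** removes training molecules with Morgan-fingerprint
  Tanimoto ≥ 0.8 to any test molecule and training RNAs with global
  alignment identity ≥ 0.8 (unit match, zero mismatch/gap, normalized by
  the longer length). Both thresholds are package assumptions exposed in
  the API, not values taken from upstream work.
- **Duplicate (rna_id, mol_id) pairs are rejected** rather than averaged;
  how multi-measurement pairs should collapse is not defined upstream.
- **DNA letter T is normalized to U** with a logged warning, since real
  sources mix alphabets; any other non-ACGU character is an error. RNAs
  longer than 512 nt are rejected rather than truncated.

## External models as providers

Contact-map prediction and pretrained nucleotide embeddings are consumed
through provider interfaces, never reimplemented: a file-backed provider
loads precomputed matrices for real use, and deterministic stand-ins serve
tests and synthetic runs. The mock embedding provider is synthetic: each
row comes from a PCG64 stream keyed by a BLAKE2b hash of (seed, sequence,
position), bit-reproducible across processes. Synthetic contact maps place
backbone contacts (|i − j| = 1) plus seeded random symmetric long-range
contacts at density 0.05.

## Synthetic data: what it emulates and what it does not

The generator mirrors the *structure* of a curated RNA–ligand affinity
collection at desk scale: 30 RNAs / 40 molecules / 120 pairs by default
(larger for specific experiments), sequences 20–60 nt (real collections
reach ~300 nt; desk-scale lengths keep CPU budgets while exercising every
code path), molecules assembled from a small fragment grammar and validated
by RDKit, and labels

    pKd = 2.0 + 4.0·GC_fraction + 3.0·aromatic_fraction + N(0, 0.3)

spanning roughly 2–9 and straddling the 4.0 classification threshold. The
planted signal uses only features both encoder families can see, so
end-to-end recovery is a fair test of the architecture and plumbing.
Passing these tests shows the implementation learns what it should and
nothing it should not (the permutation control); it says nothing about
predictive accuracy on real RNA–ligand physics, which the synthetic
generator deliberately does not model.

## Numerical notes

- Everything is float64; softmax subtracts the row max; masked positions
  get probability exactly 0 and no gradient; a softmax row with empty
  support is an error (cannot occur with self-loops).
- Layer normalization uses ε = 1e-5.
- Glorot-uniform initialization throughout, seeded; embeddings N(0, 0.02).
- Adam uses β = (0.9, 0.999), ε = 1e-8; weight decay is the classic L2
  term added to the gradient.
- Checkpoints (single `.npz`) store config, parameters, optimizer moments,
  and the dropout RNG state; reload reproduces predictions bit-for-bit.
- Degenerate inputs: empty pair tables, single-class labels, constant
  targets, zero-atom token streams, and shape mismatches all raise typed
  errors with the offending record named.

## Experiment sizes

Desk-scale protocols (in `rsmanet.experiments`, reused by the acceptance
script): overfit capacity on 8 pairs (d = 32, dropout 0, ≤ 500 steps,
target MSE < 0.01); planted-signal recovery on 500 pairs (noise σ = 0.3,
80/20 split, 10 epochs, held-out PCC with a label-permutation control);
stratified 3-fold CV on 120 pairs. These sizes are the package's standard
self-check conditions.

## Known limitations

- CPU-only and O(p² + pq) per pair in attention; hundreds of epochs on
  thousands of long RNAs would need the usual framework/GPU route.
- The SMILES token vocabulary covers the common organic subset plus
  frequent bracket atoms; rare bracket tokens map to `<unk>` (their atom
  positions are still tracked exactly).
- The independent-test filter reports what it removed; with thresholds
  other than the upstream (unpublished) ones, removal counts will differ
  from published ones and no claim is made otherwise.
- Attention-based importance is a model diagnostic, not a binding-site
  predictor; rankings are only as meaningful as the trained model behind
  them.
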