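# Methods

## The model

A molecule enters the model twice: as a SMILES token sequence and as a
heavy-atom graph. The two views are joined by an order-preserving alignment
and trained end-to-end on a property label.

**Parsing and featurization.** SMILES are parsed with RDKit without
canonicalization, so atom index equals order of first appearance in the
string — alignment correctness depends on this. Explicit and isotopic
hydrogens are removed after sanitization. Node features concatenate four
per-atom encodings: element one-hot over a configurable list (default C, N,
O, S, F, Cl, Br, I, P, B, plus an "other" slot), signed formal charge,
hybridization one-hot (S, SP, SP2, SP3, SP3D, SP3D2, UNSPECIFIED) and
chirality-tag one-hot (4 RDKit categories); default width 23. Edge features
concatenate bond-type (SINGLE/DOUBLE/TRIPLE/AROMATIC — aromatic bonds are a
category of their own, no kekulization, so lowercase aromatic tokens stay
consistent with the graph) and bond-direction one-hots; every undirected
bond is stored as two directed pairs with identical features. The category
vocabularies are configuration, not claims about any external model's
encoding; they are serialized with every run.

**Tokenization.** Greedy longest-match against a vocabulary with a
SMILES-aware regex fallback (bracket atoms, two-letter halogens, `%nn` ring
closures, structural symbols). The shipped default vocabulary is
regex-derived; a user vocabulary file (one token per line, id = line number)
overrides it. Tokens are classified by scanning for element symbols
(two-letter first, ignoring chirality markers, charges, isotope digits, and
H-counts inside brackets): HEAVY_ATOM with multiplicity m when m non-hydrogen
elements occur, HYDROGEN_ONLY when the only element is H, STRUCTURAL
otherwise, SPECIAL for begin/end/pad/unknown. Out-of-vocabulary spans keep
their literal string and true class but carry the unknown id, so alignment
still works when the vocabulary is smaller than the chemistry.

**Alignment.** A single left-to-right walk assigns each heavy-atom token of
multiplicity m the next m unassigned node indices; a multiplicity-m token
broadcasts one embedding to m consecutive nodes (order- and
dimension-preserving; no sub-token structure is invented). The element
symbol of every token is checked case-insensitively against the node it
maps to; disagreement raises immediately, because it means tokenizer and
parser drifted apart. Begin/end tokens receive attention 0 by default
(configurable) — the mask is defined over chemistry tokens.

**Fusion and prediction.** The encoder consumes the token ids under the
heavy-atom attention mask (masked tokens are excluded as keys, so
structural and padding tokens never influence the embeddings that get
fused). Mapped token embeddings are concatenated onto node features; a
linear projection reduces `d_node + d_L` to the GNN hidden width; a stack of
GCN or GATv2 layers updates node states; mean pooling over nodes
(configurable to sum/max) feeds a dense layer + ReLU + dropout + linear
head. Classification uses a single logistic output. The language-only
ablation pools the masked token embeddings (mean over attention-1
positions — the begin-token alternative is not used) straight into the head;
the graph-only ablation never builds an encoder. GCN consumes no edge
features (its cited form is nodes-only); GATv2 adds a learned edge-feature
embedding into the attention score. Both are toggles.

## Training protocol

Adam, batch 16, 50 epochs and 32-bit parameters by default. Two parameter
groups: the encoder at `lr_lang`, everything else at `lr_coder`, both scaled
per epoch by `min(e/w, sqrt(w/e))` (linear warmup over `w` epochs, then
inverse-square-root decay; continuous and maximal at `e = w`). The training
loss is the literal reported metric — RMSE, MAE or clamped BCE — with MSE
available behind a flag. Regression targets are z-scored per training fold
and predictions un-scaled before any metric is computed; this stabilizes
small-data training and changes no reported number. The epoch with the best
validation selection metric (lowest RMSE/MAE or highest ROC-AUC) supplies
the final weights. Layer freezing excludes the embedding tables from
gradient updates unconditionally — the convention for fine-tuning a
pretrained encoder, whose embeddings are part of the pretrained artifact —
and additionally freezes the first n transformer blocks (all blocks frozen
also freezes the final layer norm, so only post-encoder parameters can
move). The random-search hyperparameter sampler draws
`lr_coder ~ loguniform(1e-5, 1e-2)`, `lr_lang ~ loguniform(1e-9, 1e-6)`,
`warmup ~ randint(1,5)`, `freeze ~ randint(0,3)`,
`dropout ~ uniform(0.1, 0.5)`; "warmup" is interpreted in epochs. A
Bayesian/hyperband driver can be plugged in behind the same sampling
contract but is not part of the tested core.

The desk-scale experiment configs (`molfuse.experiments`) set
`lr_lang = lr_coder = 5e-3`: the shipped encoder is small and randomly
initialized rather than pretrained, so the tiny fine-tuning rates
appropriate for a 46M-parameter pretrained encoder would leave it untrained.

**Splits.** Bemis-Murcko scaffolds (RDKit) group molecules; groups are
ordered by size descending with a lexicographic tie-break on the scaffold
SMILES and assigned whole, greedily: train until ≥ 80%, then validation
until ≥ 10%, remainder to test. Determinism is exact: the same input always
yields the same split. Acyclic molecules share the empty scaffold and travel
together — a documented consequence of the scaffold definition. Ensembles
re-split the train+validation pool into k seeded near-equal folds; the test
set never enters a fold. Reports give the sample mean ± sample std (ddof=1)
of the k per-fold test metrics — metric first, aggregate second, never the
metric of averaged predictions. Model comparisons use a Welch t-test from
summary statistics (pooled-variance variant behind a flag) with stars at
p < 0.05 / 0.01 / 0.001. For external baselines the caller must supply n,
since published tables rarely record it. The `mean ± std` strings round the
std to two significant digits and the mean to the same decimal place.

**Embeddings.** The latent embedding of a molecule is its penultimate
dense-layer activation (post-ReLU, pre-dropout). 2-D projection goes through
an external projector interface; the default is UMAP with 10 neighbors,
minimum distance 0.25, Chebyshev distance for regression tasks and Jaccard
for classification tasks. Jaccard on continuous activations relies on the
projector's internal handling of the metric; the embeddings are not
binarized first. The projection is visualization plumbing, not part of any
reported metric.

## Numerical core

No GPU framework is used: a small reverse-mode autodiff engine over NumPy
arrays (`molfuse._tensor`) implements exactly the operations the
architectures need. Graphs in a batch are stacked into one block-diagonal
union graph; GATv2's per-neighborhood softmax is computed with a dense
node-by-edge incidence matrix and a constant per-destination max shift for
stability — cheap at molecular scale (≤ ~20 heavy atoms). Both layers are
tested against dense brute-force oracles (explicit adjacency products,
explicit per-node softmax loops) to 1e-5 and against finite-difference
gradient checks. Training runs in float32; oracle tests run in float64.
BCE probabilities are clamped to [1e-7, 1-1e-7]; the RMSE used as a training
loss adds 1e-12 under the square root so the gradient exists at a perfect
fit; MAE uses the same smoothing. Every stochastic element (parameter
initialization, batch order, dropout, fold permutation, generator, label
noise) draws from an explicit seed, and repeated runs reproduce metrics
CSVs byte-identically.

## The synthetic generator

The generator emulates a MoleculeNet-style property table at desk scale:
valid SMILES grown by a stochastic grammar (chains with branches, saturated
rings assembled atom-by-atom with N/O/S substitutions, aromatic rings from a
verified template list, optional second ring over a short linker), with
scaffold diversity switchable between all-unique (every molecule a distinct
Bemis-Murcko scaffold — which forces a ring) and clustered (few cores, many
decorations). Labels follow

    y = w_heavy·(heavy atoms) + w_hetero·(N+O fraction)
      + w_ring·(ring count) + w_arom·(aromatic-token fraction) + ε

with ε ~ N(0, noise_sd²); the classification variant thresholds the
noiseless score. Defaults: w = (0.1, 2.0, 1.0, 3.0), noise_sd = 0.3 —
chosen so the four channels contribute comparable variance on the default
molecule distribution and the noise floor sits near half the label spread.
The aromatic-token fraction (aromatic heavy-atom tokens over all non-special
tokens) is read directly by the language branch but only indirectly — via
aromaticity-linked features — by the graph branch; ring count is the
converse. What the generator does **not** emulate: real assay noise
structure, activity cliffs, tautomer/salt artifacts, the label distributions
of any real benchmark, or molecules beyond ~16 heavy atoms. Passing tests
on this fixture demonstrate that the machinery is correct and that fusion
can exploit complementary channels; they say nothing quantitative about
real-task accuracy, which additionally depends on a large pretrained
encoder.

## Study conditions for the shipped experiments

The synergy experiment uses 300 all-unique-scaffold molecules, a 3-fold
ensemble, 30 epochs, the small encoder (one block, 8-dim) and a 16-wide
2-layer GATv2, repeated over 5 seeds with a fresh fixture per seed; the
fused model and both ablations share splits, folds, hyperparameters and
seeds, and are compared on mean validation RMSE. The benchmark demonstration
uses 100 molecules and k = 3. These sizes are the package's chosen
desk-scale conditions; the full-size defaults (hidden 128, 3 GNN layers,
k = 10, 50 epochs) remain the library defaults.

## Known limitations

- The alignment is static and hydrogen-free by design; hydrogen-inclusive or
  dynamic token↔node mappings are out of scope.
- The shipped encoder is a stand-in scale model of a chemical language
  model; reproducing published benchmark numbers requires an externally
  trained encoder behind the `LanguageEncoder` interface (`TableEncoder`
  accepts exported per-token embedding matrices).
- Mean pooling discards molecule size; count-like targets are intentionally
  hard for both branches under this readout.
- The scaffold split is deterministic greedy largest-first; other published
  variants (e.g. randomized scaffold ordering) will place borderline groups
  differently.
- GCN ignores edge features; only GATv2 consumes them, and only through the
  attention score.
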