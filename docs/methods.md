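# Methods

## Model

A molecule is a heavy-atom graph: nodes carry (atomic number, chirality
tag) and bonds carry (bond type, bond direction), each mapped to a learned
embedding. The default encoder is a five-layer, single-head graph
attention network with 100-dimensional hidden states (d^g = 100); GCN,
GIN and GraphSAGE are drop-in alternatives. Bond embeddings are added
into messages for GAT and GIN; GCN and GraphSAGE aggregate over topology
only. ReLU sits between layers, with no residual connections or
normalisation layers — the reference model is deliberately minimal, and
each of those choices is configurable.

The attribute vector `a` of a molecule is a fingerprint family reduced to
100 dimensions by centred PCA (full LAPACK SVD, components' signs fixed by
making each component's largest-magnitude loading positive, no
whitening), a sum or concatenation of two or three such reductions, or a
PCA-reduced precomputed embedding ingested from a table keyed by
canonical SMILES. Deep embeddings pass through the same PCA step
regardless of their input dimension. When fewer than 100 components exist
(small fitting sets), projections are zero-padded so downstream shapes
never change. PCA is fitted on all molecules of the dataset by default;
`fit_reducer`/`apply_reducer` are separated so a leakage-averse caller
can fit on meta-training molecules only.

Attribute-guided dual-channel attention (AGDA) refines the encoder
output. With node embeddings G = {g_j}:

* local channel: `Attn_local = σ(W_l [g_j ; a] + b_l)` elementwise-gates
  every node, `g'_j = Attn_local ⊙ g_j`;
* global channel: `g = mean_j g'_j`, `z' = σ(W_g [g ; a] + b_g) ⊙ g`.

Both gates are single affine layers; the same attribute vector is
broadcast to every node row. Sigmoid outputs are clamped to
[1e−12, 1 − 1e−12] so gates remain strictly inside (0, 1) even when the
logits saturate in double precision.

Class prototypes are inverse-distance-weighted sums of the support
embeddings; ε = 1e−8 is added to each summed distance before inversion so
duplicate supports and K = 1 are well defined (all-coincident supports
degrade gracefully to uniform weights). Queries are scored by a two-way
softmax over similarities to the two prototypes. The similarity is the
dot product; the "w/o S" ablation replaces it with the negative *squared*
Euclidean distance (the standard prototypical-network distance). The
similarity→probability map is not uniquely determined by the
architecture's description; the two-way softmax was chosen because it is
differentiable, order-preserving and yields calibrated-looking
probabilities for the cross-entropy loss. Predictions use a fixed 0.5
threshold for F1 (ties predict positive); ROC-AUC and PR-AUC use the raw
probabilities. Cross-entropy clips probabilities to [1e−7, 1 − 1e−7].

## Training and evaluation protocol

Each optimizer step samples one training task uniformly, draws a 2-way
K-shot episode (K positive + K negative supports without replacement, q
queries from the remaining molecules, stratified towards a balanced query
set when the pool allows) and takes an Adam step on the episode's loss.
Tasks with fewer than K positives contribute positives sampled with
replacement (logged); tasks with fewer than 2 positives are skipped.

Early stopping monitors mean ROC-AUC on a fixed set of validation
episodes — never drawn from test tasks. By default whole training tasks
(two) are held out as meta-validation tasks, so the monitor measures
what actually matters in this setting: transfer to properties the
optimizer never trains on. The alternative monitor (a 20% molecule
holdout within every training task) measures within-task fit; on the
synthetic benchmark it keeps improving while transfer to unseen tasks
degrades — episodic training meta-overfits to the training properties —
so it is not the default, but remains available (`val_on="molecules"`)
and is used automatically when a split has too few tasks to spare. The
monitor is checked every 25 episodes with a patience of 100 checks; the
untrained parameters count as checkpoint candidate zero, and the
best-scoring parameters are restored at the end. Evaluation on meta-test tasks performs no
gradient updates: per task and run, a fresh support set (2K) and query
set (q, resampled up to 20 times if single-class) are drawn and ROC-AUC,
F1 and PR-AUC accumulated; reports carry per-run entries, per-task
means/stds and the grand mean/std. All randomness flows from one root
seed through named substreams (episode sampling, holdout split,
validation, per-run evaluation), so any component is individually
reproducible and two runs with the same seed are bit-identical.

Defaults: K = 10, q = 32, 2000 episodes (interpreted as total optimizer
steps), learning rate 1e−3 within the method's usual 5e−4 to 5e−2 range,
20 evaluation runs. The learning rate is the one hyperparameter worth
selecting per problem — on the synthetic benchmark below, validation
ROC-AUC prefers a larger step (see "Synthetic benchmark").

## Automatic differentiation

Training runs on a compact reverse-mode autodiff engine over numpy
arrays (`apn.autodiff`) supporting the operations the model needs:
broadcast arithmetic, matrix products, row gather / segment reduction
(the message-passing primitives), the nonlinearities and reductions.
Every operation is validated against central finite differences in the
test suite. Episodes are processed as one disjoint-union graph per
batch, so a 2-way 10-shot episode with 32 queries is five sparse layer
passes over ~1000 nodes rather than 52 separate graphs.

## Synthetic benchmark

The generator emulates a multi-assay screening panel: molecules are
decorated alkyl chains (optional carbocyclic appendages) whose
decorations are drawn independently per motif. The twelve motifs are
distinct heteroaromatic rings and heteroatom-rich groups — furan,
thiophene, pyridine, pyrimidine, pyrrole, imidazole, morpholine,
piperidine, nitro, sulfonamide, CF3, carboxylic acid. A task's
noise-free label is the SMARTS presence of its motif, flipped with
probability `label_noise`. Motifs were chosen to be mutually exclusive
at the SMARTS level (the pyridine pattern cannot map onto pyrimidine,
the carboxylic OH is not an alcohol, the decoy carbocycles match
nothing) so task labels are near-independent, and because each motif
seeds many unique circular atom environments, fingerprint attributes
separate every task's classes sharply — the attribute-benefit
comparison is sharp rather than flaky. Defaults:
2000 molecules, prevalence 0.35 per task, noise 0, nine training and
three test motifs (disjoint, so test properties are genuinely unseen).
Stereocentres are avoided so canonicalisation is toolkit-stable.

What the generator does *not* emulate: realistic chemistry distributions
(scaffold diversity, activity cliffs, correlated assays, the extreme
class imbalance of virtual-screening panels). Passing the benchmark demonstrates that the machinery
learns and that attributes carry transferable signal under controlled
conditions; it is not evidence about any particular public dataset.

The benchmark study trains 2-way 10-shot for 500 episodes on the
2000-molecule panel and compares against the no-attribute ablation
("w/o A": encoder mean pooling, no AGDA) trained identically. The
attribute is the concatenation of the reduced ECFP4 and MACCS
attributes, selected by the package's own screening protocol on the
meta-validation tasks (never on test tasks). Problem sizes were chosen
so the full study runs in minutes on one CPU core.

Because the benchmark's tasks are near-independent by construction,
cross-task transfer can only flow through the attribute channel — a
deliberately adversarial setting for episodic training, which on such
panels meta-overfits to the training motifs within tens of episodes.
This is why the early-stopping monitor is task-level, checks frequently,
and admits the untrained parameters as a candidate: on panels with
independent tasks the monitor often selects a very early checkpoint,
whereas on real multi-assay data (where tasks correlate) later
checkpoints win. The attribute-benefit comparison is unaffected: with
attributes the model transfers to unseen motifs far above chance, while
the no-attribute ablation stays near chance.

## Numerical choices and edge cases

* Pairwise support distances use `sqrt(‖·‖² + 1e−12)` in the
  differentiable path so the gradient at coincident points is finite.
* Two-way softmax and segment softmax subtract the (detached) per-row or
  per-segment maximum before exponentiation.
* Single-atom molecules: message passing degenerates gracefully (GAT/GCN
  keep the self-loop; GraphSAGE's neighbour mean is zero-filled).
* Non-finite training loss aborts with an error rather than continuing.
* `classify_relationship` uses strict inequalities for mutual promotion
  (R1) and mutual inhibition (R3); all ties fall into one-sided promotion
  (R2), evaluated R1 → R3 → R2.

## Known limitations

* Single attention head per GAT layer by default; multi-head
  concatenation is not implemented.
* The no-framework engine is CPU-bound and processes one episode per
  step; it is sized for desk-scale studies, not for 90k-molecule screens.
* Pretrained encoder weights can be loaded from this package's own
  checkpoints only; no pretraining procedure is included.
* An optional 15th physicochemical-descriptor attribute is not included;
  the registry is exactly the 14 fingerprint families plus deep
  embeddings.
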