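# apn — attribute-guided prototype networks for few-shot molecular property prediction

Predicting a *new* binary molecular property (a toxicity endpoint, a side
effect, an assay outcome) from only a handful of labelled molecules is the
few-shot molecular property prediction problem. `apn` implements a
metric-based meta-learner for the 2-way K-shot setting: a graph attention
network encodes each molecule, human-defined **molecular attributes** —
one of 14 fingerprint families (ECFP/FCFP circular, RDK path, hashed
atom-pair/torsion, MACCS, Avalon) PCA-reduced to 100 dimensions, their
pairwise/triplet combinations, or precomputed deep embeddings — gate the
node-level and molecule-level representations through two sigmoid
attention channels, and queries are classified against
**distance-weighted class prototypes** built from the support set.

For a support set {z'_i} of one class, each point's weight is the inverse
of its total Euclidean distance to its classmates,

    distance_i = Σ_j ‖z'_i − z'_j‖,   a_i ∝ 1 / (distance_i + ε),
    p_class    = Σ_i a_i z'_i,

so outliers contribute less than central examples. A query z' is scored by
a two-way softmax over its dot-product similarities to the positive and
negative prototypes, and meta-training minimises the mean binary
cross-entropy on the query set, episode by episode, with Adam and early
stopping on validation ROC-AUC.

Every stage is testable without external data: `apn.synthetic_tasks`
generates libraries of valid molecules whose task labels are determined by
the presence of functional-group motifs (nitro, sulfonamide, CF3, …) with
controllable prevalence and label noise, split into disjoint meta-training
and meta-testing motif tasks.

## Worked example

```python
from apn.attributes import attribute_pipeline
from apn.meta_runner import TaskSplit, TrainConfig, meta_train, meta_evaluate
from apn.model import APNModel
from apn.synthetic_tasks import SynthSpec, make_benchmark

spec = SynthSpec(n_molecules=600, seed=7)
table, split_dict = make_benchmark(spec)          # 9 train / 3 test motif tasks
smiles = table["smiles"].tolist()
attr = attribute_pipeline(smiles, "ecfp4").values  # n x 100 attribute matrix
split = TaskSplit.from_table(table, split_dict)

model = APNModel.build(smiles, attr, seed=0)
history = meta_train(model, split, TrainConfig(K=10, q=32, episodes=120, seed=0))
report = meta_evaluate(model, split, K=10, q=32, runs=5, seed=0)
print(round(history["loss"][0], 3), round(history["loss"][-1], 3))
print(round(report.mean["roc_auc"], 3))
```

prints

```
0.692 0.528
0.754
```

— the episodic loss falls from chance level (ln 2 ≈ 0.693) as training
progresses, and the model reaches ROC-AUC ≈ 0.75 on the three *unseen*
motif tasks after at most 120 episodes at this small scale (mean over 5
evaluation runs × 3 tasks; exact values depend on the seeds shown).

The same pipeline is available from a shell:

```sh
apn synth --n-molecules 2000 --out bench/
apn train --dataset bench/molecules.csv --split bench/split.json \
          --attribute ecfp4 --episodes 500 --checkpoint model.npz
apn eval  --dataset bench/molecules.csv --split bench/split.json \
          --attribute ecfp4 --checkpoint model.npz --runs 20
apn screen --dataset bench/molecules.csv --split bench/split.json \
           --attributes ecfp4,rdk5,hashap
```

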