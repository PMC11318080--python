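"""Episode sampling, training loop and evaluation reporting."""

import numpy as np
import pytest

from apn.encoder import EncoderConfig
from apn.meta_runner import (
    EvalReport,
    SkipTask,
    TaskSplit,
    TrainConfig,
    meta_evaluate,
    meta_train,
    sample_episode,
)
from apn.model import APNModel


@pytest.fixture(scope="module")
def problem(request):
    """A tiny trainable problem: 300 molecules, ecfp4 attribute."""
    from apn.attributes import attribute_pipeline
    from apn.synthetic_tasks import SynthSpec, make_benchmark

    spec = SynthSpec(n_molecules=300, seed=42)
    table, split_dict = make_benchmark(spec, 9, 3)
    smiles = table["smiles"].tolist()
    attr = attribute_pipeline(smiles, "ecfp4").values
    split = TaskSplit.from_table(table, split_dict)
    return smiles, attr, split


def small_model(problem, seed=0, **flags):
    smiles, attr, _ = problem
    cfg = EncoderConfig(arch="gat", n_layers=2, hidden_dim=24)
    return APNModel.build(smiles, attr, cfg=cfg, seed=seed, **flags)


class TestSampleEpisode:
    def test_sizes_and_disjointness(self, problem, rng):
        _, _, split = problem
        task = split.train_tasks[0]
        for _ in range(200):
            ep = sample_episode(split, task, K=10, q=16, rng=rng)
            assert len(ep.support_pos) == len(ep.support_neg) == 10
            support = set(ep.support_pos) | set(ep.support_neg)
            assert len(support & set(ep.query)) == 0
            assert len(ep.query) == len(ep.query_labels)

    def test_deterministic_for_fixed_seed(self, problem):
        _, _, split = problem
        task = split.train_tasks[1]
        e1 = sample_episode(split, task, 5, 8, np.random.default_rng(9))
        e2 = sample_episode(split, task, 5, 8, np.random.default_rng(9))
        assert np.array_equal(e1.support_pos, e2.support_pos)
        assert np.array_equal(e1.query, e2.query)
        assert np.array_equal(e1.query_labels, e2.query_labels)

    def test_labels_match_pools(self, problem, rng):
        _, _, split = problem
        task = split.test_tasks[0]
        pos, neg = split.pools[task]
        ep = sample_episode(split, task, 5, 16, rng)
        for mol, lab in zip(ep.query, ep.query_labels):
            assert mol in (pos if lab == 1 else neg)

    def test_scarce_positives_sampled_with_replacement(self, rng):
        pools = {"t": (np.array([1, 2, 3]), np.arange(10, 40))}
        split = TaskSplit(["t"], [], pools)
        ep = sample_episode(split, "t", K=5, q=4, rng=rng)
        assert len(ep.support_pos) == 5  # drawn with replacement from 3

    def test_tiny_pool_raises_skip(self, rng):
        split = TaskSplit(["t"], [], {"t": (np.array([1]), np.arange(10))})
        with pytest.raises(SkipTask):
            sample_episode(split, "t", K=5, q=4, rng=rng)


class TestTaskSplit:
    def test_overlapping_tasks_rejected(self):
        from apn.chem_data import MoleculeRecord

        recs = [MoleculeRecord("CCO", {"a": 1, "b": 0}, 0)]
        with pytest.raises(ValueError):
            TaskSplit.from_records(recs, ["a"], ["a"])

    def test_missing_labels_excluded(self):
        from apn.chem_data import MISSING, MoleculeRecord

        recs = [
            MoleculeRecord("CCO", {"a": 1}, 0),
            MoleculeRecord("CCN", {"a": MISSING}, 1),
            MoleculeRecord("CCC", {"a": 0}, 2),
        ]
        split = TaskSplit.from_records(recs, ["a"], [])
        pos, neg = split.pools["a"]
        assert list(pos) == [0] and list(neg) == [2]


class TestMetaTrain:
    def test_loss_decreases_on_learnable_task(self, problem):
        model = small_model(problem)
        _, _, split = problem
        cfg = TrainConfig(K=5, q=16, episodes=50, eval_every=1000, seed=0)
        hist = meta_train(model, split, cfg)
        assert hist["episodes_run"] == 50
        early = np.mean(hist["loss"][:5])
        late = np.mean(hist["loss"][-5:])
        assert late < early
        assert late < np.log(2.0)

    def test_same_seed_identical_params_and_metrics(self, problem):
        _, _, split = problem
        cfg = TrainConfig(K=3, q=8, episodes=12, eval_every=6, seed=7)
        digests, reports = [], []
        for _ in range(2):
            model = small_model(problem, seed=7)
            meta_train(model, split, cfg)
            digests.append(model.params_digest())
            reports.append(
                meta_evaluate(model, split, K=3, q=8, runs=2, seed=7).to_json()
            )
        assert digests[0] == digests[1]
        assert reports[0] == reports[1]

    def test_no_attribute_ablation_runs_end_to_end(self, problem):
        smiles, _, split = problem
        cfg = EncoderConfig(arch="gat", n_layers=2, hidden_dim=16)
        model = APNModel.build(smiles, None, cfg=cfg, seed=0, use_attributes=False)
        hist = meta_train(model, split, TrainConfig(K=3, q=8, episodes=10,
                                                    eval_every=5, seed=0))
        assert len(hist["loss"]) == 10
        report = meta_evaluate(model, split, K=3, q=8, runs=2, seed=0)
        assert 0.0 <= report.mean["roc_auc"] <= 1.0


class TestMetaEvaluate:
    def test_runs_20_entries_per_task_and_self_consistency(self, problem):
        model = small_model(problem)
        _, _, split = problem
        report = meta_evaluate(model, split, K=3, q=8, runs=20, seed=1)
        for task in split.test_tasks:
            rows = report.per_task[task]
            assert len(rows) == 20
            assert [r["run"] for r in rows] == list(range(20))
            for m in ("roc_auc", "f1", "pr_auc"):
                assert report.task_means[task][m] == pytest.approx(
                    np.mean([r[m] for r in rows]), abs=1e-12
                )
        all_rows = [r for rows in report.per_task.values() for r in rows]
        assert report.mean["roc_auc"] == pytest.approx(
            np.mean([r["roc_auc"] for r in all_rows]), abs=1e-12
        )

    def test_metrics_within_bounds(self, problem):
        model = small_model(problem)
        _, _, split = problem
        report = meta_evaluate(model, split, K=3, q=8, runs=3, seed=2)
        for m in ("roc_auc", "f1", "pr_auc"):
            assert 0.0 <= report.mean[m] <= 1.0
            assert report.std[m] >= 0.0

    def test_evaluation_does_not_mutate_params(self, problem):
        model = small_model(problem)
        _, _, split = problem
        before = model.params_digest()
        meta_evaluate(model, split, K=3, q=8, runs=2, seed=0)
        assert model.params_digest() == before

    def test_random_scores_near_half_auc(self, rng):
        # permutation baseline: label-independent scores give AUC ~ 0.5
        from sklearn.metrics import roc_auc_score

        aucs = [
            roc_auc_score(rng.integers(0, 2, 500), rng.random(500))
            for _ in range(20)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.02


class TestMetricOracle:
    """sklearn metric calls vs hand-rolled rank/PR oracles."""

    @staticmethod
    def rank_auc(labels, scores):
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        return (wins + 0.5 * ties) / (len(pos) * len(neg))

    @staticmethod
    def ap_oracle(labels, scores):
        order = np.argsort(-scores, kind="stable")
        labels = labels[order]
        tp = np.cumsum(labels)
        precision = tp / np.arange(1, len(labels) + 1)
        return float((precision * labels).sum() / labels.sum())

    def test_agreement_on_100_random_vectors(self, rng):
        from sklearn.metrics import average_precision_score, roc_auc_score

        for _ in range(100):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.random(n)  # continuous: ties almost surely absent
            assert roc_auc_score(labels, scores) == pytest.approx(
                self.rank_auc(labels, scores), abs=1e-9
            )
            assert average_precision_score(labels, scores) == pytest.approx(
                self.ap_oracle(labels, scores), abs=1e-9
            )


def test_report_json_round_trip():
    import json

    per_task = {"t": [{"run": 0, "roc_auc": 0.9, "f1": 0.8, "pr_auc": 0.85}]}
    report = EvalReport.from_runs(per_task)
    parsed = json.loads(report.to_json())
    assert parsed["mean"]["roc_auc"] == pytest.approx(0.9)
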