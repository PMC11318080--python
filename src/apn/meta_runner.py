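"""Episodic meta-training and evaluation.

Tasks are columns of a multi-task molecule table.  Each optimizer step
samples one training task, draws a 2-way K-shot episode (K positive + K
negative supports, q queries), forwards it through the model and takes
an Adam step on the episode's cross-entropy.  Early stopping monitors
mean ROC-AUC on validation episodes drawn from held-out molecules of
the training tasks.  Evaluation on meta-test tasks repeats support/query
sampling over independent runs and reports ROC-AUC, F1 and PR-AUC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from .chem_data import MISSING
from .model import APNModel
from .proto_head import Episode

log = logging.getLogger("apn")


class SkipTask(Exception):
    """Raised when a task pool is too small to form an episode."""


# ---------------------------------------------------------------------------
# task splits and episode sampling


@dataclass
class TaskSplit:
    train_tasks: list
    test_tasks: list
    pools: dict  # task -> (pos mol_ids, neg mol_ids), missing labels excluded

    @classmethod
    def from_records(cls, records, train_tasks, test_tasks) -> "TaskSplit":
        if set(train_tasks) & set(test_tasks):
            raise ValueError("train and test task lists overlap")
        pools = {}
        for task in list(train_tasks) + list(test_tasks):
            pos = [r.mol_id for r in records if r.labels.get(task, MISSING) == 1]
            neg = [r.mol_id for r in records if r.labels.get(task, MISSING) == 0]
            pools[task] = (np.array(pos, np.int64), np.array(neg, np.int64))
        return cls(list(train_tasks), list(test_tasks), pools)

    @classmethod
    def from_table(cls, table, split: dict, smiles_col: str = "smiles") -> "TaskSplit":
        """Build directly from a labelled DataFrame + split dict."""
        pools = {}
        for task in split["train_tasks"] + split["test_tasks"]:
            col = table[task].to_numpy()
            pools[task] = (
                np.flatnonzero(col == 1).astype(np.int64),
                np.flatnonzero(col == 0).astype(np.int64),
            )
        return cls(list(split["train_tasks"]), list(split["test_tasks"]), pools)


def sample_episode(
    split: TaskSplit, task, K: int, q: int, rng: np.random.Generator
) -> Episode:
    """Draw one class-balanced episode; support and query never overlap.

    Positive-scarce pools: with fewer than K positives but at least 2,
    positives are drawn with replacement (logged); below 2 the task is
    skipped.
    """
    pos, neg = split.pools[task]
    if len(pos) < 2 or len(neg) < K:
        raise SkipTask(f"task {task!r}: pool too small ({len(pos)}+/{len(neg)}-)")
    if len(pos) < K:
        log.warning("task %r: %d positives < K=%d, sampling with replacement",
                    task, len(pos), K)
        sup_pos = rng.choice(pos, size=K, replace=True)
    else:
        sup_pos = rng.choice(pos, size=K, replace=False)
    sup_neg = rng.choice(neg, size=K, replace=False)

    used = set(sup_pos) | set(sup_neg)
    rem_pos = np.array([i for i in pos if i not in used], np.int64)
    rem_neg = np.array([i for i in neg if i not in used], np.int64)
    if len(rem_pos) + len(rem_neg) < 1:
        raise SkipTask(f"task {task!r}: no query candidates left")
    # stratified: half positives when the pool allows, topped up as available
    n_pos = min(q // 2, len(rem_pos))
    n_neg = min(q - n_pos, len(rem_neg))
    n_pos = min(q - n_neg, len(rem_pos))
    q_pos = rng.choice(rem_pos, size=n_pos, replace=False)
    q_neg = rng.choice(rem_neg, size=n_neg, replace=False)
    query = np.concatenate([q_pos, q_neg])
    labels = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
    order = rng.permutation(len(query))
    return Episode(
        support_pos=sup_pos,
        support_neg=sup_neg,
        query=query[order],
        query_labels=labels[order],
        K=K,
        task_id=task,
    )


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


# ---------------------------------------------------------------------------
# config / report containers


@dataclass
class TrainConfig:
    K: int = 10
    q: int = 32
    episodes: int = 2000
    lr: float = 1e-3
    patience: int = 100
    eval_every: int = 25
    n_val_episodes: int = 4
    val_on: str = "tasks"     # "tasks": hold out whole training tasks for the
    #                           monitor; "molecules": hold out molecules per task
    n_val_tasks: int = 2
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.K < 1 or self.q < 1 or self.episodes < 1:
            raise ValueError("K, q and episodes must all be >= 1")
        if not 5e-4 / 10 <= self.lr <= 5e-2 * 10:
            log.warning("learning rate %g far outside the usual 5e-4..5e-2 range",
                        self.lr)


@dataclass
class EvalReport:
    """Per-task, per-run metrics plus their summaries."""

    per_task: dict        # task -> list of {run, roc_auc, f1, pr_auc}
    task_means: dict      # task -> {metric: mean}, task_stds analogous
    task_stds: dict
    mean: dict            # metric -> mean over all (task, run) entries
    std: dict

    @classmethod
    def from_runs(cls, per_task: dict) -> "EvalReport":
        metrics = ("roc_auc", "f1", "pr_auc")
        task_means, task_stds = {}, {}
        for task, rows in per_task.items():
            task_means[task] = {m: float(np.mean([r[m] for r in rows])) for m in metrics}
            task_stds[task] = {m: float(np.std([r[m] for r in rows])) for m in metrics}
        all_rows = [r for rows in per_task.values() for r in rows]
        mean = {m: float(np.mean([r[m] for r in all_rows])) for m in metrics}
        std = {m: float(np.std([r[m] for r in all_rows])) for m in metrics}
        return cls(per_task, task_means, task_stds, mean, std)

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_task": self.per_task,
                "task_means": self.task_means,
                "task_stds": self.task_stds,
                "mean": self.mean,
                "std": self.std,
            },
            indent=2,
            sort_keys=True,
        )


def _episode_metrics(probs: np.ndarray, labels: np.ndarray) -> dict:
    return {
        "roc_auc": float(roc_auc_score(labels, probs)),
        "f1": float(f1_score(labels, (probs >= 0.5).astype(int))),
        "pr_auc": float(average_precision_score(labels, probs)),
    }


# ---------------------------------------------------------------------------
# training


def _substream(seed: int, name: str) -> np.random.Generator:
    tag = int.from_bytes(name.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def _validation_split(split: TaskSplit, frac: float, rng) -> tuple[TaskSplit, TaskSplit]:
    """Hold out a fraction of each training task's molecules for validation."""
    train_pools, val_pools = {}, {}
    for task in split.train_tasks:
        pos, neg = split.pools[task]
        tp, vp = _holdout(pos, frac, rng)
        tn, vn = _holdout(neg, frac, rng)
        train_pools[task] = (tp, tn)
        val_pools[task] = (vp, vn)
    inner = TaskSplit(split.train_tasks, [], train_pools)
    val = TaskSplit(split.train_tasks, [], val_pools)
    return inner, val


def _holdout(ids: np.ndarray, frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    ids = rng.permutation(ids)
    n_val = max(int(round(frac * len(ids))), 0)
    return np.sort(ids[n_val:]), np.sort(ids[:n_val])


def meta_train(model: APNModel, split: TaskSplit, cfg: TrainConfig) -> dict:
    """Episodic training with early stopping; returns the training log.

    The model is left holding the parameters of the best monitor
    checkpoint (the untrained state included).  The monitor is mean
    ROC-AUC on validation episodes; with ``val_on="tasks"`` these come
    from whole held-out training tasks (monitoring transfer to unseen
    properties), with ``val_on="molecules"`` from held-out molecules of
    every training task (monitoring within-task fit).
    """
    ep_rng = _substream(cfg.seed, "episode")
    val_rng = _substream(cfg.seed, "val")
    use_task_val = (
        cfg.val_on == "tasks" and len(split.train_tasks) > cfg.n_val_tasks + 1
    )
    if use_task_val:
        val_tasks = split.train_tasks[-cfg.n_val_tasks:]
        inner = TaskSplit(split.train_tasks[:-cfg.n_val_tasks], [], split.pools)
        val_split = TaskSplit(val_tasks, [], split.pools)
        val_K = cfg.K
    else:
        inner, val_split = _validation_split(split, frac=cfg.val_fraction,
                                             rng=_substream(cfg.seed, "holdout"))
        val_K = min(cfg.K, 5)
    # validation episodes are fixed once so the monitor is comparable
    val_eps = []
    for task in val_split.train_tasks:
        for _ in range(cfg.n_val_episodes):
            try:
                ep = sample_episode(val_split, task, val_K, cfg.q, val_rng)
            except SkipTask:
                continue
            if len(np.unique(ep.query_labels)) == 2:
                val_eps.append(ep)

    def monitor() -> float:
        aucs = [
            roc_auc_score(ep.query_labels, model.predict_episode(ep))
            for ep in val_eps
        ]
        return float(np.mean(aucs)) if aucs else np.nan

    opt = Adam(model.parameters(), lr=cfg.lr)
    history = {"loss": [], "val_auc": [], "episodes_run": 0, "stopped_early": False,
               "val_on": "tasks" if use_task_val else "molecules"}
    best_auc, best_state, checks_since_best = -np.inf, model.get_state(), 0
    if val_eps:  # the untrained model is checkpoint candidate number zero
        best_auc = monitor()
        history["val_auc"].append(best_auc)

    for step in range(cfg.episodes):
        task = inner.train_tasks[int(ep_rng.integers(len(inner.train_tasks)))]
        try:
            ep = sample_episode(inner, task, cfg.K, cfg.q, ep_rng)
        except SkipTask:
            continue
        opt.zero_grad()
        loss, _ = model.episode_forward(ep, training=True)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite loss at episode {step}; aborting (lr={cfg.lr})"
            )
        loss.backward()
        opt.step()
        history["loss"].append(float(loss.data))
        history["episodes_run"] = step + 1

        if val_eps and (step + 1) % cfg.eval_every == 0:
            val_auc = monitor()
            history["val_auc"].append(val_auc)
            if val_auc > best_auc:
                best_auc, best_state, checks_since_best = val_auc, model.get_state(), 0
            else:
                checks_since_best += 1
                if checks_since_best >= cfg.patience:
                    history["stopped_early"] = True
                    break

    if best_auc > -np.inf:
        model.set_state(best_state)
    history["best_val_auc"] = None if best_auc == -np.inf else float(best_auc)
    return history


# ---------------------------------------------------------------------------
# evaluation


def meta_evaluate(
    model: APNModel,
    split: TaskSplit,
    K: int = 10,
    q: int = 32,
    runs: int = 20,
    seed: int = 0,
    max_retries: int = 20,
) -> EvalReport:
    """Repeated-episode evaluation on the meta-test tasks (no updates)."""
    if not split.test_tasks:
        raise ValueError("split has no test tasks")
    per_task = {task: [] for task in split.test_tasks}
    for run in range(runs):
        rng = _substream(seed, f"eval-run-{run}")
        for task in split.test_tasks:
            for attempt in range(max_retries):
                ep = sample_episode(split, task, K, q, rng)
                if len(np.unique(ep.query_labels)) == 2:
                    break
                log.info("task %r run %d: one-class query, resampling", task, run)
            else:
                raise RuntimeError(f"task {task!r}: no two-class query in "
                                   f"{max_retries} draws")
            probs = model.predict_episode(ep)
            row = {"run": run, **_episode_metrics(probs, ep.query_labels)}
            per_task[task].append(row)
    return EvalReport.from_runs(per_task)


# ---------------------------------------------------------------------------
# attribute screening


def attribute_screen(
    build_model,  # callable: attribute_name -> APNModel (fresh, same seed)
    split: TaskSplit,
    attributes: list,
    train_cfg: TrainConfig,
    eval_runs: int = 5,
) -> list:
    """Train/evaluate one model per attribute under identical seeds.

    Returns rows ``{"attribute", "roc_auc", "f1", "pr_auc"}`` sorted by
    ROC-AUC descending.
    """
    rows = []
    for name in attributes:
        m = build_model(name)
        meta_train(m, split, train_cfg)
        report = meta_evaluate(
            m, split, K=train_cfg.K, q=train_cfg.q, runs=eval_runs,
            seed=train_cfg.seed,
        )
        rows.append({"attribute": name, **report.mean})
    return sorted(rows, key=lambda r: -r["roc_auc"])


def pair_relationships(single_scores: dict, pair_scores: dict) -> dict:
    """R1/R2/R3 heatmap values for attribute pairs.

    ``pair_scores`` keys are "fp1_fp2" names; returns the same keys
    mapped to {"relationship", "heatmap"}.
    """
    from .attributes import HEATMAP_VALUE, classify_relationship

    out = {}
    for pair, auc in pair_scores.items():
        fp1, fp2 = pair.split("_", 1)
        rel = classify_relationship(auc, single_scores[fp1], single_scores[fp2])
        out[pair] = {"relationship": rel, "heatmap": HEATMAP_VALUE[rel]}
    return out
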