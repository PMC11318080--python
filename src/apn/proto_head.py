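"""Distance-weighted prototypes, query classification and episodic loss.

Each class prototype is a convex combination of its K support
embeddings.  A support point's weight is the inverse of the sum of its
Euclidean distances to the other support points of the same class
(plus a small epsilon), normalized to sum to one — outliers far from
their classmates contribute less.  Queries are scored against the two
prototypes with dot-product similarity (or negative squared Euclidean
distance for the "w/o S" ablation) passed through a two-way softmax,
and training minimizes the mean binary cross-entropy over the query
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, gather_rows, segment_sum

EPS_DISTANCE = 1e-8     # regularizes 1/distance at coincident supports
PROB_CLIP = 1e-7        # cross-entropy probability floor/ceiling
SIMILARITIES = ("dot", "neg_l2")


@dataclass
class Episode:
    """One 2-way K-shot task: 2K labeled supports + q queries."""

    support_pos: np.ndarray   # indices or vectors, positive class
    support_neg: np.ndarray
    query: np.ndarray
    query_labels: np.ndarray
    K: int
    task_id: object = None


@dataclass
class Prototypes:
    p_positive: np.ndarray
    p_negative: np.ndarray
    weights_pos: np.ndarray
    weights_neg: np.ndarray


@dataclass
class PredictionSet:
    probs: np.ndarray
    labels_pred: np.ndarray
    per_query_loss: np.ndarray = field(default=None)
    episode_loss: float = None


# ---------------------------------------------------------------------------
# numpy reference path (inference / contracts)


def support_weights(support: np.ndarray) -> np.ndarray:
    """Inverse-total-distance weights a_i over one class's support set."""
    support = np.atleast_2d(np.asarray(support, dtype=np.float64))
    if support.shape[0] == 0:
        raise ValueError("empty support set")
    diffs = support[:, None, :] - support[None, :, :]
    dist = np.sqrt((diffs**2).sum(axis=2))
    total = dist.sum(axis=1)
    w = 1.0 / (total + EPS_DISTANCE)
    return w / w.sum()


def compute_prototype(support, uniform: bool = False):
    """Return ``(prototype, weights)`` for one class.

    ``uniform=True`` is the "w/o W" ablation: a plain arithmetic mean.
    """
    support = np.atleast_2d(np.asarray(support, dtype=np.float64))
    K = support.shape[0]
    if K == 0:
        raise ValueError("empty support set")
    weights = np.full(K, 1.0 / K) if uniform else support_weights(support)
    return weights @ support, weights


def compute_prototypes(episode_pos, episode_neg, uniform: bool = False) -> Prototypes:
    p_pos, w_pos = compute_prototype(episode_pos, uniform=uniform)
    p_neg, w_neg = compute_prototype(episode_neg, uniform=uniform)
    return Prototypes(p_pos, p_neg, w_pos, w_neg)


def classify_query(z, protos: Prototypes, similarity: str = "dot") -> float:
    """Probability that query ``z`` is positive (two-way softmax)."""
    if similarity not in SIMILARITIES:
        raise ValueError(f"unknown similarity {similarity!r}; one of {SIMILARITIES}")
    z = np.asarray(z, dtype=np.float64).ravel()
    if z.shape != protos.p_positive.shape:
        raise ValueError(
            f"query dim {z.shape} does not match prototype dim "
            f"{protos.p_positive.shape}"
        )
    if similarity == "dot":
        s_pos, s_neg = z @ protos.p_positive, z @ protos.p_negative
    else:
        s_pos = -((z - protos.p_positive) ** 2).sum()
        s_neg = -((z - protos.p_negative) ** 2).sum()
    m = max(s_pos, s_neg)
    e_pos, e_neg = np.exp(s_pos - m), np.exp(s_neg - m)
    return float(e_pos / (e_pos + e_neg))


def classify_queries(Z, protos: Prototypes, similarity: str = "dot") -> PredictionSet:
    probs = np.array([classify_query(z, protos, similarity) for z in np.atleast_2d(Z)])
    return PredictionSet(probs=probs, labels_pred=(probs >= 0.5).astype(int))


def episode_loss(probs, labels) -> float:
    """Mean binary cross-entropy with probabilities clipped to [1e-7, 1-1e-7]."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if probs.shape != labels.shape:
        raise ValueError(
            f"probs length {probs.shape} does not match labels {labels.shape}"
        )
    p = np.clip(probs, PROB_CLIP, 1.0 - PROB_CLIP)
    L = -(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p))
    return float(L.mean())


# ---------------------------------------------------------------------------
# differentiable path (training)


def prototype_t(support: Tensor, uniform: bool = False) -> Tensor:
    """Differentiable Eq.-5 prototype of one class's (K, d) support block."""
    K = support.data.shape[0]
    if K == 0:
        raise ValueError("empty support set")
    if uniform or K == 1:
        return support.mean(axis=0, keepdims=True)
    ii, jj = np.meshgrid(np.arange(K), np.arange(K), indexing="ij")
    diff = gather_rows(support, ii.ravel()) - gather_rows(support, jj.ravel())
    pair = ((diff * diff).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    total = segment_sum(pair, ii.ravel(), K)           # (K, 1)
    w = 1.0 / (total + EPS_DISTANCE)
    w = w / w.sum()
    return (w * support).sum(axis=0, keepdims=True)    # (1, d)


def query_probs_t(
    queries: Tensor, p_pos: Tensor, p_neg: Tensor, similarity: str = "dot"
) -> Tensor:
    """Differentiable positive-class probabilities for a (q, d) query block."""
    if similarity == "dot":
        s_pos = (queries * p_pos).sum(axis=1, keepdims=True)
        s_neg = (queries * p_neg).sum(axis=1, keepdims=True)
    elif similarity == "neg_l2":
        dp = queries - p_pos
        dn = queries - p_neg
        s_pos = -(dp * dp).sum(axis=1, keepdims=True)
        s_neg = -(dn * dn).sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown similarity {similarity!r}")
    shift = np.maximum(s_pos.data, s_neg.data)  # constant: stabilizes exp
    e_pos = (s_pos - Tensor(shift)).exp()
    e_neg = (s_neg - Tensor(shift)).exp()
    return e_pos / (e_pos + e_neg)


def episode_loss_t(probs: Tensor, labels: np.ndarray) -> Tensor:
    y = np.asarray(labels, dtype=np.float64).reshape(-1, 1)
    p = probs.clip(PROB_CLIP, 1.0 - PROB_CLIP)
    L = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log())
    return L.mean()
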