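"""Graph neural network encoders for molecular graphs.

The default encoder is a five-layer graph attention network (GAT) with
100-dimensional hidden states; GCN, GIN and GraphSAGE variants share the
same interface.  Atom features (atomic number, chirality tag) and bond
features (bond type, bond direction) enter as learned categorical
embeddings.  GAT and GIN add bond embeddings into messages; GCN and
GraphSAGE use topology only.

Molecules are encoded in batches as one disjoint-union graph: node and
edge arrays are stacked with offset indices, and a ``node2mol`` segment
vector maps nodes back to molecules for pooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import chem_data
from .autodiff import Tensor, concat, gather_rows, segment_sum
from .chem_data import MolecularGraph

ARCHS = ("gat", "gcn", "gin", "graphsage")


@dataclass
class EncoderConfig:
    arch: str = "gat"
    n_layers: int = 5
    hidden_dim: int = 100  # d^g
    heads: int = 1
    dropout: float = 0.0
    batch_norm: bool = False  # per-layer BatchNorm over the node dimension
    pretrained_path: str | None = None

    def __post_init__(self):
        self.arch = self.arch.lower()
        if self.arch not in ARCHS:
            raise ValueError(f"unknown encoder arch {self.arch!r}; one of {ARCHS}")
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("n_layers and hidden_dim must be >= 1")


@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs."""

    node_features: np.ndarray  # (N, 2)
    edge_index: np.ndarray     # (2, E)
    edge_features: np.ndarray  # (E, 2)
    node2mol: np.ndarray       # (N,)
    num_mols: int

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph]) -> "GraphBatch":
        nodes, edges, efeats, seg = [], [], [], []
        offset = 0
        for m, g in enumerate(graphs):
            nodes.append(g.node_features)
            edges.append(g.edge_index + offset)
            efeats.append(g.edge_features)
            seg.append(np.full(g.num_nodes, m, dtype=np.int64))
            offset += g.num_nodes
        return cls(
            node_features=np.vstack(nodes),
            edge_index=np.hstack(edges) if edges else np.zeros((2, 0), np.int64),
            edge_features=np.vstack(efeats),
            node2mol=np.concatenate(seg),
            num_mols=len(graphs),
        )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_encoder_params(cfg: EncoderConfig, seed: int = 0) -> dict:
    """Build the parameter dictionary (name -> Tensor) for ``cfg``."""
    rng = np.random.default_rng(seed)
    d = cfg.hidden_dim
    p: dict[str, Tensor] = {
        "atom_emb": Tensor.param(0.1 * rng.standard_normal((chem_data.ATOM_NUM_CLASSES, d))),
        "chir_emb": Tensor.param(0.1 * rng.standard_normal((chem_data.NUM_CHIRALITY, d))),
    }
    for layer in range(cfg.n_layers):
        pre = f"l{layer}."
        if cfg.arch in ("gat", "gin"):
            p[pre + "bond_emb"] = Tensor.param(
                0.1 * rng.standard_normal((chem_data.NUM_BOND_TYPES, d))
            )
            p[pre + "dir_emb"] = Tensor.param(
                0.1 * rng.standard_normal((chem_data.NUM_BOND_DIRS, d))
            )
        if cfg.arch == "gat":
            p[pre + "W"] = Tensor.param(_glorot(rng, d, d))
            p[pre + "b"] = Tensor.param(np.zeros(d))
            p[pre + "att_src"] = Tensor.param(_glorot(rng, d, 1).T)
            p[pre + "att_dst"] = Tensor.param(_glorot(rng, d, 1).T)
        elif cfg.arch == "gcn":
            p[pre + "W"] = Tensor.param(_glorot(rng, d, d))
            p[pre + "b"] = Tensor.param(np.zeros(d))
        elif cfg.arch == "gin":
            p[pre + "W1"] = Tensor.param(_glorot(rng, d, 2 * d))
            p[pre + "b1"] = Tensor.param(np.zeros(2 * d))
            p[pre + "W2"] = Tensor.param(_glorot(rng, 2 * d, d))
            p[pre + "b2"] = Tensor.param(np.zeros(d))
            p[pre + "eps"] = Tensor.param(np.zeros(1))
        else:  # graphsage
            p[pre + "W_self"] = Tensor.param(_glorot(rng, d, d))
            p[pre + "W_neigh"] = Tensor.param(_glorot(rng, d, d))
            p[pre + "b"] = Tensor.param(np.zeros(d))
        if cfg.batch_norm:
            p[pre + "bn_gamma"] = Tensor.param(np.ones(d))
            p[pre + "bn_beta"] = Tensor.param(np.zeros(d))
            # running statistics: buffers, never updated by the optimizer
            p[pre + "bn_mean"] = Tensor(np.zeros(d))
            p[pre + "bn_var"] = Tensor(np.ones(d))
    return p


_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _batch_norm(h: Tensor, params: dict, pre: str, training: bool) -> Tensor:
    """BatchNorm over all nodes in the batch, one statistic per channel."""
    gamma, beta = params[pre + "bn_gamma"], params[pre + "bn_beta"]
    if training:
        mu = h.mean(axis=0, keepdims=True)
        centered = h - mu
        var = (centered * centered).mean(axis=0, keepdims=True)
        out = centered / (var + _BN_EPS).sqrt() * gamma + beta
        rm, rv = params[pre + "bn_mean"], params[pre + "bn_var"]
        n = h.data.shape[0]
        unbiased = var.data[0] * (n / max(n - 1, 1))
        rm.data[...] = (1 - _BN_MOMENTUM) * rm.data + _BN_MOMENTUM * mu.data[0]
        rv.data[...] = (1 - _BN_MOMENTUM) * rv.data + _BN_MOMENTUM * unbiased
        return out
    rm, rv = params[pre + "bn_mean"], params[pre + "bn_var"]
    scale = Tensor(1.0 / np.sqrt(rv.data + _BN_EPS))
    return (h - Tensor(rm.data[None, :])) * scale * gamma + beta


def _check_feature_indices(batch: GraphBatch):
    nf, ef = batch.node_features, batch.edge_features
    if nf.size and (
        nf[:, 0].max() >= chem_data.ATOM_NUM_CLASSES
        or nf[:, 1].max() >= chem_data.NUM_CHIRALITY
    ):
        raise ValueError("atom feature index outside embedding vocabulary")
    if ef.size and (
        ef[:, 0].max() >= chem_data.NUM_BOND_TYPES
        or ef[:, 1].max() >= chem_data.NUM_BOND_DIRS
    ):
        raise ValueError("bond feature index outside embedding vocabulary")


def _segment_softmax(logits: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    # subtract the per-segment max (constant shift) for stability
    shift = np.full(n_seg, -np.inf)
    np.maximum.at(shift, seg, logits.data[:, 0])
    shift[~np.isfinite(shift)] = 0.0
    e = (logits - Tensor(shift[seg][:, None])).exp()
    denom = segment_sum(e, seg, n_seg)
    return e / gather_rows(denom, seg)


def _with_self_loops(batch: GraphBatch):
    n = batch.node_features.shape[0]
    loops = np.arange(n, dtype=np.int64)
    src = np.concatenate([batch.edge_index[0], loops])
    dst = np.concatenate([batch.edge_index[1], loops])
    return src, dst, batch.edge_index.shape[1]


def _edge_embedding(p, pre: str, batch: GraphBatch, n_self: int) -> Tensor:
    """Bond embeddings for real edges, zeros for appended self loops."""
    e = gather_rows(p[pre + "bond_emb"], batch.edge_features[:, 0]) + gather_rows(
        p[pre + "dir_emb"], batch.edge_features[:, 1]
    )
    if n_self == 0:
        return e
    d = p[pre + "bond_emb"].data.shape[1]
    return concat([e, Tensor(np.zeros((n_self, d)))], axis=0)


def encode_batch(
    batch: GraphBatch, cfg: EncoderConfig, params: dict, training: bool = False
) -> Tensor:
    """Forward pass: (N, d^g) node embeddings for the whole batch.

    ``training`` matters only with batch normalization: batch statistics
    (and running-average updates) in training mode, frozen running
    statistics at inference.
    """
    _check_feature_indices(batch)
    n = batch.node_features.shape[0]
    h = gather_rows(params["atom_emb"], batch.node_features[:, 0]) + gather_rows(
        params["chir_emb"], batch.node_features[:, 1]
    )
    src, dst, n_real = _with_self_loops(batch)

    for layer in range(cfg.n_layers):
        pre = f"l{layer}."
        if cfg.arch == "gat":
            hw = h @ params[pre + "W"]
            # one row per real edge then one zero row per appended self loop
            e_emb = _edge_embedding(params, pre, batch, n)
            msg = gather_rows(hw, src) + e_emb
            logits = (msg * params[pre + "att_src"]).sum(axis=1, keepdims=True) + (
                gather_rows(hw, dst) * params[pre + "att_dst"]
            ).sum(axis=1, keepdims=True)
            alpha = _segment_softmax(logits.leaky_relu(0.2), dst, n)
            h_new = segment_sum(alpha * msg, dst, n) + params[pre + "b"]
        elif cfg.arch == "gcn":
            hw = h @ params[pre + "W"]
            deg = np.bincount(dst, minlength=n).astype(np.float64)
            norm = 1.0 / np.sqrt(deg[src] * deg[dst])
            msg = gather_rows(hw, src) * Tensor(norm[:, None])
            h_new = segment_sum(msg, dst, n) + params[pre + "b"]
        elif cfg.arch == "gin":
            e_emb = _edge_embedding(params, pre, batch, 0)
            msg = (gather_rows(h, batch.edge_index[0]) + e_emb).relu()
            agg = segment_sum(msg, batch.edge_index[1], n)
            mixed = h * (1.0 + params[pre + "eps"]) + agg
            h_new = (
                (mixed @ params[pre + "W1"] + params[pre + "b1"]).relu()
                @ params[pre + "W2"]
                + params[pre + "b2"]
            )
        else:  # graphsage, mean aggregation over real neighbours
            e_src, e_dst = batch.edge_index
            deg = np.maximum(np.bincount(e_dst, minlength=n), 1).astype(np.float64)
            neigh = segment_sum(gather_rows(h, e_src), e_dst, n) * Tensor(
                1.0 / deg[:, None]
            )
            h_new = (
                h @ params[pre + "W_self"]
                + neigh @ params[pre + "W_neigh"]
                + params[pre + "b"]
            )
        if cfg.batch_norm:
            h_new = _batch_norm(h_new, params, pre, training)
        h = h_new.relu() if layer < cfg.n_layers - 1 else h_new
    return h


def encode_graph(graph: MolecularGraph, cfg: EncoderConfig, params: dict) -> np.ndarray:
    """Node embeddings (N x d^g) for a single molecule."""
    batch = GraphBatch.from_graphs([graph])
    return encode_batch(batch, cfg, params).data


# ---------------------------------------------------------------------------
# Checkpointing


def save_checkpoint(path, cfg: EncoderConfig, params: dict, extra_params: dict | None = None):
    """Serialize parameters with an embedded config header (npz)."""
    header = json.dumps(
        {"arch": cfg.arch, "n_layers": cfg.n_layers, "hidden_dim": cfg.hidden_dim}
    )
    arrays = {f"enc/{k}": v.data for k, v in params.items()}
    if extra_params:
        arrays.update({f"extra/{k}": v.data for k, v in extra_params.items()})
    np.savez(path, __config__=np.array(header), **arrays)


def load_pretrained(cfg: EncoderConfig, path):
    """Load encoder (and any extra) parameters saved by ``save_checkpoint``.

    Returns ``(params, extra_params)``; fails if the stored architecture
    or dimensions disagree with ``cfg``.
    """
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["__config__"]))
        if header["arch"] != cfg.arch:
            raise ValueError(
                f"checkpoint arch {header['arch']!r} does not match config "
                f"arch {cfg.arch!r}"
            )
        if (
            header["n_layers"] != cfg.n_layers
            or header["hidden_dim"] != cfg.hidden_dim
        ):
            raise ValueError(
                f"checkpoint dims (layers={header['n_layers']}, "
                f"dim={header['hidden_dim']}) do not match config "
                f"(layers={cfg.n_layers}, dim={cfg.hidden_dim})"
            )
        params = {
            k[4:]: Tensor.param(data[k]) for k in data.files if k.startswith("enc/")
        }
        extra = {
            k[6:]: Tensor.param(data[k]) for k in data.files if k.startswith("extra/")
        }
    return params, extra
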