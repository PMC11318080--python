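"""Attribute-guided dual-channel attention (AGDA).

Two sigmoid gates refine the encoder output using the molecule's
attribute vector ``a``:

* local:  Attn_local = sigmoid(f_local([g_j ; a])), applied elementwise
  to every node embedding g_j, giving refined nodes g'_j;
* global: the molecule embedding is the mean of the refined nodes,
  g = mean_j g'_j, and the final representation is
  z' = sigmoid(f_global([g ; a])) * g.

Both f_local and f_global are single affine layers.  Ablations switch
either gate to the identity ("w/o L" / "w/o G").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, segment_sum

ABLATIONS = ("full", "no_local", "no_global")


@dataclass
class AGDAParams:
    """Affine gate parameters; both maps are (d^g + d^a) -> d^g."""

    W_local: Tensor
    b_local: Tensor
    W_global: Tensor
    b_global: Tensor

    @staticmethod
    def init(d_g: int, d_a: int, seed: int = 0) -> "AGDAParams":
        rng = np.random.default_rng(seed)
        limit = np.sqrt(6.0 / (d_g + d_a + d_g))
        return AGDAParams(
            W_local=Tensor.param(rng.uniform(-limit, limit, (d_g + d_a, d_g))),
            b_local=Tensor.param(np.zeros(d_g)),
            W_global=Tensor.param(rng.uniform(-limit, limit, (d_g + d_a, d_g))),
            b_global=Tensor.param(np.zeros(d_g)),
        )

    @staticmethod
    def zeros(d_g: int, d_a: int) -> "AGDAParams":
        return AGDAParams.init(d_g, d_a, seed=0).scaled(0.0)

    def scaled(self, factor: float) -> "AGDAParams":
        return AGDAParams(
            *(Tensor.param(t.data * factor)
              for t in (self.W_local, self.b_local, self.W_global, self.b_global))
        )

    def as_dict(self) -> dict:
        return {
            "W_local": self.W_local,
            "b_local": self.b_local,
            "W_global": self.W_global,
            "b_global": self.b_global,
        }

    @staticmethod
    def from_dict(d: dict) -> "AGDAParams":
        return AGDAParams(d["W_local"], d["b_local"], d["W_global"], d["b_global"])

    def check_dims(self, d_g: int, d_a: int):
        if self.W_local.data.shape != (d_g + d_a, d_g):
            raise ValueError(
                f"f_local expects input dim {self.W_local.data.shape[0]} but "
                f"got d^g={d_g}, d^a={d_a}"
            )


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def local_attention_t(G: Tensor, a_rows: Tensor, params: AGDAParams):
    """Gate each node row; ``a_rows`` must already be one row per node."""
    inp = concat([G, a_rows], axis=1)
    attn = (inp @ params.W_local + params.b_local).sigmoid()
    return attn, attn * G


def global_attention_t(g_mean: Tensor, a_rows: Tensor, params: AGDAParams):
    """Gate molecule-level embeddings (one row per molecule)."""
    inp = concat([g_mean, a_rows], axis=1)
    attn = (inp @ params.W_global + params.b_global).sigmoid()
    return attn, attn * g_mean


def local_attention(G, a, params: AGDAParams):
    """Single-molecule local gate: returns (Attn_local, refined nodes)."""
    G = np.atleast_2d(np.asarray(G, dtype=np.float64))
    a = np.asarray(a, dtype=np.float64).ravel()
    params.check_dims(G.shape[1], a.size)
    a_rows = Tensor(np.broadcast_to(a, (G.shape[0], a.size)).copy())
    attn, out = local_attention_t(Tensor(G), a_rows, params)
    return attn.data, out.data


def global_attention(F_l_out, a, params: AGDAParams) -> np.ndarray:
    """Single-molecule global gate on the mean of refined nodes -> z'."""
    F = np.atleast_2d(np.asarray(F_l_out, dtype=np.float64))
    if F.shape[0] == 0:
        raise ValueError("global attention requires at least one node")
    a = np.asarray(a, dtype=np.float64).ravel()
    g_mean = F.mean(axis=0, keepdims=True)
    _, z = global_attention_t(Tensor(g_mean), Tensor(a[None, :]), params)
    return z.data[0]


def agda_forward(G, a, params: AGDAParams, ablation: str = "full") -> np.ndarray:
    """Full AGDA pass for one molecule, with optional gate ablations."""
    if ablation not in ABLATIONS:
        raise ValueError(f"unknown ablation {ablation!r}; one of {ABLATIONS}")
    G = np.atleast_2d(np.asarray(G, dtype=np.float64))
    if ablation == "no_local":
        refined = G
    else:
        _, refined = local_attention(G, a, params)
    if ablation == "no_global":
        return refined.mean(axis=0)
    return global_attention(refined, a, params)


def agda_batch(
    node_emb: Tensor,
    node2mol: np.ndarray,
    num_mols: int,
    attr: Tensor,
    params: AGDAParams,
    ablation: str = "full",
) -> Tensor:
    """Batched AGDA over a disjoint-union node embedding matrix.

    ``attr`` has one attribute row per molecule; returns (num_mols, d^g)
    final representations z'.
    """
    if ablation not in ABLATIONS:
        raise ValueError(f"unknown ablation {ablation!r}; one of {ABLATIONS}")
    from .autodiff import gather_rows

    counts = np.bincount(node2mol, minlength=num_mols).astype(np.float64)
    if ablation == "no_local":
        refined = node_emb
    else:
        a_rows = gather_rows(attr, node2mol)
        _, refined = local_attention_t(node_emb, a_rows, params)
    g_mean = segment_sum(refined, node2mol, num_mols) * Tensor(1.0 / counts[:, None])
    if ablation == "no_global":
        return g_mean
    _, z = global_attention_t(g_mean, attr, params)
    return z
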