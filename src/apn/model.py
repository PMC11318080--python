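"""End-to-end attribute-guided prototype network.

Pipeline per episode: molecular graphs -> graph encoder -> AGDA gates
(conditioned on the molecule's attribute vector) -> distance-weighted
class prototypes -> two-way softmax over prototype similarities.

Ablation flags mirror the module switches studied with this
architecture:

* ``use_attributes=False`` ("w/o A") bypasses attributes and AGDA — a
  molecule is the mean of its encoder node embeddings;
* ``agda_ablation`` in {"full", "no_local", "no_global"} ("w/o L",
  "w/o G") switches off one gate;
* ``similarity`` in {"dot", "neg_l2"} ("w/o S" uses negative squared
  Euclidean distance);
* ``uniform_weights=True`` ("w/o W") replaces distance weighting with
  the plain prototype mean.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import agda as agda_mod
from . import encoder as enc_mod
from . import proto_head
from .autodiff import Tensor, segment_sum
from .chem_data import GraphCache
from .encoder import EncoderConfig, GraphBatch


@dataclass
class APNModel:
    cfg: EncoderConfig
    enc_params: dict
    agda_params: "agda_mod.AGDAParams"
    attribute_values: np.ndarray | None = None   # (n_molecules, d^a)
    use_attributes: bool = True
    agda_ablation: str = "full"
    similarity: str = "dot"
    uniform_weights: bool = False
    graph_cache: GraphCache = field(default_factory=GraphCache)
    _smiles: list | None = None  # mol_id -> SMILES for the bound dataset

    @classmethod
    def build(
        cls,
        smiles_by_mol_id: list[str] | None = None,
        attribute_values: np.ndarray | None = None,
        cfg: EncoderConfig | None = None,
        seed: int = 0,
        **flags,
    ) -> "APNModel":
        cfg = cfg or EncoderConfig()
        d_a = attribute_values.shape[1] if attribute_values is not None else 1
        model = cls(
            cfg=cfg,
            enc_params=enc_mod.init_encoder_params(cfg, seed=seed),
            agda_params=agda_mod.AGDAParams.init(cfg.hidden_dim, d_a, seed=seed + 1),
            attribute_values=attribute_values,
            **flags,
        )
        model._smiles = smiles_by_mol_id
        return model

    def parameters(self) -> dict:
        params = dict(self.enc_params)
        if self.use_attributes:
            params.update(
                {f"agda.{k}": v for k, v in self.agda_params.as_dict().items()}
            )
        return params

    def param_list(self) -> list:
        return list(self.parameters().values())

    def params_digest(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.parameters()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.parameters()[name].data).tobytes())
        return h.hexdigest()

    # -- forward --------------------------------------------------------------
    def embed(self, mol_ids: np.ndarray, training: bool = False) -> Tensor:
        """Final representations z' (len(mol_ids) x d^g) for dataset molecules."""
        mol_ids = np.asarray(mol_ids, dtype=np.int64)
        graphs = [self.graph_cache.get(self._smiles[i]) for i in mol_ids]
        batch = GraphBatch.from_graphs(graphs)
        node_emb = enc_mod.encode_batch(
            batch, self.cfg, self.enc_params, training=training
        )
        if not self.use_attributes:
            counts = np.bincount(batch.node2mol, minlength=batch.num_mols)
            return segment_sum(node_emb, batch.node2mol, batch.num_mols) * Tensor(
                1.0 / counts.astype(np.float64)[:, None]
            )
        attr = Tensor(self.attribute_values[mol_ids])
        return agda_mod.agda_batch(
            node_emb,
            batch.node2mol,
            batch.num_mols,
            attr,
            self.agda_params,
            ablation=self.agda_ablation,
        )

    def episode_forward(
        self, episode, training: bool = False
    ) -> tuple[Tensor, np.ndarray]:
        """Loss tensor and query probabilities for one episode."""
        K, q = episode.K, len(episode.query)
        ids = np.concatenate([episode.support_pos, episode.support_neg, episode.query])
        z = self.embed(ids, training=training)
        z_pos = _rows(z, np.arange(K))
        z_neg = _rows(z, np.arange(K, 2 * K))
        z_query = _rows(z, np.arange(2 * K, 2 * K + q))
        p_pos = proto_head.prototype_t(z_pos, uniform=self.uniform_weights)
        p_neg = proto_head.prototype_t(z_neg, uniform=self.uniform_weights)
        probs = proto_head.query_probs_t(z_query, p_pos, p_neg, self.similarity)
        loss = proto_head.episode_loss_t(probs, episode.query_labels)
        return loss, probs.data.ravel()

    def predict_episode(self, episode) -> np.ndarray:
        """Query probabilities without building a gradient graph."""
        _, probs = self.episode_forward(episode)
        return probs

    # -- state ----------------------------------------------------------------
    def get_state(self) -> dict:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def set_state(self, state: dict):
        for k, v in self.parameters().items():
            v.data[...] = state[k]

    def save(self, path):
        enc_mod.save_checkpoint(
            path,
            self.cfg,
            self.enc_params,
            extra_params=self.agda_params.as_dict() if self.use_attributes else None,
        )


def _rows(z: Tensor, idx: np.ndarray) -> Tensor:
    from .autodiff import gather_rows

    return gather_rows(z, idx)
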