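"""Graph isomorphism network (GIN) encoder for molecular graphs.

Message passing follows the sum-aggregation update

    h_v^(j) = MLP^(j)( h_v^(j-1) + sum_{u in N(v)} (h_u^(j-1) + e_uv) )

with h_v^(0) the sum of the atom-type and chirality embeddings and e_uv a
learned embedding of the bond type and direction (each layer owns its edge
embeddings).  Each layer's MLP is linear -> ReLU -> linear at constant width,
followed by batch normalization; ReLU is applied between layers but not after
the last.  A permutation-invariant readout (mean by default) pools the final
node embeddings into a graph embedding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence

import numpy as np

from .molio import GraphTensors, NUM_ATOM_TYPES
from .nn import autograd as ag
from .nn.autograd import Parameter, Tensor

CHECKPOINT_VERSION = 1

N_CHIRALITY = 4
N_BOND_TYPES = 4
N_BOND_DIRS = 3


@dataclass(frozen=True)
class EncoderConfig:
    n_layers: int = 5
    hidden_dim: int = 300
    dropout: float = 0.0
    readout: str = "mean"

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("n_layers and hidden_dim must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.readout not in ("mean", "sum", "max"):
            raise ValueError(f"unknown readout {self.readout!r}")


@dataclass
class GraphBatch:
    """A disjoint union of featurized graphs."""

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray
    node2graph: np.ndarray
    n_graphs: int

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


def batch_graphs(tensors: Sequence[GraphTensors]) -> GraphBatch:
    """Concatenate graphs with node-index offsets into one batch."""
    nf, ei, ef, seg = [], [], [], []
    offset = 0
    for g, gt in enumerate(tensors):
        nf.append(gt.node_features)
        ei.append(gt.edge_index + offset)
        ef.append(gt.edge_features)
        seg.append(np.full(gt.n_nodes, g, dtype=np.int64))
        offset += gt.n_nodes
    return GraphBatch(
        node_features=np.concatenate(nf, axis=0),
        edge_index=np.concatenate(ei, axis=1) if ei else np.zeros((2, 0), dtype=np.int64),
        edge_features=np.concatenate(ef, axis=0) if ef else np.zeros((0, 2), dtype=np.int64),
        node2graph=np.concatenate(seg),
        n_graphs=len(tensors),
    )


class GINLayer:
    """One GIN message-passing layer with typed-edge embeddings."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.bond_emb = Parameter(ag.xavier_uniform(rng, N_BOND_TYPES, dim, (N_BOND_TYPES, dim)))
        self.bdir_emb = Parameter(ag.xavier_uniform(rng, N_BOND_DIRS, dim, (N_BOND_DIRS, dim)))
        self.w1 = Parameter(ag.xavier_uniform(rng, dim, dim))
        self.b1 = Parameter(np.zeros(dim))
        self.w2 = Parameter(ag.xavier_uniform(rng, dim, dim))
        self.b2 = Parameter(np.zeros(dim))
        self.bn_gamma = Parameter(np.ones(dim))
        self.bn_beta = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def parameters(self) -> List[Parameter]:
        return [self.bond_emb, self.bdir_emb, self.w1, self.b1, self.w2, self.b2,
                self.bn_gamma, self.bn_beta]

    def forward(self, h: Tensor, batch: GraphBatch, training: bool) -> Tensor:
        src, dst = batch.edge_index
        edge = ag.embedding(self.bond_emb, batch.edge_features[:, 0]) + ag.embedding(
            self.bdir_emb, batch.edge_features[:, 1]
        )
        messages = ag.gather_rows(h, src) + edge
        agg = ag.segment_sum(messages, dst, batch.n_nodes)
        pre = h + agg
        hidden = ag.linear(pre, self.w1, self.b1).relu()
        out = ag.linear(hidden, self.w2, self.b2)
        return ag.batch_norm(
            out, self.bn_gamma, self.bn_beta,
            self.running_mean, self.running_var, training,
        )


class GINEncoder:
    """Stacked GIN layers over atom/chirality/bond index features.

    Deterministic given the construction seed and inputs; dropout draws come
    from the generator passed to :meth:`forward`.
    """

    def __init__(self, config: EncoderConfig = EncoderConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.hidden_dim
        self.atom_emb = Parameter(ag.xavier_uniform(rng, NUM_ATOM_TYPES, d, (NUM_ATOM_TYPES, d)))
        self.chir_emb = Parameter(ag.xavier_uniform(rng, N_CHIRALITY, d, (N_CHIRALITY, d)))
        self.layers = [GINLayer(d, rng) for _ in range(config.n_layers)]

    def parameters(self) -> List[Parameter]:
        ps = [self.atom_emb, self.chir_emb]
        for layer in self.layers:
            ps.extend(layer.parameters())
        return ps

    def forward(
        self,
        batch: GraphBatch,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        """Node embeddings after the final layer, shape (n_nodes, hidden_dim)."""
        if rng is None:
            rng = np.random.default_rng(0)
        h = ag.embedding(self.atom_emb, batch.node_features[:, 0]) + ag.embedding(
            self.chir_emb, batch.node_features[:, 1]
        )
        last = len(self.layers) - 1
        for j, layer in enumerate(self.layers):
            h = layer.forward(h, batch, training)
            if j != last:
                h = h.relu()
            h = ag.dropout(h, self.config.dropout, rng, training)
        return h

    def encode(self, gt: GraphTensors, training: bool = False) -> Tensor:
        return self.forward(batch_graphs([gt]), training=training)


def readout(node_embeddings: Tensor, batch: GraphBatch, method: str = "mean") -> Tensor:
    """Pool per-node embeddings into per-graph embeddings (permutation invariant)."""
    if batch.n_nodes == 0:
        raise ValueError("cannot pool an empty node set")
    if method == "mean":
        return ag.segment_mean(node_embeddings, batch.node2graph, batch.n_graphs)
    if method == "sum":
        return ag.segment_sum(node_embeddings, batch.node2graph, batch.n_graphs)
    if method == "max":
        return ag.segment_max(node_embeddings, batch.node2graph, batch.n_graphs)
    raise ValueError(f"unknown readout {method!r}")


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _named_arrays(encoder: GINEncoder) -> dict:
    arrs = {"atom_emb": encoder.atom_emb.data, "chir_emb": encoder.chir_emb.data}
    for i, layer in enumerate(encoder.layers):
        for name in ("bond_emb", "bdir_emb", "w1", "b1", "w2", "b2", "bn_gamma", "bn_beta"):
            arrs[f"layer{i}.{name}"] = getattr(layer, name).data
        arrs[f"layer{i}.running_mean"] = layer.running_mean
        arrs[f"layer{i}.running_var"] = layer.running_var
    return arrs


def save_checkpoint(path, encoder: GINEncoder, extra: Optional[dict] = None) -> None:
    """Save encoder parameters in a self-describing single-file format."""
    header = {
        "format": "molmask-checkpoint",
        "version": CHECKPOINT_VERSION,
        "config": asdict(encoder.config),
        "extra": extra or {},
    }
    arrays = _named_arrays(encoder)
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path, config: Optional[EncoderConfig] = None) -> GINEncoder:
    """Load an encoder; validates header and (optionally) config compatibility."""
    import os

    path = str(path)
    if not os.path.exists(path) and os.path.exists(path + ".npz"):
        path = path + ".npz"
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"].tobytes()).decode())
        if header.get("format") != "molmask-checkpoint":
            raise ValueError("not a molmask checkpoint file")
        if header.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header.get('version')}")
        saved_cfg = EncoderConfig(**header["config"])
        if config is not None and config != saved_cfg:
            raise ValueError(f"config mismatch: file has {saved_cfg}, requested {config}")
        enc = GINEncoder(saved_cfg, seed=0)
        enc.atom_emb.data = data["atom_emb"].copy()
        enc.chir_emb.data = data["chir_emb"].copy()
        for i, layer in enumerate(enc.layers):
            for name in ("bond_emb", "bdir_emb", "w1", "b1", "w2", "b2",
                         "bn_gamma", "bn_beta"):
                getattr(layer, name).data = data[f"layer{i}.{name}"].copy()
            layer.running_mean = data[f"layer{i}.running_mean"].copy()
            layer.running_var = data[f"layer{i}.running_var"].copy()
    return enc
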