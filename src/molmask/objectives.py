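"""Node-level self-supervised objectives: masked-atom classification and
masked-autoencoder node-feature reconstruction.

Both objectives score only the masked positions.  The classification task
(AttrMask style) puts a linear head over the atom-type vocabulary on the
masked-node embeddings and minimizes mean cross-entropy.  The autoencoder
task (GraphMAE style) re-masks the masked-node embeddings with a learned
vector, decodes through one additional GIN layer, and reconstructs the
atom-type of each masked node — cross-entropy by default (atom types are
categorical), with a scaled-cosine-error variant available for lineage
comparability with continuous-feature reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .encoder import GINEncoder, GINLayer, GraphBatch
from .molio import NUM_ATOM_TYPES
from .nn import autograd as ag
from .nn.autograd import Parameter, Tensor


@dataclass
class PretrainBatchResult:
    """Loss plus masked-atom prediction bookkeeping for one batch."""

    loss: Tensor
    masked_atom_accuracy: float
    n_masked: int

    def __post_init__(self):
        if self.n_masked < 1:
            raise ValueError("a pretraining batch must mask at least one atom")
        if not np.isfinite(self.loss.data):
            raise ValueError("non-finite loss")


class AttrMaskHead:
    """Linear classifier over the atom-type vocabulary."""

    def __init__(self, hidden_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w = Parameter(ag.xavier_uniform(rng, hidden_dim, NUM_ATOM_TYPES))
        self.b = Parameter(np.zeros(NUM_ATOM_TYPES))

    def parameters(self) -> List[Parameter]:
        return [self.w, self.b]

    def logits(self, embeddings: Tensor) -> Tensor:
        return ag.linear(embeddings, self.w, self.b)


def attrmask_objective(
    node_embeddings: Tensor,
    masked_indices: np.ndarray,
    targets: np.ndarray,
    head: AttrMaskHead,
) -> PretrainBatchResult:
    """Cross-entropy on masked-node atom-type predictions.

    ``masked_indices`` index rows of ``node_embeddings`` (batch-global);
    ``targets`` are the original atom-type indices at those rows, in the same
    order.
    """
    masked_indices = np.asarray(masked_indices, dtype=np.int64)
    targets = np.asarray(targets, dtype=np.int64)
    if masked_indices.size == 0:
        raise ValueError("no masked nodes")
    if masked_indices.size != targets.size:
        raise ValueError("targets must cover exactly the masked indices")
    logits = head.logits(ag.gather_rows(node_embeddings, masked_indices))
    loss = ag.cross_entropy(logits, targets)
    pred = logits.data.argmax(axis=1)
    acc = float((pred == targets).mean())
    return PretrainBatchResult(loss=loss, masked_atom_accuracy=acc, n_masked=targets.size)


class GraphMAEDecoder:
    """Re-mask vector + one GIN decode layer + linear reconstruction head."""

    def __init__(self, hidden_dim: int, seed: int = 0, loss_type: str = "cross_entropy",
                 sce_gamma: float = 2.0):
        if loss_type not in ("cross_entropy", "scaled_cosine"):
            raise ValueError(f"unknown loss_type {loss_type!r}")
        rng = np.random.default_rng(seed)
        self.mask_vec = Parameter(np.zeros(hidden_dim))
        self.gin = GINLayer(hidden_dim, rng)
        self.w_out = Parameter(ag.xavier_uniform(rng, hidden_dim, NUM_ATOM_TYPES))
        self.b_out = Parameter(np.zeros(NUM_ATOM_TYPES))
        self.loss_type = loss_type
        self.sce_gamma = sce_gamma

    def parameters(self) -> List[Parameter]:
        return [self.mask_vec, *self.gin.parameters(), self.w_out, self.b_out]


def graphmae_objective(
    corrupted_batch: GraphBatch,
    masked_indices: np.ndarray,
    targets: np.ndarray,
    encoder: GINEncoder,
    decoder: GraphMAEDecoder,
    training: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> PretrainBatchResult:
    """Masked-autoencoder reconstruction of masked-node atom types.

    Encodes the corrupted batch, replaces masked-node embeddings with the
    decoder's learned mask vector (re-masking), runs one GIN decode layer,
    and scores the reconstruction at masked positions only.
    """
    masked_indices = np.asarray(masked_indices, dtype=np.int64)
    targets = np.asarray(targets, dtype=np.int64)
    if masked_indices.size == 0:
        raise ValueError("no masked nodes")
    if masked_indices.size != targets.size:
        raise ValueError("targets must cover exactly the masked indices")
    h = encoder.forward(corrupted_batch, training=training, rng=rng)
    h = ag.replace_rows(h, masked_indices, decoder.mask_vec)
    dec = decoder.gin.forward(h, corrupted_batch, training)
    logits = ag.linear(ag.gather_rows(dec, masked_indices), decoder.w_out, decoder.b_out)
    if decoder.loss_type == "cross_entropy":
        loss = ag.cross_entropy(logits, targets)
    else:
        onehot = np.eye(NUM_ATOM_TYPES)[targets]
        loss = ag.scaled_cosine_error(logits, onehot, gamma=decoder.sce_gamma)
    pred = logits.data.argmax(axis=1)
    acc = float((pred == targets).mean())
    return PretrainBatchResult(loss=loss, masked_atom_accuracy=acc, n_masked=targets.size)
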