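"""Pretraining and transfer-learning pipelines.

The two estimators are the primary interface:

* :class:`MaskedAtomPretrainer` — fits a GIN encoder with a node-level
  self-supervised objective (masked-atom classification or masked-autoencoder
  reconstruction) under either uniform-random or frequency-weighted (WMM)
  atom masking; ``transform`` yields pooled graph embeddings.
* :class:`GraphPropertyClassifier` — multi-task binary property predictor on
  top of a (pretrained) encoder, trained with missing-label masking and
  optional best-validation-epoch selection.

Module-level functions (``pretrain``, ``scaffold_split``, ``finetune``,
``compare_strategies``) wrap the estimators into the standard evaluation
protocol: Bemis–Murcko scaffold splitting 80/10/10, fine-tuning over several
seeds, test ROC-AUC taken at the best-validation epoch, aggregated as
mean ± standard deviation.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import roc_auc_score

from . import masking
from .encoder import (
    EncoderConfig,
    GINEncoder,
    GraphBatch,
    batch_graphs,
    readout,
    save_checkpoint,
)
from .masking import WMMConfig, apply_mask, sample_mask_random, sample_mask_wmm
from .molio import MolGraph, featurize, parse_smiles, to_rdkit
from .nn import autograd as ag
from .nn.autograd import Adam, Parameter
from .objectives import (
    AttrMaskHead,
    GraphMAEDecoder,
    attrmask_objective,
    graphmae_objective,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters shared by pretraining and fine-tuning runs.

    Stage defaults follow the standard protocol of the AttrMask lineage:
    pretraining 100 epochs, batch 256, dropout 0.0; fine-tuning 100 epochs,
    batch 32, dropout 0.5; Adam with learning rate 1e-3 in both stages.
    ``desk_scale`` shrinks the model and corpus for laptop-speed runs.
    """

    epochs: int = 100
    batch_size: int = 256
    learning_rate: float = 1e-3
    dropout: float = 0.0
    mask_ratio: Optional[float] = None
    strategy: str = "random"
    k: float = 0.9
    seed: int = 0
    objective: str = "attrmask"
    hidden_dim: int = 300
    n_layers: int = 5

    @classmethod
    def pretrain_defaults(cls, **kw) -> "TrainConfig":
        return cls(**{**dict(epochs=100, batch_size=256, dropout=0.0), **kw})

    @classmethod
    def finetune_defaults(cls, **kw) -> "TrainConfig":
        return cls(**{**dict(epochs=100, batch_size=32, dropout=0.5), **kw})

    @classmethod
    def desk_scale(cls, **kw) -> "TrainConfig":
        """Small preset (hidden_dim 64, 3 layers, short runs) for desk-scale work."""
        return cls(**{**dict(epochs=30, batch_size=32, hidden_dim=64, n_layers=3), **kw})


@dataclass
class AccuracyCurve:
    """Per-epoch mean masked-atom accuracy and loss during pretraining."""

    records: List[Tuple[int, float, float]] = field(default_factory=list)

    def append(self, epoch: int, accuracy: float, loss: float) -> None:
        if not (0.0 <= accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")
        self.records.append((epoch, accuracy, loss))

    @property
    def final_accuracy(self) -> float:
        return self.records[-1][1]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records, columns=["epoch", "accuracy", "loss"])


@dataclass(frozen=True)
class SplitResult:
    train: tuple
    valid: tuple
    test: tuple
    method: str = "scaffold"

    def __post_init__(self):
        all_idx = (*self.train, *self.valid, *self.test)
        if len(set(all_idx)) != len(all_idx):
            raise ValueError("split partitions overlap")


class SplitError(ValueError):
    pass


def _as_molgraphs(X) -> List[MolGraph]:
    return [x if isinstance(x, MolGraph) else parse_smiles(x) for x in X]


def murcko_scaffold_smiles(mol: MolGraph) -> str:
    """Canonical Bemis–Murcko scaffold SMILES ('' for acyclic molecules)."""
    return MurckoScaffold.MurckoScaffoldSmiles(mol=to_rdkit(mol))


def scaffold_split(
    dataset: Sequence, fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> SplitResult:
    """Deterministic greedy scaffold split.

    Molecules are grouped by Bemis–Murcko scaffold; groups are ordered by
    size (largest first, ties by first occurrence) and filled into
    train/valid/test toward the target fractions.  A whole group goes to
    train while it fits; a group exceeding train's remaining capacity goes
    to whichever later partition is least filled relative to its capacity
    (ties toward valid), so no scaffold is ever split across partitions and
    the small partitions fill evenly.
    """
    mols = _as_molgraphs(dataset)
    n = len(mols)
    groups: Dict[str, List[int]] = {}
    order: List[str] = []
    for i, mol in enumerate(mols):
        key = murcko_scaffold_smiles(mol)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
    if len(groups) < 3:
        raise SplitError(
            f"only {len(groups)} scaffold group(s); cannot form three partitions"
        )
    first_seen = {key: j for j, key in enumerate(order)}
    ordered = sorted(groups, key=lambda key: (-len(groups[key]), first_seen[key]))

    caps = [int(round(f * n)) for f in fractions]
    caps[0] += n - sum(caps)  # largest partition absorbs rounding residue
    parts: List[List[int]] = [[], [], []]
    for key in ordered:
        g = groups[key]
        if len(parts[0]) + len(g) <= caps[0]:
            parts[0].extend(g)
        else:
            later = max((1, 2), key=lambda p: (caps[p] - len(parts[p]), -p))
            parts[later].extend(g)
    return SplitResult(tuple(parts[0]), tuple(parts[1]), tuple(parts[2]))


# ---------------------------------------------------------------------------
# pretraining
# ---------------------------------------------------------------------------

class MaskedAtomPretrainer(BaseEstimator, TransformerMixin):
    """Self-supervised pretrainer for molecular-graph encoders.

    Parameters mirror the standard protocol; ``strategy`` selects uniform
    random masking or the frequency-weighted scheme (``"wmm"``) with
    hyperparameter ``k``; ``mask_ratio`` defaults to 0.15 for the
    classification objective and 0.25 for the autoencoder objective.  Masks
    are resampled independently for every molecule in every epoch.

    Fitted attributes: ``encoder_``, ``head_`` (classification) or
    ``decoder_`` (autoencoder), and ``accuracy_curve_``.
    """

    def __init__(
        self,
        objective: str = "attrmask",
        strategy: str = "random",
        k: float = 0.9,
        mask_ratio: Optional[float] = None,
        n_layers: int = 5,
        hidden_dim: int = 300,
        epochs: int = 100,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        dropout: float = 0.0,
        readout: str = "mean",
        graphmae_loss: str = "cross_entropy",
        seed: int = 0,
    ):
        self.objective = objective
        self.strategy = strategy
        self.k = k
        self.mask_ratio = mask_ratio
        self.n_layers = n_layers
        self.hidden_dim = hidden_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.readout = readout
        self.graphmae_loss = graphmae_loss
        self.seed = seed

    # -- internals ----------------------------------------------------------
    def _effective_mask_ratio(self) -> float:
        if self.mask_ratio is not None:
            return self.mask_ratio
        return 0.25 if self.objective == "graphmae" else 0.15

    def _sample_plan(self, mol: MolGraph, rng) -> masking.MaskPlan:
        if self.strategy == "wmm":
            cfg = WMMConfig(k=self.k, mask_ratio=self._effective_mask_ratio())
            return sample_mask_wmm(mol, cfg, rng)
        if self.strategy == "random":
            return sample_mask_random(mol, self._effective_mask_ratio(), rng)
        raise ValueError(f"unknown strategy {self.strategy!r}")

    def fit(self, X, y=None):
        """Pretrain on an unlabeled corpus of molecules (SMILES or MolGraph)."""
        if self.objective not in ("attrmask", "graphmae"):
            raise ValueError(f"unknown objective {self.objective!r}")
        mols = _as_molgraphs(X)
        if not mols:
            raise ValueError("empty corpus")
        tensors = [featurize(m) for m in mols]
        cfg = EncoderConfig(
            n_layers=self.n_layers,
            hidden_dim=self.hidden_dim,
            dropout=self.dropout,
            readout=self.readout,
        )
        encoder = GINEncoder(cfg, seed=self.seed)
        params: List[Parameter] = encoder.parameters()
        head = decoder = None
        if self.objective == "attrmask":
            head = AttrMaskHead(self.hidden_dim, seed=self.seed + 1)
            params = params + head.parameters()
        else:
            decoder = GraphMAEDecoder(
                self.hidden_dim, seed=self.seed + 1, loss_type=self.graphmae_loss
            )
            params = params + decoder.parameters()
        opt = Adam(params, lr=self.learning_rate)
        rng = np.random.default_rng(self.seed)
        curve = AccuracyCurve()
        n = len(mols)
        for epoch in range(1, self.epochs + 1):
            perm = rng.permutation(n)
            tot_correct = tot_masked = 0
            tot_loss = 0.0
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                batch_tensors, masked_global, targets = [], [], []
                offset = 0
                for i in idx:
                    plan = self._sample_plan(mols[i], rng)
                    corrupted, tgt = apply_mask(tensors[i], plan)
                    batch_tensors.append(corrupted)
                    masked_global.extend(offset + j for j in plan.masked_indices)
                    targets.extend(tgt.tolist())
                    offset += corrupted.n_nodes
                batch = batch_graphs(batch_tensors)
                masked_global = np.array(masked_global, dtype=np.int64)
                targets_arr = np.array(targets, dtype=np.int64)
                if self.objective == "attrmask":
                    h = encoder.forward(batch, training=True, rng=rng)
                    res = attrmask_objective(h, masked_global, targets_arr, head)
                else:
                    res = graphmae_objective(
                        batch, masked_global, targets_arr, encoder, decoder,
                        training=True, rng=rng,
                    )
                opt.zero_grad()
                res.loss.backward()
                opt.step()
                tot_correct += res.masked_atom_accuracy * res.n_masked
                tot_masked += res.n_masked
                tot_loss += float(res.loss.data)
                n_batches += 1
            curve.append(epoch, tot_correct / tot_masked, tot_loss / n_batches)
        self.encoder_ = encoder
        self.head_ = head
        self.decoder_ = decoder
        self.accuracy_curve_ = curve
        self.n_features_out_ = self.hidden_dim
        return self

    def transform(self, X) -> np.ndarray:
        """Pooled graph embeddings of shape (n_molecules, hidden_dim)."""
        if not hasattr(self, "encoder_"):
            raise RuntimeError("pretrainer is not fitted")
        mols = _as_molgraphs(X)
        batch = batch_graphs([featurize(m) for m in mols])
        h = self.encoder_.forward(batch, training=False)
        return readout(h, batch, self.readout).data.copy()

    def save(self, path) -> None:
        save_checkpoint(
            path,
            self.encoder_,
            extra={
                "objective": self.objective,
                "strategy": self.strategy,
                "k": self.k,
                "mask_ratio": self._effective_mask_ratio(),
                "seed": self.seed,
            },
        )


def pretrain(corpus, config: TrainConfig) -> Tuple[MaskedAtomPretrainer, AccuracyCurve]:
    """Functional wrapper: pretrain an encoder on a corpus per the config."""
    est = MaskedAtomPretrainer(
        objective=config.objective,
        strategy=config.strategy,
        k=config.k,
        mask_ratio=config.mask_ratio,
        n_layers=config.n_layers,
        hidden_dim=config.hidden_dim,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        dropout=config.dropout,
        seed=config.seed,
    )
    est.fit(corpus)
    return est, est.accuracy_curve_


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def _mean_task_auc(scores: np.ndarray, labels: np.ndarray) -> Optional[float]:
    """Mean ROC-AUC over tasks with both classes present (others skipped)."""
    aucs = []
    for t in range(labels.shape[1]):
        valid = ~np.isnan(labels[:, t])
        y = labels[valid, t]
        if valid.sum() == 0 or len(np.unique(y)) < 2:
            logger.warning("task %d has a single class in this set; excluded", t)
            continue
        aucs.append(roc_auc_score(y, scores[valid, t]))
    return float(np.mean(aucs)) if aucs else None


class GraphPropertyClassifier(BaseEstimator):
    """Multi-task binary molecular property predictor.

    A linear per-task head over the pooled graph embedding, trained jointly
    with the (optionally pretrained) encoder; missing labels (NaN) are
    excluded from the loss via a validity mask.  When validation data is
    supplied to :meth:`fit`, parameters are restored to the epoch with the
    best validation ROC-AUC (ties toward the earlier epoch), and the
    per-epoch history is kept in ``history_``.
    """

    def __init__(
        self,
        pretrained: Optional[MaskedAtomPretrainer] = None,
        n_layers: int = 5,
        hidden_dim: int = 300,
        epochs: int = 100,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        dropout: float = 0.5,
        readout: str = "mean",
        seed: int = 0,
    ):
        self.pretrained = pretrained
        self.n_layers = n_layers
        self.hidden_dim = hidden_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.readout = readout
        self.seed = seed

    def _init_encoder(self) -> GINEncoder:
        if self.pretrained is not None:
            src = self.pretrained
            enc = copy.deepcopy(getattr(src, "encoder_", src))
        else:
            enc = GINEncoder(
                EncoderConfig(n_layers=self.n_layers, hidden_dim=self.hidden_dim),
                seed=self.seed,
            )
        enc.config = replace(enc.config, dropout=self.dropout)
        return enc

    def _scores(self, tensors: List, idx: Sequence[int]) -> np.ndarray:
        batch = batch_graphs([tensors[i] for i in idx])
        h = self.encoder_.forward(batch, training=False)
        g = readout(h, batch, self.readout)
        logits = ag.linear(g, self.w_, self.b_)
        return 1.0 / (1.0 + np.exp(-logits.data))

    def fit(self, X, y, validation_data: Optional[Tuple] = None):
        mols = _as_molgraphs(X)
        labels = np.atleast_2d(np.asarray(y, dtype=float))
        if labels.shape[0] != len(mols):
            labels = labels.T
        n_tasks = labels.shape[1]
        tensors = [featurize(m) for m in mols]
        self.encoder_ = self._init_encoder()
        rng = np.random.default_rng(self.seed)
        d = self.encoder_.config.hidden_dim
        self.w_ = Parameter(ag.xavier_uniform(rng, d, n_tasks))
        self.b_ = Parameter(np.zeros(n_tasks))
        params = self.encoder_.parameters() + [self.w_, self.b_]
        opt = Adam(params, lr=self.learning_rate)

        val_tensors = val_labels = None
        if validation_data is not None:
            vmols = _as_molgraphs(validation_data[0])
            val_labels = np.atleast_2d(np.asarray(validation_data[1], dtype=float))
            if val_labels.shape[0] != len(vmols):
                val_labels = val_labels.T
            val_tensors = [featurize(m) for m in vmols]

        history: List[dict] = []
        best_auc, best_epoch, best_state = -np.inf, None, None
        n = len(mols)
        for epoch in range(1, self.epochs + 1):
            perm = rng.permutation(n)
            ep_loss, nb = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                batch = batch_graphs([tensors[i] for i in idx])
                yb = labels[idx]
                h = self.encoder_.forward(batch, training=True, rng=rng)
                g = readout(h, batch, self.readout)
                logits = ag.linear(g, self.w_, self.b_)
                loss = ag.bce_with_logits_masked(logits, yb, ~np.isnan(yb))
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep_loss += float(loss.data)
                nb += 1
            rec = {"epoch": epoch, "train_loss": ep_loss / nb}
            if val_tensors is not None:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    scores = self._scores(val_tensors, range(len(val_tensors)))
                val_auc = _mean_task_auc(scores, val_labels)
                rec["valid_auc"] = val_auc
                if val_auc is not None and val_auc > best_auc:
                    best_auc, best_epoch = val_auc, epoch
                    best_state = ([p.data.copy() for p in params],
                                  [(l.running_mean.copy(), l.running_var.copy())
                                   for l in self.encoder_.layers])
            history.append(rec)
        if best_state is not None:
            for p, data in zip(params, best_state[0]):
                p.data = data
            for layer, (rm, rv) in zip(self.encoder_.layers, best_state[1]):
                layer.running_mean, layer.running_var = rm, rv
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_valid_auc_ = None if best_epoch is None else best_auc
        self.n_tasks_ = n_tasks
        self.classes_ = np.array([0.0, 1.0])
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-task probability of the positive class, shape (n, n_tasks)."""
        mols = _as_molgraphs(X)
        tensors = [featurize(m) for m in mols]
        return self._scores(tensors, range(len(tensors)))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(float)

    def score_auc(self, X, y) -> Optional[float]:
        labels = np.atleast_2d(np.asarray(y, dtype=float))
        if labels.shape[0] != len(list(X)):
            labels = labels.T
        return _mean_task_auc(self.predict_proba(X), labels)


def finetune(
    pretrained: Optional[MaskedAtomPretrainer],
    mols,
    labels,
    config: TrainConfig,
    seeds: Sequence[int] = tuple(range(10)),
    split: Optional[SplitResult] = None,
) -> dict:
    """Scaffold-split fine-tuning over several seeds.

    For each seed, a classifier (optionally initialized from the pretrained
    encoder) is trained on the train partition; per epoch the validation
    ROC-AUC is computed and the reported test ROC-AUC is the one at the
    best-validation epoch.  Returns per-seed results plus mean ± std.
    """
    mols = _as_molgraphs(mols)
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    if labels.shape[0] != len(mols):
        labels = labels.T
    if split is None:
        split = scaffold_split(mols)
    tr, va, te = list(split.train), list(split.valid), list(split.test)
    results = []
    for seed in seeds:
        clf = GraphPropertyClassifier(
            pretrained=pretrained,
            n_layers=config.n_layers,
            hidden_dim=config.hidden_dim,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            dropout=config.dropout,
            seed=seed,
        )
        clf.fit(
            [mols[i] for i in tr], labels[tr],
            validation_data=([mols[i] for i in va], labels[va]),
        )
        test_auc = clf.score_auc([mols[i] for i in te], labels[te]) if te else None
        results.append(
            {
                "seed": seed,
                "best_epoch": clf.best_epoch_,
                "valid_auc": clf.best_valid_auc_,
                "test_auc": test_auc,
                "history": clf.history_,
            }
        )
    test_aucs = [r["test_auc"] for r in results if r["test_auc"] is not None]
    return {
        "per_seed": results,
        "mean_test_auc": float(np.mean(test_aucs)) if test_aucs else None,
        "std_test_auc": float(np.std(test_aucs)) if test_aucs else None,
        "split": split,
    }


# ---------------------------------------------------------------------------
# strategy comparison
# ---------------------------------------------------------------------------

def compare_strategies(
    corpus,
    datasets: Dict[str, Tuple[Sequence, np.ndarray]],
    arms: Sequence[dict],
    pretrain_config: TrainConfig,
    finetune_config: TrainConfig,
    seeds: Sequence[int] = (0, 1, 2),
):
    """Pretrain + fine-tune each strategy arm and tabulate test ROC-AUCs.

    ``arms`` are dicts overriding pretraining fields, e.g.
    ``{"label": "AttrMask(WMM)", "objective": "attrmask", "strategy": "wmm",
    "k": 0.9}``.  Returns a DataFrame with one row per arm, one
    ``mean ± std`` column per dataset, and an ``avg.`` column of dataset
    means, matching the usual benchmark-table layout.
    """
    import pandas as pd

    if len(arms) < 2:
        raise ValueError("need at least two strategy arms to compare")
    rows = {}
    for arm in arms:
        label = arm.get("label") or f"{arm.get('objective', 'attrmask')}({arm.get('strategy', 'random')})"
        overrides = {k: v for k, v in arm.items() if k != "label"}
        pcfg = replace(pretrain_config, **overrides)
        est, _ = pretrain(corpus, pcfg)
        row = {}
        means = []
        for name, (mols, labels) in datasets.items():
            res = finetune(est, mols, labels, finetune_config, seeds=seeds)
            mean = res["mean_test_auc"]
            std = res["std_test_auc"]
            row[name] = f"{100 * mean:.1f} ± {100 * std:.1f}" if mean is not None else "n/a"
            if mean is not None:
                means.append(mean)
        row["avg."] = f"{100 * float(np.mean(means)):.2f}" if means else "n/a"
        rows[label] = row
    return pd.DataFrame(rows).T
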