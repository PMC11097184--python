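import numpy as np
import pytest
from sklearn.base import clone

import molmask as mm
from molmask.training import (
    GraphPropertyClassifier,
    MaskedAtomPretrainer,
    SplitError,
    TrainConfig,
    _mean_task_auc,
    murcko_scaffold_smiles,
    scaffold_split,
)

TINY = dict(n_layers=2, hidden_dim=16, epochs=2, batch_size=16)


# ---------------------------------------------------------------------------
# pretraining loop
# ---------------------------------------------------------------------------

def test_pretrain_curve_has_one_record_per_epoch(corpus150):
    est = MaskedAtomPretrainer(seed=0, **TINY).fit(corpus150[:10])
    assert [e for e, _, _ in est.accuracy_curve_.records] == [1, 2]
    assert all(0 <= a <= 1 for _, a, _ in est.accuracy_curve_.records)


def test_pretrain_deterministic(corpus150):
    a = MaskedAtomPretrainer(strategy="wmm", k=0.9, seed=1, **TINY).fit(corpus150[:20])
    b = MaskedAtomPretrainer(strategy="wmm", k=0.9, seed=1, **TINY).fit(corpus150[:20])
    assert a.accuracy_curve_.records == b.accuracy_curve_.records
    assert np.array_equal(a.encoder_.atom_emb.data, b.encoder_.atom_emb.data)


def test_pretrain_rejects_bad_inputs():
    with pytest.raises(ValueError):
        MaskedAtomPretrainer(**TINY).fit([])
    with pytest.raises(ValueError):
        MaskedAtomPretrainer(objective="mam", **TINY).fit(["CCO"])
    with pytest.raises(ValueError):
        MaskedAtomPretrainer(strategy="learned", **TINY).fit(["CCO", "CC", "CCC", "C"])


def test_pretrainer_is_sklearn_compatible(corpus150):
    est = MaskedAtomPretrainer(strategy="wmm", **TINY)
    cloned = clone(est)
    assert cloned.get_params()["strategy"] == "wmm"
    est.set_params(k=1.1)
    assert est.k == 1.1
    est.fit(corpus150[:10])
    emb = est.transform(corpus150[:5])
    assert emb.shape == (5, 16)


def test_default_mask_ratio_follows_objective():
    assert MaskedAtomPretrainer(objective="attrmask")._effective_mask_ratio() == 0.15
    assert MaskedAtomPretrainer(objective="graphmae")._effective_mask_ratio() == 0.25
    assert MaskedAtomPretrainer(mask_ratio=0.3)._effective_mask_ratio() == 0.3


def test_pretrain_functional_wrapper(corpus150):
    cfg = TrainConfig(epochs=2, batch_size=16, hidden_dim=16, n_layers=2, seed=0)
    est, curve = mm.pretrain(corpus150[:10], cfg)
    assert curve is est.accuracy_curve_
    assert len(curve.records) == 2


# ---------------------------------------------------------------------------
# scaffold split
# ---------------------------------------------------------------------------

def test_split_ten_distinct_scaffolds(ten_scaffold_smiles):
    sp = scaffold_split(ten_scaffold_smiles)
    assert (len(sp.train), len(sp.valid), len(sp.test)) == (8, 1, 1)


def test_split_hand_traced_group_sizes_5_2_2_1():
    """Greedy fill with groups (5,2,2,1) into capacities (8,1,1)."""
    smis = [
        "c1ccccc1C", "c1ccccc1CC", "c1ccccc1O", "c1ccccc1N", "c1ccccc1F",  # 5
        "c1ccncc1C", "c1ccncc1O",                                          # 2
        "C1CCCCC1C", "C1CCCCC1O",                                          # 2
        "c1ccc2ccccc2c1",                                                  # 1
    ]
    sp = scaffold_split(smis)
    # size-5 benzene group and first size-2 group fit train; second size-2
    # group overflows to the least-filled later partition (valid); the
    # singleton then still fits train.  No scaffold is split.
    assert sp.train == (0, 1, 2, 3, 4, 5, 6, 9)
    assert sp.valid == (7, 8)
    assert sp.test == ()


def test_split_errors_on_too_few_scaffolds():
    same = ["c1ccccc1C", "c1ccccc1O", "c1ccccc1N"]
    with pytest.raises(SplitError):
        scaffold_split(same)


def test_split_partitions_disjoint_exhaustive_scaffold_atomic(corpus150):
    sp = scaffold_split(corpus150)
    n = len(corpus150)
    all_idx = sorted(sp.train + sp.valid + sp.test)
    assert all_idx == list(range(n))
    assert abs(len(sp.train) - 0.8 * n) <= 1
    assert abs(len(sp.valid) - 0.1 * n) <= 1
    assert abs(len(sp.test) - 0.1 * n) <= 1
    part_of = {}
    for name, part in (("tr", sp.train), ("va", sp.valid), ("te", sp.test)):
        for i in part:
            part_of[i] = name
    scaff = [murcko_scaffold_smiles(m) for m in corpus150]
    for i in range(n):
        for j in range(i + 1, n):
            if scaff[i] == scaff[j]:
                assert part_of[i] == part_of[j]


# ---------------------------------------------------------------------------
# fine-tuning and evaluation
# ---------------------------------------------------------------------------

def test_mean_task_auc_perfect_and_chance():
    labels = np.array([[0.0], [0.0], [1.0], [1.0]])
    scores = np.array([[0.1], [0.2], [0.8], [0.9]])
    assert _mean_task_auc(scores, labels) == 1.0
    rng = np.random.default_rng(0)
    n = 20_000
    y = np.concatenate([np.zeros((n, 1)), np.ones((n, 1))])
    s = rng.random((2 * n, 1))
    assert _mean_task_auc(s, y) == pytest.approx(0.5, abs=0.02)


def test_mean_task_auc_skips_single_class_tasks():
    labels = np.array([[1.0, 0.0], [1.0, 1.0]])
    scores = np.array([[0.3, 0.2], [0.9, 0.8]])
    assert _mean_task_auc(scores, labels) == 1.0  # task 0 excluded


def test_classifier_restores_best_validation_epoch(labeled_dataset):
    mols, labels = labeled_dataset
    clf = GraphPropertyClassifier(pretrained=None, n_layers=2, hidden_dim=16,
                                  epochs=4, batch_size=32, seed=0)
    clf.fit(mols[:80], labels[:80], validation_data=(mols[80:110], labels[80:110]))
    assert clf.best_epoch_ is not None
    recorded = [r["valid_auc"] for r in clf.history_ if r["valid_auc"] is not None]
    assert clf.best_valid_auc_ == max(recorded)
    # earlier epoch wins ties / argmax matches logged history
    best_from_history = min(
        (r["epoch"] for r in clf.history_ if r["valid_auc"] == clf.best_valid_auc_)
    )
    assert clf.best_epoch_ == best_from_history
    proba = clf.predict_proba(mols[:5])
    assert proba.shape == (5, 2)
    assert np.all((proba >= 0) & (proba <= 1))


def test_finetune_deterministic_and_aggregated(labeled_dataset):
    mols, labels = labeled_dataset
    pre = MaskedAtomPretrainer(seed=0, **TINY).fit(mols[:40])
    cfg = TrainConfig.finetune_defaults(epochs=3, hidden_dim=16, n_layers=2)
    r1 = mm.finetune(pre, mols, labels, cfg, seeds=(0, 1))
    r2 = mm.finetune(pre, mols, labels, cfg, seeds=(0, 1))
    assert r1["mean_test_auc"] == r2["mean_test_auc"]
    assert r1["std_test_auc"] == r2["std_test_auc"]
    per_seed = [r["test_auc"] for r in r1["per_seed"]]
    assert r1["mean_test_auc"] == pytest.approx(np.mean(per_seed))
    # reported test metric corresponds to the argmax-validation epoch
    for r in r1["per_seed"]:
        vals = [h["valid_auc"] for h in r["history"]]
        assert r["valid_auc"] == max(v for v in vals if v is not None)


def test_finetune_learns_composition_task(labeled_dataset):
    """Contains-N / contains-O labels are learnable well above chance."""
    mols, labels = labeled_dataset
    cfg = TrainConfig.finetune_defaults(epochs=8, hidden_dim=16, n_layers=2)
    res = mm.finetune(None, mols, labels, cfg, seeds=(0,))
    assert res["mean_test_auc"] is not None and res["mean_test_auc"] > 0.6


# ---------------------------------------------------------------------------
# strategy comparison
# ---------------------------------------------------------------------------

def _tiny_compare(corpus, labeled, arms, seeds=(0,)):
    mols, labels = labeled
    pre = TrainConfig(epochs=1, batch_size=32, hidden_dim=16, n_layers=2)
    fin = TrainConfig.finetune_defaults(epochs=2, batch_size=32, hidden_dim=16, n_layers=2)
    return mm.compare_strategies(
        corpus[:30], {"toy": (mols, labels)}, arms, pre, fin, seeds=seeds
    )


def test_compare_identical_arms_identical_rows(corpus150, labeled_dataset):
    arms = [
        {"label": "a", "strategy": "random"},
        {"label": "b", "strategy": "random"},
    ]
    table = _tiny_compare(corpus150, labeled_dataset, arms)
    assert table.shape[0] == 2
    assert (table.loc["a"] == table.loc["b"]).all()


def test_compare_k_sweep_row_count(corpus150, labeled_dataset):
    arms = [{"label": f"wmm-k{k}", "strategy": "wmm", "k": k} for k in (0.8, 0.9, 1.0)]
    table = _tiny_compare(corpus150, labeled_dataset, arms)
    assert list(table.index) == ["wmm-k0.8", "wmm-k0.9", "wmm-k1.0"]
    assert "avg." in table.columns


def test_compare_requires_two_arms(corpus150, labeled_dataset):
    with pytest.raises(ValueError):
        _tiny_compare(corpus150, labeled_dataset, [{"strategy": "random"}])
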