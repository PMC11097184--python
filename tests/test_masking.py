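import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import molmask as mm
from molmask.masking import TypeCounts, WMMConfig, draw_mask_indices, mask_budget
from molmask.molio import MASK_ATOM_INDEX

K_GRID = (0.8, 0.9, 1.0, 1.1, 1.2)


@pytest.mark.parametrize(
    "smiles,expected",
    [("CCO", {"C": 2, "O": 1}), ("c1ccccc1", {"C": 6}), ("FC(F)(F)F", {"C": 1, "F": 4})],
)
def test_count_atom_types(smiles, expected):
    tc = mm.count_atom_types(mm.parse_smiles(smiles))
    assert tc.counts == expected
    assert tc.total == sum(expected.values())


@pytest.mark.parametrize(
    "n,k,expected",
    [
        (1, 1.0, 0.6931471805599453),       # ln 2
        (10, 0.9, 0.22925347571405444),     # ln(9.9)/10
        (1, 0.8, 0.47000362924573563),      # ln(1.6)
        (2, 0.8, 0.4377343686769499),       # ln(2.4)/2
    ],
)
def test_atom_weight_frozen_values(n, k, expected):
    """Frozen high-precision evaluations of ln(k(n+1))/n."""
    assert mm.atom_weight(n, k) == pytest.approx(expected, rel=1e-12)


def test_atom_weight_rare_atoms_weigh_more():
    assert mm.atom_weight(1, 0.8) > mm.atom_weight(2, 0.8)


def test_atom_weight_domain_error():
    with pytest.raises(ValueError):
        mm.atom_weight(1, 0.4)  # k(n+1) = 0.8 <= 1
    with pytest.raises(ValueError):
        mm.atom_weight(0, 1.0)


@pytest.mark.parametrize("k", K_GRID)
def test_weight_strictly_decreasing_in_count(k):
    w = [mm.atom_weight(n, k) for n in range(1, 51)]
    assert all(a > b for a, b in zip(w, w[1:]))
    assert all(x > 0 for x in w)


def test_k_sensitivity_shrinks_with_count():
    """The k-induced spread of the weight decreases as the count grows."""
    spread = [mm.atom_weight(n, 1.2) - mm.atom_weight(n, 0.8) for n in range(1, 51)]
    assert all(a > b > 0 for a, b in zip(spread, spread[1:]))


def test_expected_masked_counts_frozen_example():
    m = mm.expected_masked_counts(TypeCounts({"C": 7, "O": 2, "N": 1}), M=2, k=0.9)
    assert m["C"] == pytest.approx(1.1105567877808054, rel=1e-12)
    assert m["O"] == pytest.approx(0.558772656213956, rel=1e-12)
    assert m["N"] == pytest.approx(0.33067055600523865, rel=1e-12)
    assert sum(m.values()) == pytest.approx(2.0, abs=1e-12)


def test_expected_masked_counts_degenerate_cases():
    for M in (1, 3, 6):
        assert mm.expected_masked_counts(TypeCounts({"C": 6}), M, 1.1) == {"C": M}
    m = mm.expected_masked_counts(TypeCounts({"C": 3, "O": 3}), 2, 1.0)
    assert m["C"] == pytest.approx(1.0) and m["O"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        mm.expected_masked_counts(TypeCounts({"C": 2}), 3, 1.0)


def test_expected_counts_increase_with_type_count():
    """Within one molecule, the more abundant type gets more masked atoms."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        counts = {f"E{i}": int(c) for i, c in enumerate(rng.integers(1, 30, size=4))}
        tc = TypeCounts(counts)
        k = float(rng.choice(K_GRID))
        M = int(rng.integers(1, tc.total + 1))
        m = mm.expected_masked_counts(tc, M, k)
        for a in counts:
            for b in counts:
                if counts[a] > counts[b]:
                    assert m[a] > m[b]


@settings(derandomize=True, max_examples=50)
@given(
    counts=st.lists(st.integers(1, 40), min_size=1, max_size=6),
    k=st.sampled_from(K_GRID),
    data=st.data(),
)
def test_expected_counts_normalization_property(counts, k, data):
    tc = TypeCounts({f"E{i}": c for i, c in enumerate(counts)})
    M = data.draw(st.integers(1, tc.total))
    m = mm.expected_masked_counts(tc, M, k)
    assert sum(m.values()) == pytest.approx(M, abs=1e-12)


def test_mask_budget_rounding():
    assert mask_budget(20, 0.15) == 3
    assert mask_budget(1, 0.15) == 1       # at least one atom masked
    assert mask_budget(10, 0.15) == 2      # round half up: 1.5 -> 2
    assert mask_budget(3, 1.0) == 3


def test_wmm_config_validation():
    with pytest.raises(ValueError):
        WMMConfig(k=0.5)
    WMMConfig(k=0.5, allow_unsafe_k=True)
    with pytest.raises(ValueError):
        WMMConfig(mask_ratio=0.0)


def test_sample_mask_wmm_deterministic():
    mol = mm.parse_smiles("CC(=O)Nc1ccc(Cl)c(Cl)c1Cl")
    cfg = WMMConfig(k=0.9, mask_ratio=0.25, seed=5)
    assert mm.sample_mask_wmm(mol, cfg).masked_indices == mm.sample_mask_wmm(mol, cfg).masked_indices


def test_sample_mask_wmm_plan_contract():
    mol = mm.parse_smiles("CC(=O)Nc1ccc(F)cc1")
    plan = mm.sample_mask_wmm(mol, WMMConfig(k=0.9, mask_ratio=0.15), np.random.default_rng(0))
    assert plan.M == mask_budget(mol.n_atoms, 0.15)
    assert all(w > 0 for w in plan.per_atom_weight)
    assert plan.strategy == "wmm"


def test_single_draw_frequencies_match_exact_probabilities():
    """N=4, M=1: selection frequency of each atom ~ w_i / sum(w)."""
    w = np.array([1.0, 1.0, 1.0, 3.0])
    exact = w / w.sum()
    rng = np.random.default_rng(42)
    draws = draw_mask_indices(w, 1, rng, n_draws=100_000).ravel()
    freq = np.bincount(draws, minlength=4) / 100_000
    sigma = np.sqrt(exact * (1 - exact) / 100_000)
    assert np.all(np.abs(freq - exact) <= 3 * sigma)


def test_sampler_matches_bruteforce_oracle_small():
    """tc={C:4,Cl:1}, M=2: inclusion frequencies within 3 sigma of enumeration."""
    mol = mm.parse_smiles("CCCCCl")
    from molmask.masking import _per_atom_weights

    w = _per_atom_weights(mol, 0.9)
    exact = mm.inclusion_probabilities_bruteforce(w, 2)
    rng = np.random.default_rng(7)
    draws = draw_mask_indices(w, 2, rng, n_draws=100_000)
    freq = np.bincount(draws.ravel(), minlength=5) / 100_000
    sigma = np.sqrt(exact * (1 - exact) / 100_000)
    assert np.all(np.abs(freq - exact) <= 3 * sigma)


def test_bruteforce_oracle_basics():
    assert np.allclose(mm.inclusion_probabilities_bruteforce([1, 1, 1, 1], 2), 0.5)
    assert np.allclose(mm.inclusion_probabilities_bruteforce([0.3, 2.0, 1.1], 3), 1.0)
    assert np.allclose(
        mm.inclusion_probabilities_bruteforce([1, 1, 2], 1), [0.25, 0.25, 0.5]
    )
    probs = mm.inclusion_probabilities_bruteforce([0.7, 1.3, 2.2, 0.1], 2)
    assert probs.sum() == pytest.approx(2.0, abs=1e-12)
    with pytest.raises(ValueError):
        mm.inclusion_probabilities_bruteforce(np.ones(9), 2)


def test_sample_mask_random_uniform_and_deterministic():
    mol = mm.parse_smiles("C" * 10)
    plan = mm.sample_mask_random(mol, 0.2, np.random.default_rng(3))
    assert plan.M == 2 and plan.strategy == "random"
    single = mm.parse_smiles("C")
    assert mm.sample_mask_random(single, 0.15, np.random.default_rng(0)).masked_indices == (0,)
    rng = np.random.default_rng(1)
    counts = np.zeros(10)
    for _ in range(20_000):
        for i in mm.sample_mask_random(mol, 0.2, rng).masked_indices:
            counts[i] += 1
    freq = counts / 20_000
    sigma = math.sqrt(0.2 * 0.8 / 20_000)
    assert np.all(np.abs(freq - 0.2) <= 3 * sigma)


def test_apply_mask_roundtrip_and_isolation():
    mol = mm.parse_smiles("CCO")
    gt = mm.featurize(mol)
    original = gt.node_features.copy()
    plan = mm.MaskPlan((0,), (1.0, 1.0, 1.0), "random", 3)
    corrupted, targets = mm.apply_mask(gt, plan)
    assert corrupted.node_features[0, 0] == MASK_ATOM_INDEX
    assert corrupted.node_features[0, 1] == 0
    assert targets.tolist() == [original[0, 0]]
    assert np.array_equal(gt.node_features, original)  # input untouched
    # restore
    corrupted.node_features[0, 0] = targets[0]
    corrupted.node_features[0, 1] = original[0, 1]
    assert np.array_equal(corrupted.node_features, original)
    # full masking
    full = mm.MaskPlan((0, 1, 2), (1.0,) * 3, "random", 3)
    allmasked, _ = mm.apply_mask(gt, full)
    assert np.all(allmasked.node_features[:, 0] == MASK_ATOM_INDEX)


def test_apply_mask_index_out_of_range():
    gt = mm.featurize(mm.parse_smiles("CCO"))
    plan = mm.MaskPlan((0, 4), (1.0,) * 5, "random", 5)
    with pytest.raises(ValueError):
        mm.apply_mask(gt, plan)


def test_mask_distribution_report_properties():
    pure = [mm.parse_smiles("C" * 8) for _ in range(10)]
    df = mm.mask_distribution_report(
        pure,
        [{"strategy": "random"}, {"strategy": "wmm", "k": 0.9}],
        n_epochs=3,
        seed=0,
    )
    assert np.allclose(df.sum(axis=0), 1.0)
    # pure-carbon corpus: both strategies can only mask carbon
    assert np.allclose(df.loc["C"], 1.0)


def test_mask_distribution_report_trace_enrichment(corpus150):
    df = mm.mask_distribution_report(
        corpus150,
        [{"strategy": "random", "mask_ratio": 0.15},
         {"strategy": "wmm", "k": 0.9, "mask_ratio": 0.15}],
        n_epochs=3,
        seed=0,
    )
    assert np.allclose(df.sum(axis=0), 1.0)
    assert df.attrs["trace_ratio_wmm_over_random"] > 1.0
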