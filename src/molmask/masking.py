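"""Frequency-weighted masking for each molecule (WMM) and baselines.

The core idea: within one molecule with atom-type counts ``n_alpha``, an atom
of type ``alpha`` receives masking weight

    w_alpha = ln(k * (n_alpha + 1)) / n_alpha,

which is strictly decreasing in ``n_alpha`` for k >= 0.8, so rare atom types
(halogens, sulfur) are masked disproportionately often while abundant carbon
is down-weighted.  The hyperparameter ``k`` modulates how strongly rare types
are boosted; for large ``n_alpha`` the weight is insensitive to ``k``.
Summing type weights over atoms, the expected number of masked atoms of type
``alpha`` out of a budget of M is

    m_alpha = M * ln(k (n_alpha + 1)) / sum_beta ln(k (n_beta + 1)),

increasing in ``n_alpha``: abundant types still receive more masked atoms in
absolute count, just fewer than under uniform masking.

Atom selection is probability-proportional-to-weight sampling without
replacement via the exponential-keys scheme (Efraimidis-Spirakis): draw
u_i ~ U(0,1), key_i = u_i**(1/w_i), keep the M largest keys.  This induces
the same distribution as sequential draws proportional to remaining weight,
which the brute-force enumeration oracle here computes exactly for tiny N.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .molio import GraphTensors, MASK_ATOM_INDEX, MolGraph


@dataclass(frozen=True)
class TypeCounts:
    """Within-molecule atom-type counts n_alpha and their total N."""

    counts: dict

    def __post_init__(self):
        if not self.counts or any(c < 1 for c in self.counts.values()):
            raise ValueError("all type counts must be positive")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class WMMConfig:
    """Hyperparameters of the weighted masking strategy.

    k outside [0.8, 1.2] is rejected unless ``allow_unsafe_k`` is set; below
    k = 0.8 the weight can lose positivity/monotonicity guarantees.
    """

    k: float = 0.9
    mask_ratio: float = 0.15
    seed: int = 0
    allow_unsafe_k: bool = False

    def __post_init__(self):
        if not (0.0 < self.mask_ratio <= 1.0):
            raise ValueError("mask_ratio must lie in (0, 1]")
        if not self.allow_unsafe_k and not (0.8 <= self.k <= 1.2):
            raise ValueError(
                f"k={self.k} outside the validated range [0.8, 1.2]; "
                "pass allow_unsafe_k=True to override"
            )


@dataclass(frozen=True)
class MaskPlan:
    """A selected set of masked atom indices plus the weights behind it."""

    masked_indices: tuple
    per_atom_weight: tuple
    strategy: str
    n_atoms: int

    @property
    def M(self) -> int:
        return len(self.masked_indices)

    def __post_init__(self):
        idx = self.masked_indices
        if len(set(idx)) != len(idx):
            raise ValueError("masked indices must be distinct")
        if any(not (0 <= i < self.n_atoms) for i in idx):
            raise ValueError("masked index out of range")


def mask_budget(n_atoms: int, mask_ratio: float) -> int:
    """M = max(1, round(mask_ratio * N)) with round-half-up, clamped to N."""
    m = int(math.floor(mask_ratio * n_atoms + 0.5))
    return min(max(1, m), n_atoms)


def count_atom_types(mol: MolGraph) -> TypeCounts:
    """Within-molecule counts of each element symbol."""
    counts: Dict[str, int] = {}
    for sym, _, _ in mol.atoms:
        counts[sym] = counts.get(sym, 0) + 1
    return TypeCounts(counts)


def atom_weight(n: int, k: float) -> float:
    """Masking weight w = ln(k*(n+1))/n for one atom of a type with count n.

    Strictly positive and strictly decreasing in n for k >= 0.8.
    """
    if n < 1:
        raise ValueError("type count n must be >= 1")
    if k * (n + 1) <= 1.0:
        raise ValueError(f"k*(n+1)={k * (n + 1)} <= 1 yields a non-positive weight")
    return math.log(k * (n + 1)) / n


def expected_masked_counts(tc: TypeCounts, M: int, k: float) -> Dict[str, float]:
    """Expected number of masked atoms per type for a budget of M.

    m_alpha = M * ln(k(n_alpha+1)) / sum_beta ln(k(n_beta+1)); the values
    sum to M exactly.
    """
    if M > tc.total:
        raise ValueError(f"M={M} exceeds atom count N={tc.total}")
    terms = {a: n * atom_weight(n, k) for a, n in tc.counts.items()}
    z = sum(terms.values())
    return {a: M * t / z for a, t in terms.items()}


def _per_atom_weights(mol: MolGraph, k: float) -> np.ndarray:
    tc = count_atom_types(mol)
    w = {a: atom_weight(n, k) for a, n in tc.counts.items()}
    return np.array([w[sym] for sym, _, _ in mol.atoms], dtype=float)


def draw_mask_indices(
    weights: np.ndarray, M: int, rng: np.random.Generator, n_draws: int = 1
) -> np.ndarray:
    """Draw ``n_draws`` weighted without-replacement M-subsets at once.

    Exponential-keys scheme: key_i = u_i**(1/w_i) with u_i ~ U(0,1); the M
    largest keys win.  Ties (probability zero, but possible in floating
    point) break toward the lower atom index.  Returns an (n_draws, M) array
    of selected indices.  The single-draw path of :func:`sample_mask_wmm`
    goes through this same selection code.
    """
    w = np.asarray(weights, dtype=float)
    n = len(w)
    # log-domain keys: log(key) = log(u)/w; stable and order-preserving
    keys = np.log(rng.random((n_draws, n))) / w
    return np.argsort(-keys, axis=1, kind="stable")[:, :M]


def sample_mask_wmm(
    mol: MolGraph, cfg: WMMConfig, rng: Optional[np.random.Generator] = None
) -> MaskPlan:
    """Select M atoms by weighted sampling without replacement (WMM).

    Selection pressure on each atom is proportional to the weight of its
    type; deterministic given the generator state.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = mol.n_atoms
    m = mask_budget(n, cfg.mask_ratio)
    w = _per_atom_weights(mol, cfg.k)
    chosen = draw_mask_indices(w, m, rng)[0]
    return MaskPlan(tuple(sorted(int(i) for i in chosen)), tuple(w),
                    strategy="wmm", n_atoms=n)


def sample_mask_random(
    mol: MolGraph,
    mask_ratio: float = 0.15,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> MaskPlan:
    """Uniform M-subset baseline: every atom equally likely to be masked."""
    if rng is None:
        rng = np.random.default_rng(seed)
    n = mol.n_atoms
    m = mask_budget(n, mask_ratio)
    chosen = tuple(sorted(int(i) for i in rng.choice(n, size=m, replace=False)))
    return MaskPlan(chosen, tuple([1.0] * n), strategy="random", n_atoms=n)


def inclusion_probabilities_bruteforce(weights: Sequence[float], M: int) -> np.ndarray:
    """Exact per-atom inclusion probabilities of PPS-without-replacement.

    Enumerates every ordered draw of M distinct atoms under sequential
    selection proportional to remaining weight.  Test oracle only; refuses
    N > 8 (factorial enumeration).
    """
    w = np.asarray(weights, dtype=float)
    n = len(w)
    if n > 8:
        raise ValueError("brute-force oracle limited to N <= 8")
    if not (1 <= M <= n):
        raise ValueError("M must lie in [1, N]")
    probs = np.zeros(n)
    for draw in itertools.permutations(range(n), M):
        p = 1.0
        rem = w.sum()
        for i in draw:
            p *= w[i] / rem
            rem -= w[i]
        for i in draw:
            probs[i] += p
    return probs


def apply_mask(gt: GraphTensors, plan: MaskPlan):
    """Corrupt a graph per a mask plan.

    Masked nodes get the reserved mask-token atom-type index and chirality
    reset to "unspecified"; edges and unmasked nodes are untouched.  Returns
    ``(corrupted copy, targets)`` where targets are the original atom-type
    indices at the masked positions (in masked-index order).
    """
    idx = np.array(plan.masked_indices, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= gt.n_nodes):
        raise ValueError("mask plan indices out of range for these tensors")
    out = gt.copy()
    targets = out.node_features[idx, 0].copy()
    out.node_features[idx, 0] = MASK_ATOM_INDEX
    out.node_features[idx, 1] = 0
    return out, targets


def mask_distribution_report(
    corpus: Sequence[MolGraph],
    strategies: Sequence[dict],
    n_epochs: int = 10,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    trace_elements: frozenset = frozenset({"S", "F", "Cl", "Br", "I"}),
):
    """Tabulate the element distribution of masked atoms per strategy.

    ``strategies`` is a list of dicts like ``{"strategy": "wmm", "k": 0.9,
    "mask_ratio": 0.15}`` or ``{"strategy": "random", "mask_ratio": 0.15}``.
    Masks are resampled independently each epoch for each molecule.  Returns
    a pandas DataFrame (index element, one column per strategy label, columns
    sum to 1) plus the ratio of trace-element masked fraction wmm/random when
    both arms are present.
    """
    import pandas as pd

    if not corpus:
        raise ValueError("corpus must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    table: Dict[str, Dict[str, int]] = {}
    labels = []
    for scfg in strategies:
        strat = scfg["strategy"]
        label = scfg.get("label") or (
            f"wmm(k={scfg.get('k', 0.9)})" if strat == "wmm" else "random"
        )
        labels.append(label)
        counts: Dict[str, int] = {}
        for _ in range(n_epochs):
            for mol in corpus:
                if strat == "wmm":
                    cfg = WMMConfig(
                        k=scfg.get("k", 0.9),
                        mask_ratio=scfg.get("mask_ratio", 0.15),
                    )
                    plan = sample_mask_wmm(mol, cfg, rng)
                elif strat == "random":
                    plan = sample_mask_random(
                        mol, scfg.get("mask_ratio", 0.15), rng
                    )
                else:
                    raise ValueError(f"unknown strategy {strat!r}")
                for i in plan.masked_indices:
                    sym = mol.atoms[i][0]
                    counts[sym] = counts.get(sym, 0) + 1
        table[label] = counts
    df = pd.DataFrame(table).fillna(0.0)
    df = df / df.sum(axis=0)
    df = df[labels]
    trace_ratio = None
    wmm_cols = [l for l in labels if l.startswith("wmm")]
    if "random" in labels and wmm_cols:
        trace_rows = [e for e in df.index if e in trace_elements]
        denom = df.loc[trace_rows, "random"].sum()
        if denom > 0:
            trace_ratio = float(df.loc[trace_rows, wmm_cols[0]].sum() / denom)
    df.attrs["trace_ratio_wmm_over_random"] = trace_ratio
    return df
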