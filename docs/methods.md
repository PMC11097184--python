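# Methods

## Weighted masking model

For a molecule `Mol = (a_1, …, a_N)` let `n_α(i)` be the number of atoms
sharing atom `i`'s element type α. Every atom of type α receives the
masking weight

    w_α = ln(k · (n_α + 1)) / n_α .

Properties relied on throughout (all covered by tests):

* positivity for `k ≥ 0.8, n ≥ 1` (since `k(n+1) ≥ 1.6 > 1`);
* strict monotone decrease in `n` — rarer types weigh more;
* `n · w_α = ln(k(n_α+1))` is monotone increasing in `n`, so the expected
  masked count of a type, `m_α = M · ln(k(n_α+1)) / Σ_β ln(k(n_β+1))`,
  increases with abundance even though the per-atom weight decreases —
  abundant types are down-weighted per atom, not starved;
* the spread `w(n, k=1.2) − w(n, k=0.8)` decreases in `n`: `k` mainly
  modulates rare types.

The normalization `Σ_α m_α = M` holds exactly by construction. Because all
atoms of one type share one weight, the model deliberately ignores
intra-type context (a carbonyl carbon and a phenyl carbon of the same
molecule are weighted identically); distinguishing them is the realm of
learned tokenizers, which are out of scope here.

`M = max(1, round(mask_ratio · N))` with round-half-up: the floor of one
masked atom keeps the objective defined on the smallest molecules. Default
mask ratios are 0.15 for the classification objective and 0.25 for the
autoencoder objective, following the conventions of the respective
pretraining tasks. `k` defaults to 0.9 and is validated into `[0.8, 1.2]`
(an explicit unsafe flag lifts the check, e.g. for ablation sweeps).

## Sampling without replacement

Atoms are selected by exponential-keys weighted reservoir sampling: draw
`u_i ~ U(0,1)`, rank by `key_i = u_i^{1/w_i}` (computed in the log domain as
`log u_i / w_i`), keep the top `M`; floating-point ties break toward the
lower atom index. This induces the same distribution as sequential draws
proportional to the remaining weight, which
`inclusion_probabilities_bruteforce` computes exactly by enumerating all
ordered draws (refused above `N = 8`). The sampler's vectorized many-draw
path (`draw_mask_indices`) shares the single-draw selection code, so the
distribution tests exercise the production path.

Masks are resampled independently for every molecule in every epoch; a
single seeded generator drives corpus synthesis, mask sampling, batch
shuffling and dropout, making every pipeline number reproducible from one
seed.

The statistical sampler test compares ~390 per-atom inclusion frequencies
(all type-count multisets with `N ≤ 6`, `M ≤ 3`, 100 000 draws each)
against the enumeration oracle. A simultaneous "every comparison within
3σ" rule would falsely fail about half the time by multiplicity alone, so
the test asserts the family-wise version: every comparison within 4.5σ and
at least 99% within 3σ, with one independent RNG stream per combination.

## Encoder

Five GIN layers at width 300 are the full-scale defaults (mean-pooling
readout, Adam at 1e-3, 100 epochs, batch 256, dropout 0.0 for pretraining;
batch 32, dropout 0.5 for fine-tuning). One layer computes

    h_v ← BatchNorm(MLP(h_v + Σ_{u∈N(v)} (h_u + e_uv)))

with `h_v^{(0)}` the sum of atom-type and chirality embeddings, `e_uv` the
sum of per-layer bond-type and bond-direction embeddings, MLP =
linear→ReLU→linear at constant width, ε fixed at 0, ReLU between layers but
not after the last, dropout after each layer's nonlinearity. Node features
are (atomic number 1–118 → index, plus one reserved mask-token index;
chirality ∈ {unspecified, CW, CCW, other}); edges are (bond type ∈ {single,
double, triple, aromatic}, direction ∈ {none, end-up, end-down}), each
undirected bond doubled into two directed edges. This is the de-facto
standard featurization and layer recipe of the attribute-masking lineage;
the exact catalog is a design choice of this package.

Initialization is Glorot-uniform for all dense maps and embedding tables,
governed by the construction seed. Batch normalization uses batch
statistics in training and running averages (momentum 0.1) in evaluation.
Everything runs in float64 on a small reverse-mode autodiff core
(`molmask.nn.autograd`) providing exactly the needed operations (embedding
lookup, segment scatter/gather, dense algebra, batch norm, dropout,
cross-entropy, masked BCE, scaled-cosine error) — chosen to keep the stack
CPU-only, dependency-light, and deterministic.

## Objectives

*Masked-atom classification* (AttrMask style): a linear head over the
119-way atom-type vocabulary on masked-node embeddings; mean cross-entropy
over masked nodes only. *Masked-autoencoder reconstruction* (GraphMAE
style): the masked nodes' encoder embeddings are re-masked with a learned
vector, one additional GIN layer decodes, and a linear head reconstructs
the masked atom types. Atom types are categorical, so the default
reconstruction loss is cross-entropy; the scaled-cosine error
`mean((1 − cos)^γ)` on one-hot targets is available behind
`graphmae_loss="scaled_cosine"` for comparability with continuous-feature
formulations. Both objectives are provably blind to unmasked positions
(tested by perturbation).

## Scaffold split and fine-tuning protocol

Molecules are grouped by Bemis–Murcko scaffold (acyclic molecules share the
empty scaffold). Groups ordered by size (largest first, ties by first
occurrence) are filled greedily toward 80/10/10 capacities (largest
partition absorbs the rounding residue): a group goes to train while it
fits; otherwise to whichever of valid/test has the greater remaining
capacity, ties toward valid. No scaffold ever straddles partitions; fewer
than three scaffold groups is an error. The overflow-balancing rule (rather
than first-fit on valid/test) is what keeps both small partitions populated
when a corpus contains a few dominant scaffolds.

Fine-tuning trains encoder plus a per-task linear head on the pooled graph
embedding with missing-label masking (NaN labels carry zero loss weight).
Per epoch the validation ROC-AUC — the mean over tasks with both classes
present; single-class tasks are excluded with a logged warning rather than
scored 0.5 — is computed, and the reported test ROC-AUC is the one at the
best-validation epoch (ties toward the earlier epoch; selection is on the
reported metric, not the loss). Aggregation over seeds is mean ± standard
deviation; the full-scale protocol uses seeds 0–9.

## Synthetic corpus generator

The generator emulates the atom-type imbalance of large drug-like screening
libraries: target global frequencies C 0.74, O 0.12, N 0.10, and S/F/Cl/Br
0.01 each (C+O+N = 96%, trace = 4%). Each molecule draws its own
composition from a Dirichlet perturbation of the target (concentration 12)
and a multinomial atom count within an 8–30 heavy-atom budget, so
per-molecule distributions deviate from the global one — including
occasional chlorine- or sulfur-heavy molecules where a trace element
outnumbers oxygen and nitrogen — while corpus-level frequencies converge to
the target (realized carbon fraction within a few tenths of a percentage
point at 500 molecules; the contract tested is ±3 percentage points).
Molecules are assembled under explicit valence caps (C4, N3, O2, S2,
halogens 1): high-valence atoms first, each new atom attached by a single
bond to a uniformly chosen atom with free valence, up to two benzene rings
(the second attached to a random grown atom so ring systems plus linkers
diversify the Murcko-scaffold profile), and occasional aliphatic ring
closures. Every molecule is sanitized by RDKit and round-trips through its
canonical SMILES; infeasible compositions are resampled with bounded
retries.

What the generator does *not* emulate: realistic functional-group
chemistry, multiple bond orders (all acyclic bonds are single), stereo
centers, aromatic heterocycles, or the size distribution of real screening
libraries. Consequently, passing pipeline tests demonstrates correctness of
the masking/encoding/training machinery and the direction of the masking
effects — not transfer-learning performance on real chemistry benchmarks,
which requires library-scale pretraining outside this package's scope.

## Problem sizes and numerical choices

Desk-scale presets used by the tests and the acceptance script: corpora of
150–500 molecules, hidden width 16–64, 2–3 GIN layers, up to 30 pretraining
epochs, fine-tuning over 1–2 seeds — sizes chosen so the entire suite runs
in a couple of minutes on one CPU while every qualitative effect (trace
enrichment, accuracy ordering between random and weighted masking,
split properties, determinism) is already stable. At this scale the
accuracy plateaus sit well below the levels reached by library-scale
pretraining, but their ordering — uniform-random masking converging above
the weighted arm because the weighted task is deliberately harder — is the
contract under test. Full-scale defaults (300-wide, 5 layers, 100 epochs,
seeds 0–9) remain the constructor defaults.

Other numerical choices: round-half-up for the mask budget; checkpoint
files are single `.npz` archives with a JSON header (format tag, version,
encoder config) validated on load; degenerate inputs (single-atom
molecules, edgeless graphs, empty eval partitions, single-class tasks) are
handled explicitly and tested.

## Known limitations

* All-atoms-of-a-type-weigh-the-same is an explicit modeling assumption;
  context-dependent atom roles are invisible to the weighting.
* The expectation formula is treated as the normalization identity of the
  weighting scheme; under without-replacement sampling the realized
  per-type counts match it only approximately (the sampler is instead
  verified exactly against the enumeration oracle).
* The autodiff core supports exactly the operations this package needs; it
  is not a general deep-learning framework, and large-scale pretraining is
  out of scope.
* Benchmark-scale numbers (multi-dataset ROC-AUC tables from 2M-molecule
  pretraining) are reproduced in protocol and table structure only, at
  synthetic desk scale.
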