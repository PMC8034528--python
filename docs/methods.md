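# Methods

## Model

Diffusion scoring treats a biological network as a smoothing operator: a
kernel matrix `K` derived from the graph Laplacian redistributes an input
label vector `y` into scores `f = K·y`. All five kernels are functions of the
Laplacian spectrum and therefore symmetric positive semi-definite; they assume
an **undirected** network with non-negative weights and no self-loops, which
the network validator enforces (directed inputs are symmetrized by union with
max weight, parallel edges collapse to the max weight, self-loops are dropped
— each with a logged count). Diffusion treats edge weights as affinities, not
distances.

Matrix functions (`exp`, `cos`, the Moore–Penrose pseudo-inverse) are computed
by symmetric eigendecomposition rather than series expansions. This is exact
to machine precision for the dense sizes targeted here and keeps every kernel
checkable against an independent spectral oracle. Everything is dense
`float64`; the practical ceiling is roughly 20k nodes (an n×n
eigendecomposition and a few n×n products). No sparse or iterative solvers are
in scope.

### Kernel parameters

- `sigma2` (regularized Laplacian, default 1.0): regularization strength;
  larger values smooth further. Must be > 0; the kernel stays row-stochastic
  for any value because `L·1 = 0`.
- `t` (heat kernel, default 1.0): diffusion time, in units of inverse edge
  weight; `t → 0` recovers the identity. The time parameterization
  `exp(−tL)` is adopted as the normative form (an equivalent convention
  writes `exp(−σ²/2·L)`).
- `a, p` (p-step, defaults 2 and 5): `a ≥ 2` guarantees PSD because the
  normalized Laplacian spectrum lies in `[0, 2]`; `p` is the walk length.
- Defaults mirror the convention of the established diffusion-scoring
  ecosystem so results are comparable across implementations.

### Isolated nodes

The normalized Laplacian is undefined for zero-degree nodes. The default
policy gives them the identity row/column (self-similarity one, no coupling),
which matches the common convention and keeps the spectrum in `[0, 2]`; a
strict mode raises instead for pipelines that consider isolated nodes an
input error.

### Score encodings

`raw`/`z` place the input values (1 for bare lists) on matched nodes and 0
elsewhere. `ml` uses `+1/−1/0` for positives/explicit negatives/unlabeled;
`gm` replaces the unlabeled 0 with `k = (n⁺ − n⁻)/(n⁺ + n⁻)`, the mean of the
labeled codes, so the unlabeled mass reflects class imbalance. Quantitative
values are only meaningful for `raw`/`z` and are rejected for the signed
encodings. Without a negatives file, all matched entities are positives
(`n⁻ = 0`). Unmatched input entities are always reported and warned about;
only an empty overlap aborts.

### The z-score null

`z` standardizes `f_i` by its exact mean and variance under uniform
permutation of `y` across the background. The closed forms follow from
permutation (simple-random-sampling-without-replacement) moments: with
`S1_i = Σ_j K_ij`, `S2_i = Σ_j K_ij²`, background size `n`,

    E[f_i]   = S1_i · mean(y)
    Var[f_i] = (n·Σy² − (Σy)²) · (n·S2_i − S1_i²) / (n²·(n−1))

Tests verify these against exhaustive enumeration of all `n!` permutations
for n ≤ 6 and against 200,000 sampled permutations at n = 40. The analytic
form is always used for scoring; the seeded Monte-Carlo sampler exists only
as an independent cross-check. Nodes with zero null variance (e.g. an
all-zero kernel row) are flagged undefined and carry NaN rather than a silent
zero. The background defaults to **all nodes**; a modality-restricted
background (permuting labels only within, say, genes) is available and
changes `n`, `mean(y)` and the variance accordingly — entities outside a
restricted background are reported as unmatched. Variances are floored at
zero against roundoff.

## Harmonization

Networks merge by canonical `(namespace, id)`. Identifiers written as
`namespace:local` keep that namespace; bare identifiers keep their bare form
with namespace `unknown` rather than being rewritten, which preserves
byte-level file round trips while still preventing cross-namespace collisions
for properly prefixed ids (per-layer `namespace_map`s rewrite prefixes before
merging). Layer sets union on merged nodes and edges; duplicate edges keep
the max weight; modality conflicts are hard errors because modality drives
the evaluation negatives and restricted nulls. Merging is idempotent and
layer-order invariant (layers are processed in sorted name order). Database
connectors are out of scope: the merge engine consumes any of the four
standard formats (edge list TSV/CSV, GraphML, GML, node-link JSON).

## Evaluation

The repeated-holdout harness hides `ceil(fraction_test·|pos|)` positives
(default fraction 0.2), diffuses the rest, and computes the AUROC of the
hidden positives versus negatives by the Mann–Whitney mid-rank formulation
(equivalent to pair counting with 0.5 per tie). Negatives default to all
same-modality non-positive nodes; an explicit negative set overrides. Test
positives never enter the diffusion input, so there is no leakage, and their
scores are read only at evaluation time. Repeat `r` uses seed
`base_seed + r`, so comparisons across networks are paired per repeat; the
comparison reports each network's AUROC distribution and the paired median
difference against the first (reference) network. The holdout fraction and
negative-class definition are package defaults, configurable per call.

## Synthetic data

The generators stand in for pathway-database content. The planted-community
fixture (stochastic block model; default two 25-node blocks with edge
probability 0.3 within and 0.02 between) has the one property diffusion
exploits: members of a label-sharing module are better connected to each
other than to the background. Multi-layer mode assigns each edge to one of
`n_layers` layers uniformly at random, so each single layer is an
edge-depleted view of the same structure — a desk-scale analogue of
individual databases each covering part of an integrated network. Label
generation can flip each node's membership independently with probability
`< 0.5` to emulate noisy differential-entity calls.

What passing these benchmarks does *not* show: real pathway databases differ
from random edge slices (layers are topically biased, node coverage differs
per database, degree distributions are heavy-tailed beyond the BA fixture),
real label sets are small relative to the network and biased toward
well-studied genes, and real multi-omics inputs span modalities with very
different coverage. Results on the fixtures demonstrate correctness of the
machinery and the *direction* of the integration benefit, not effect sizes on
real data.

All randomness flows through one explicit `numpy` generator per call; the
same spec yields byte-identical serialized fixtures, and evaluation results
are bitwise reproducible under the same base seed.

## Numerical and design choices

- PSD test tolerance is relative (`−1e−8 ×` spectral radius) so float noise
  on 50-node fixtures does not flag healthy kernels.
- Kernel TSVs serialize values with `repr`, which round-trips `float64`
  bit-exactly; network equality is order-insensitive on node ids and weighted
  edges.
- Ranking uses mid-rank ties, descending; ties in the output listing break
  lexicographically for determinism.
- Problem sizes in the test suite and acceptance script (50-node kernels, 30
  random fixtures, 100 holdout repeats, 200,000 Monte-Carlo permutations)
  were chosen to exercise every law at desk scale; the whole suite runs in a
  few seconds.
- The edge-list format is intentionally lossy (no isolated nodes or node
  annotations) and flagged as such; GraphML/GML/JSON are the faithful
  formats.

## Known limitations

- Dense linear algebra only; no directed-diffusion variants, hypergraphs, or
  kernel learning.
- No p-values or multiple-testing layer on z-scores; no AUPRC or significance
  tests between AUROC distributions beyond the paired median difference.
- The hosted content of specific pathway databases is out of scope; users
  supply their own standard-format exports.
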