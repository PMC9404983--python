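# Methods

## Placement model

A query `q` is attached to a backbone edge `e` (length `ℓ_e`) at distance
`x ∈ [0, ℓ_e]` from the edge's proximal endpoint, with a pendant branch
`p ≥ 0`. For a backbone leaf `i` on the proximal side the induced path
distance is `d_qi = p + x + c_i`; on the distal side it is
`d_qi = p + (ℓ_e − x) + c_i`, with `c_i` the path length from the relevant
edge endpoint to the leaf. Placement minimizes `Σ w_i (δ_i − d_qi)²` over
all edges and the box `{p ≥ 0, 0 ≤ x ≤ ℓ_e}`.

**Weights.** `w_i = δ_i^(−k)` with `k = 2` by default (Fitch–Margoliash;
`k = 0` gives OLS, `k = 1` is exposed too). Distances are clamped below at
`1e−6` before inverse-power weighting so that a zero distance (query
identical to a reference) yields a large but finite weight. Invalid
distances — saturated pairs or pairs with no mutually ungapped sites — get
weight 0; a query is rejected only when fewer than two valid distances
remain.

**Per-edge solver.** For a fixed edge the objective is a convex quadratic
in `(p, x)` (the side indicator enters only through a ±1 sign, so the
normal matrix is `[[W, A], [A, W]]` with `W = Σw`, `A = Σw·s`). We solve
the unconstrained 2×2 system and, when that stationary point is
infeasible, minimize exactly over each boundary piece of the feasible box
(`p = 0` with `x` clipped to `[0, ℓ_e]`; `x = 0` and `x = ℓ_e` with `p`
clipped at 0), keeping the feasible candidate with the smallest objective.
For a two-variable bound-constrained convex quadratic this enumeration is
exact. The solver is vectorized across replicate distance rows, which is
what makes bootstrap support (B placements per query) cheap once distances
exist.

**Degenerate edges.** When all usable references lie on one side of an
edge (possible only after invalid distances have been zero-weighted), `p`
and `x` are confounded along `p + x = const` and the normal matrix is
singular. Rather than skipping the edge we return the deterministic
boundary solution (the `x = 0` / `p = 0` candidates remain well defined),
so the edge keeps a meaningful LSE; the choice among the optimal set is a
reporting convention, not a change to the optimum.

**Ties.** Exhaustive fitting visits edges in increasing edge number; edges
whose LSE is within a relative `1e−9` of the minimum are treated as tied
and the smallest edge number wins. A tolerance is used because mirrored
subtrees produce mathematically equal sums evaluated in different orders,
which need not be bit-identical.

**Exhaustive rather than dynamic-programming placement.** Per-edge fitting
is O(n), so a query costs O(n²). This artifact targets desk-scale
backbones (up to a few thousand leaves), where exhaustive fitting is fast,
is the unambiguous definition of the optimum, and doubles as the oracle
for a linear-time dynamic program should one be added later.

## Distances

**DNA.** Normalized Hamming distance over mutually ungapped sites
(ambiguity codes count as gaps), JC69-corrected:
`δ = −¾ ln(1 − 4h/3)`. Pairs with `h ≥ ¾` are *saturated*: they are
flagged invalid and excluded from the objective (weight 0) rather than
capped — capping would inject arbitrary large pseudo-observations into a
least-squares fit. The JC69 expectation `h(t) = ¾(1 − e^(−4t/3))` is the
exact inverse and drives both the parametric sampler and the sequence
simulator.

**Amino acids (Scoredist).** The BLOSUM62 score `σ` over mutually ungapped
sites is normalized between the expected random score `σ_r` (computed from
the aligned pair's own residue composition: the mean score of all cross
pairings, `σ_r = c_aᵀ S c_b / l`) and the upper limit `σ_u` (mean of the
two self-scores). The distance is `−c · ln((σ − σ_r)/(σ_u − σ_r))` with
`c = 1.3`, the FastTree-2 convention, so distances are in substitutions
per site and commensurable with backbone branch lengths estimated by that
family of tools; the original coefficient 1.13 is selectable. Pairs whose
normalized score is non-positive (at or beyond random) receive the ceiling
3.0 substitutions/site — the 300-PAM cap of the original method. A
`site_weights` vector reweights sites, which reproduces column resampling
exactly without materializing resampled strings; this is how amino-acid
bootstrapping works.

**Replicate formulation.** Per query, `V` (mismatch) and `G` (both
ungapped) are `L×n` binary matrices computed once. Any `(B+1)×L`
non-negative integer weight matrix then gives mismatch counts `P = H·V`
and valid-site counts `L' = H·G`; `h = P/L'` and the JC69 correction
follow. Because all quantities are integer until the final division, the
result is bit-exact with materializing each resampled alignment and
counting mismatches by string comparison — a property the test suite
checks against a deliberately naive oracle. Row 0 of every weight matrix
is all ones and stands for the original alignment.

## Support estimators

All estimators share the semantics: place row 0 for the reported
placement; support of an edge is the fraction of rows `1..B` whose optimal
placement lands on it. Replicates with no valid placement are dropped from
the denominator and counted in a diagnostics field (so reported fractions
always sum to 1). `B = 100` by default. One weight matrix is drawn per run
and shared by all queries; parametric methods instead derive a per-query
seed (`run_seed XOR crc32(query_id)`), so results are independent of query
order and of any parallel execution schedule.

* **Fast bootstrap** (default): `H` rows are multinomial(L, uniform).
* **Slow bootstrap**: same `H`; additionally, for each replicate the
  backbone's pairwise distances are recomputed under the replicate's
  column weights and branch lengths are refitted by non-negative WLS
  (below) before placing. With refitting disabled it reduces exactly to
  fast bootstrapping, which the tests assert. Amino-acid alignments are
  supported through weighted Scoredist; the mismatch-count fast path and
  the subsample/parametric methods are DNA-only.
* **Subsampling**: indicator rows with `b = round(L^0.9)` ones (round half
  to even). The variance correction `√(b/n)(h_b − h_n) + h_n` is applied
  to the normalized Hamming distance, clamped below at 0, flagged invalid
  at/above ¾, and only then JC69-corrected. Note a genuine statistical
  property of without-replacement subsampling: the corrected replicate
  variance equals the bootstrap variance times the finite-population
  factor `(n − b)/(n − 1)`, so at `b = n^0.9` it is roughly half the
  bootstrap variance and the two converge only as `b/n → 0`. This is why
  subsampling yields systematically higher support than bootstrapping at
  the default subsample size; the test suite asserts the
  `(n − b)/(n − 1)` law rather than pretending the two variances match.
* **Parametric**: per reference, `x ~ Binomial(l, ĥ)` or
  `Poisson(ĥ·l)` drawn independently across references and replicates,
  then `t̂ = −¾ ln(1 − 4x/(3l))`; draws at/beyond saturation are invalid.
  Independence across references ignores the covariance induced by shared
  tree paths — a deliberate simplification, and the known reason
  parametric support is less calibrated than resampling. References
  already saturated on the original alignment are flagged invalid
  throughout rather than aborting the query; an error is raised only when
  every reference is saturated.

## Branch-length refitting

On a fixed topology, lengths solve a non-negative weighted least-squares
problem: rows are leaf pairs with valid corrected distances, the design
matrix is path-edge incidence (XOR of root-path indicators), weights are
`δ^(−2)`, solved with NNLS. Pairs without mutually ungapped sites are
excluded; the refit aborts if more than half the pairs are invalid
(configurable). Determinism follows from the solver being deterministic.

## Synthetic data

The generator emulates the study design the support methods are meant for:
a random binary tree (sequential random joins down to a trifurcating
root), i.i.d. exponential branch lengths, JC69 site-independent sequence
evolution, random leaves pruned out as queries (the two branches flanking
a pruned attachment merge, and the true attachment edge is mapped onto the
backbone's numbering through leaf bipartitions), and optional
fragmentation that keeps one random contiguous window of residues per
query and gaps the rest.

Default study conditions: 300 simulated leaves, 200 pruned queries (so a
100-leaf backbone), L = 2000 sites, branch-length mean 0.05
substitutions/site — chosen once so that typical leaf-to-leaf p-distances
fall in the 0.3–0.45 range characteristic of moderately divergent
single-gene datasets, well below JC69 saturation; fragments are 200 bp.

What the generator does *not* emulate: indels (fragmentation is masking,
not read simulation), rate variation across sites, non-uniform base
composition, and alignment error (queries are born aligned). Passing tests
therefore demonstrate correctness of the estimators under the model the
method assumes, not robustness to model violations on real data — the
known regime where distance-based placement degrades (high rates, heavy
missing data) is discussed in the placement literature and is out of scope
here.

## Evaluation

"Correct" means the top-support edge equals the edge the query was pruned
from (ties by edge number). Calibration bins are left-inclusive 10-point
bins of percent support with a final `{100}` bin; the MSE compares each
non-empty bin's accuracy to its midpoint, weighted by occupancy (an
unweighted mode exists). The ROC curve follows integer thresholds
`T ∈ {0..100}` with `support ≥ T` as the positive call; the reported AUROC
is the exact rank statistic (trapezoid over the full curve with tie
handling), which coincides with the thresholded curve whenever supports
are multiples of `1/B` and is invariant under monotone transforms of
support. With a single class present the AUROC is reported as undefined
rather than guessed. ECDFs are standard right-continuous per-class CDFs of
top support. Top-k accuracy counts the true edge among the k
highest-support edges.

## Numerical conventions

* LSE values returned to callers are recomputed from residuals at the
  chosen optimum (the vectorized path uses an algebraically equal
  expanded form).
* Edge numbering is depth-first post-order of the parsed rooted
  representation, recomputed identically on re-read; jplace output embeds
  the numbering as `{N}` annotations.
* All randomness flows through `numpy.random.default_rng` seeds; derived
  seeds stay below 2³¹.
* Problem sizes in the test suite (fixture trees of 8–64 leaves, the
  300-leaf end-to-end study) are the package's chosen desk-scale study
  conditions; the end-to-end scenario completes in about a minute on one
  core.
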