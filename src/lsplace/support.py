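"""Placement support by replicate resampling.

Four estimators, all of which reduce to "make B replicate distance vectors,
place each, report per-edge frequencies":

* fast bootstrap — sites resampled with replacement; replicate mismatch
  counts come from a single matrix product ``H @ V`` (and valid-site counts
  from ``H @ G``), so the sequences are compared exactly once per query.
* slow bootstrap — the same resampling, but branch lengths of the backbone
  are re-estimated on every replicate before placing (topology fixed).
* subsampling — ``b`` of the ``L`` sites drawn without replacement
  (``b = round(L^0.9)`` by default), with the m-out-of-n variance
  correction ``sqrt(b/n) * (h_b - h_n) + h_n`` applied to the normalized
  Hamming distance before the JC69 correction.
* parametric — per-reference draws from Binomial(l, h_hat) or
  Poisson(h_hat * l), each transformed back to a distance.  Draws are
  independent across references, ignoring the covariance induced by shared
  tree paths.

One replicate-weight matrix is generated per run and shared by every query;
row 0 is always the all-ones row representing the original alignment.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .distances import (
    DistanceReplicates,
    MismatchProfile,
    SATURATION,
    build_profile,
    distances_from_counts,
    jc69_correct,
    scoredist,
)
from .msa import Alignment
from .placement import (
    Placement,
    PlacementConfig,
    edge_fit,
    place_query,
    place_replicates,
    refit_from_distances,
    weights_from_distances,
)
from .distances import pairwise_corrected_distances
from .tree import BackboneTree

METHODS = ("fast_bs", "slow_bs", "subsample", "binomial", "poisson")


def default_subsample_size(L: int) -> int:
    """Default subsample size ``round(L^0.9)`` (round half to even)."""
    return int(np.rint(float(L) ** 0.9))


@dataclass
class ReplicateWeights:
    """Per-replicate site weights: bootstrap counts or subsample indicators.

    Row 0 is all ones (the original alignment); rows ``1..B`` each sum to
    ``L`` (bootstrap) or to ``b`` (subsample).
    """

    kind: str  # "bootstrap" | "subsample"
    matrix: np.ndarray  # (B+1, L) non-negative integers
    B: int
    seed: int
    b: Optional[int] = None

    @property
    def L(self) -> int:
        return self.matrix.shape[1]


def make_bootstrap_weights(L: int, B: int, seed: int) -> ReplicateWeights:
    """B rows of multinomial(L, uniform) site counts; computed once per run
    and shared by all queries."""
    if L < 1 or B < 1:
        raise ValueError("L and B must be >= 1")
    rng = np.random.default_rng(seed)
    rows = rng.multinomial(L, np.full(L, 1.0 / L), size=B)
    mat = np.vstack([np.ones(L, dtype=np.int64), rows.astype(np.int64)])
    return ReplicateWeights(kind="bootstrap", matrix=mat, B=B, seed=seed)


def make_subsample_weights(L: int, B: int, b: Optional[int] = None, seed: int = 0) -> ReplicateWeights:
    """B rows of 0/1 indicators selecting ``b`` distinct sites uniformly."""
    if L < 1 or B < 1:
        raise ValueError("L and B must be >= 1")
    if b is None:
        b = default_subsample_size(L)
    if not 1 <= b <= L:
        raise ValueError(f"subsample size b={b} outside 1..L={L}")
    rng = np.random.default_rng(seed)
    mat = np.zeros((B + 1, L), dtype=np.int64)
    mat[0] = 1
    for i in range(1, B + 1):
        mat[i, rng.choice(L, size=b, replace=False)] = 1
    return ReplicateWeights(kind="subsample", matrix=mat, B=B, seed=seed, b=int(b))


# --------------------------------------------------------------------------
# replicate distances
# --------------------------------------------------------------------------

def fast_bootstrap_distances(weights: ReplicateWeights, profile: MismatchProfile) -> DistanceReplicates:
    """Replicate distances by the matrix formulation ``P = H·V``,
    ``L' = H·G`` — bit-exact with materializing every resampled alignment
    and counting mismatches by string comparison."""
    H = weights.matrix
    if H.shape[1] != profile.n_sites:
        raise ValueError("weight matrix width does not match alignment length")
    P = H @ profile.V.astype(np.int64)
    Lp = H @ profile.G.astype(np.int64)
    return distances_from_counts(P, Lp, query_id=profile.query_id)


def subsample_distances(weights: ReplicateWeights, profile: MismatchProfile) -> DistanceReplicates:
    """Subsample replicate distances with the m-out-of-n correction.

    Per replicate and reference: ``h_b = (S·V)/(S·G)``; the corrected
    Hamming distance is ``sqrt(b/n) * (h_b - h_n) + h_n`` (clamped below at
    0, flagged invalid at/above the JC69 saturation point), then the JC69
    correction is applied last.
    """
    if weights.kind != "subsample":
        raise ValueError("subsample_distances requires subsample weights")
    S = weights.matrix
    if S.shape[1] != profile.n_sites:
        raise ValueError("weight matrix width does not match alignment length")
    P = S @ profile.V.astype(np.int64)
    Lp = S @ profile.G.astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(Lp > 0, P / np.where(Lp > 0, Lp, 1), np.nan)
    h_n = h[0]
    factor = np.sqrt(weights.b / weights.L)
    corr_h = factor * (h - h_n[None, :]) + h_n[None, :]
    corr_h[0] = h_n
    corr_h = np.maximum(corr_h, 0.0)
    corrected = jc69_correct(np.where(np.isfinite(corr_h), corr_h, np.inf))
    return DistanceReplicates(
        query_id=profile.query_id, hamming=corr_h, corrected=corrected, valid_sites=Lp
    )


def parametric_distances(
    h_hat,
    l,
    B: int,
    mode: str = "binomial",
    seed: int = 0,
    query_id: str = "query",
) -> DistanceReplicates:
    """Parametric replicate distances.

    Per reference with observed Hamming distance ``h_hat`` over ``l``
    mutually ungapped sites, draw ``x ~ Binomial(l, h_hat)`` (or
    ``Poisson(h_hat * l)``) independently for each replicate and transform
    back with the JC69 correction; draws with ``x/l >= 3/4`` are invalid.
    References already saturated on input are flagged invalid throughout
    (an error is raised only if every reference is).
    """
    if mode not in ("binomial", "poisson"):
        raise ValueError(f"unknown parametric mode {mode!r}")
    h_hat = np.asarray(h_hat, dtype=float)
    l = np.asarray(l)
    if np.any(l < 0):
        raise ValueError("negative site counts")
    usable = np.isfinite(h_hat) & (h_hat < SATURATION) & (l >= 1)
    if not usable.any():
        raise ValueError("all references saturated or without overlapping sites")
    n = h_hat.shape[0]
    rng = np.random.default_rng(seed)
    h = np.full((B + 1, n), np.nan)
    h[0, usable] = h_hat[usable]
    li = l[usable].astype(np.int64)
    if mode == "binomial":
        x = rng.binomial(li[None, :], h_hat[usable][None, :], size=(B, usable.sum()))
    else:
        x = rng.poisson(h_hat[usable][None, :] * li[None, :], size=(B, usable.sum()))
    h[1:, usable] = x / li[None, :]
    corrected = jc69_correct(np.where(np.isfinite(h), h, np.inf))
    valid_sites = np.tile(np.where(usable, l, 0), (B + 1, 1))
    return DistanceReplicates(
        query_id=query_id, hamming=h, corrected=corrected, valid_sites=valid_sites
    )


# --------------------------------------------------------------------------
# support aggregation
# --------------------------------------------------------------------------

@dataclass
class SupportedPlacement:
    """Original placement plus per-edge support fractions over B replicates.

    ``support`` maps edge number to the fraction of valid replicates whose
    optimal placement fell on that edge; fractions sum to 1.  Replicates
    without a valid placement are excluded from the denominator and counted
    in ``n_invalid_replicates``.  ``edge_fits`` holds, for every supported
    edge, the (distal, pendant, lse) fit of the *original* distances on
    that edge (what the jplace rows report).
    """

    query_id: str
    placement: Placement
    support: dict
    B: int
    method: str
    n_invalid_replicates: int = 0
    edge_fits: dict = field(default_factory=dict)


def aggregate_support(edge_choices) -> tuple[dict, int]:
    """Per-edge frequencies over replicate placements (−1 = invalid
    replicate, dropped from the denominator)."""
    edge_choices = np.asarray(edge_choices)
    valid = edge_choices >= 0
    n_invalid = int((~valid).sum())
    chosen = edge_choices[valid]
    if chosen.size == 0:
        raise ValueError("all replicates failed to produce a valid placement")
    edges, counts = np.unique(chosen, return_counts=True)
    total = counts.sum()
    return {int(e): float(c) / total for e, c in zip(edges, counts)}, n_invalid


def _finish(query_id, dreps, tree, config, B, method) -> SupportedPlacement:
    edges, x, p, lse = place_replicates(dreps.corrected, tree, config)
    if edges[0] < 0:
        raise ValueError(f"query {query_id!r} has no valid placement on the original alignment")
    original = Placement(
        query_id=query_id,
        edge_num=int(edges[0]),
        distal_length=float(x[0]),
        pendant_length=float(p[0]),
        lse=float(lse[0]),
    )
    support, n_invalid = aggregate_support(edges[1:])
    w0 = weights_from_distances(dreps.corrected[0], config.weight_exponent)
    fits = {e: edge_fit(e, dreps.corrected[0], w0, tree) for e in support}
    return SupportedPlacement(
        query_id=query_id,
        placement=original,
        support=support,
        B=B,
        method=method,
        n_invalid_replicates=n_invalid,
        edge_fits=fits,
    )


def query_seed(run_seed: int, query_id: str) -> int:
    """Per-query derived seed (stable hash of the id mixed with the run
    seed) so that results do not depend on query order or worker count."""
    return int((int(run_seed) ^ zlib.crc32(str(query_id).encode())) % (2**31 - 1))


def slow_bootstrap(
    query_id: str,
    query_row,
    backbone: Alignment,
    tree: BackboneTree,
    B: int = 100,
    seed: int = 0,
    refit: bool = True,
    config: Optional[PlacementConfig] = None,
    weights: Optional[ReplicateWeights] = None,
) -> SupportedPlacement:
    """Bootstrap support with per-replicate branch-length re-estimation.

    Each replicate's resampled alignment is realized through its weight
    row: query-to-reference distances come from the same matrix
    formulation as fast bootstrapping, and backbone pairwise distances (for
    the WLS branch-length refit on the fixed topology) apply the weight row
    to precomputed per-pair mismatch indicators.  With ``refit`` off the
    method is identical to fast bootstrapping.
    """
    config = config or PlacementConfig()
    if weights is None:
        weights = make_bootstrap_weights(backbone.n_sites, B, seed)
    H = weights.matrix
    profile = build_profile(query_row, backbone, query_id=query_id)
    if backbone.alphabet == "dna":
        dreps = fast_bootstrap_distances(weights, profile)
    else:
        rows = [backbone.row(s) for s in backbone.ids]
        d = np.empty((H.shape[0], len(rows)))
        for i in range(H.shape[0]):
            for j, ref in enumerate(rows):
                try:
                    d[i, j] = scoredist(query_row, ref, site_weights=H[i])
                except ValueError:
                    d[i, j] = np.nan
        dreps = DistanceReplicates(
            query_id=query_id, hamming=np.full_like(d, np.nan), corrected=d,
            valid_sites=H @ profile.G.astype(np.int64),
        )
    if not refit:
        return _finish(query_id, dreps, tree, config, weights.B, "slow_bs")

    choices = np.empty(weights.B + 1, dtype=np.int64)
    for i in range(weights.B + 1):
        dist = pairwise_corrected_distances(
            backbone, rows=tree.leaf_labels, site_weights=H[i]
        )
        tree_i = refit_from_distances(tree, dist, config.weight_exponent)
        delta = dreps.corrected[i]
        if np.isfinite(delta).sum() < 2:
            choices[i] = -1
            continue
        choices[i] = place_query(delta, tree_i, config, query_id=query_id).edge_num
    if choices[0] < 0:
        raise ValueError(f"query {query_id!r} has no valid placement on the original alignment")
    # original placement reported on the refit-from-original-alignment tree
    dist0 = pairwise_corrected_distances(backbone, rows=tree.leaf_labels, site_weights=H[0])
    tree0 = refit_from_distances(tree, dist0, config.weight_exponent)
    original = place_query(dreps.corrected[0], tree0, config, query_id=query_id)
    support, n_invalid = aggregate_support(choices[1:])
    w0 = weights_from_distances(dreps.corrected[0], config.weight_exponent)
    fits = {e: edge_fit(e, dreps.corrected[0], w0, tree0) for e in support}
    return SupportedPlacement(
        query_id=query_id,
        placement=original,
        support=support,
        B=weights.B,
        method="slow_bs",
        n_invalid_replicates=n_invalid,
        edge_fits=fits,
    )


def compute_support(
    query_id: str,
    query_row,
    backbone: Alignment,
    tree: BackboneTree,
    method: str = "fast_bs",
    B: int = 100,
    seed: int = 0,
    config: Optional[PlacementConfig] = None,
    weights: Optional[ReplicateWeights] = None,
    refit: bool = True,
) -> SupportedPlacement:
    """Place one query and estimate per-edge support with the chosen method.

    The original placement comes from row 0 (the unresampled alignment);
    support fractions are per-edge frequencies over rows ``1..B``.  A
    shared :class:`ReplicateWeights` may be passed in so all queries of a
    run use the same resampling (the default when going through
    :func:`place_with_support`).
    """
    if method not in METHODS:
        raise ValueError(f"unknown support method {method!r}; choose from {METHODS}")
    config = config or PlacementConfig()
    if method == "slow_bs":
        return slow_bootstrap(
            query_id, query_row, backbone, tree, B=B, seed=seed,
            refit=refit, config=config, weights=weights,
        )
    if backbone.alphabet != "dna":
        raise NotImplementedError(
            f"method {method!r} requires the mismatch-count formulation and is "
            "DNA-only; use slow_bs for amino-acid alignments"
        )
    profile = build_profile(query_row, backbone, query_id=query_id)
    if method == "fast_bs":
        if weights is None:
            weights = make_bootstrap_weights(backbone.n_sites, B, seed)
        dreps = fast_bootstrap_distances(weights, profile)
    elif method == "subsample":
        if weights is None:
            weights = make_subsample_weights(backbone.n_sites, B, seed=seed)
        dreps = subsample_distances(weights, profile)
    else:  # binomial | poisson
        P0 = profile.V.sum(axis=0).astype(float)
        L0 = profile.G.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            h_hat = np.where(L0 > 0, P0 / np.where(L0 > 0, L0, 1), np.nan)
        dreps = parametric_distances(
            h_hat, L0.astype(int), B, mode=method,
            seed=query_seed(seed, query_id), query_id=query_id,
        )
        weights = None
    B_eff = weights.B if weights is not None else B
    return _finish(query_id, dreps, tree, config, B_eff, method)


def place_with_support(
    queries: Alignment,
    backbone: Alignment,
    tree: BackboneTree,
    method: str = "fast_bs",
    B: int = 100,
    seed: int = 0,
    b: Optional[int] = None,
    config: Optional[PlacementConfig] = None,
    refit: bool = True,
) -> list[SupportedPlacement]:
    """Place every query of an alignment, sharing one replicate-weight
    matrix across queries (parametric methods use per-query derived seeds
    instead).  Results are independent of query order."""
    if method not in METHODS:
        raise ValueError(f"unknown support method {method!r}; choose from {METHODS}")
    weights = None
    if method in ("fast_bs", "slow_bs"):
        weights = make_bootstrap_weights(backbone.n_sites, B, seed)
    elif method == "subsample":
        weights = make_subsample_weights(backbone.n_sites, B, b=b, seed=seed)
    out = []
    for qid in queries.ids:
        out.append(
            compute_support(
                qid, queries.row(qid), backbone, tree,
                method=method, B=B, seed=seed, config=config,
                weights=weights, refit=refit,
            )
        )
    return out
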