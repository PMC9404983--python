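"""Least-squares phylogenetic placement (LSPP).

A query with observed distances ``delta_i`` to the backbone leaves is
attached to an edge ``e`` at position ``x`` from the proximal endpoint with
a pendant branch of length ``p``.  The resulting path distance to leaf
``i`` is ``p + x + c_i`` on the proximal side and ``p + (len(e) - x) + c_i``
on the distal side.  Placement minimizes the weighted least-squares error

    sum_i  w_i * (delta_i - d_i(T))^2,

with Fitch–Margoliash weights ``w_i = delta_i^-2`` by default, over all
edges and the box ``p >= 0, 0 <= x <= len(e)``.

Every edge is fitted exhaustively (O(n) per edge, so O(n^2) per query).
For a fixed edge the objective is a convex quadratic in ``(p, x)``: we
solve the 2x2 normal equations and, when the unconstrained optimum is
infeasible, minimize exactly over each boundary piece of the feasible box
(``p = 0``, ``x = 0``, ``x = len(e)``), taking the feasible candidate with
the smallest objective.  This is exact for a two-variable bound-constrained
quadratic.  The fit is vectorized across replicate distance vectors, which
is what makes bootstrap support cheap once distances are in hand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import nnls

from .distances import pairwise_corrected_distances
from .msa import Alignment
from .tree import BackboneTree

#: distances below this are clamped before inverse-power weighting
WEIGHT_EPS = 1e-6

#: relative tolerance within which per-edge LSE values count as tied
#: (ties resolve to the smallest edge number)
TIE_RTOL = 1e-9


@dataclass
class PlacementConfig:
    """Knobs of the least-squares objective.

    ``weight_exponent`` k gives weights ``w_i = delta_i^-k``; 2 is the
    Fitch–Margoliash default, 0 is ordinary least squares.  With
    ``nonneg_constraints`` off the unconstrained normal-equation solution
    is returned (pendant and attachment position may leave their bounds).
    """

    weight_exponent: float = 2.0
    nonneg_constraints: bool = True


@dataclass
class Placement:
    """Optimal attachment of one query: edge, position along it (from the
    proximal endpoint), pendant length, and the achieved weighted LSE."""

    query_id: str
    edge_num: int
    distal_length: float
    pendant_length: float
    lse: float


def weights_from_distances(delta, exponent: float = 2.0) -> np.ndarray:
    """Inverse-power least-squares weights; invalid (NaN/inf) distances get
    weight 0 so saturated pairs drop out of the objective."""
    delta = np.asarray(delta, dtype=float)
    w = np.zeros_like(delta)
    ok = np.isfinite(delta)
    if exponent == 0:
        w[ok] = 1.0
    else:
        w[ok] = np.maximum(delta[ok], WEIGHT_EPS) ** (-float(exponent))
    return w


def _fit_edge_batch(length, offsets, signs, delta, weights, constrained=True):
    """Constrained WLS fit of one edge for ``R`` replicate distance rows.

    ``offsets``/``signs`` are the per-leaf path model parameters for this
    edge (``d_i = p + signs_i * x + offsets_i``); ``delta`` and ``weights``
    are (R, n).  Returns ``(x, p, lse)`` arrays of shape (R,).
    """
    delta = np.atleast_2d(delta)
    w = np.atleast_2d(weights)
    r = np.where(w > 0, delta - offsets[None, :], 0.0)
    W = w.sum(axis=1)
    A = (w * signs[None, :]).sum(axis=1)
    Sr = (w * r).sum(axis=1)
    Srs = (w * r * signs[None, :]).sum(axis=1)
    Q = (w * r * r).sum(axis=1)

    def objective(p, x):
        return Q - 2 * p * Sr - 2 * x * Srs + (p * p + x * x) * W + 2 * p * x * A

    with np.errstate(divide="ignore", invalid="ignore"):
        det = W * W - A * A
        ok = det > np.finfo(float).tiny * 8
        p_u = np.where(ok, (W * Sr - A * Srs) / np.where(ok, det, 1.0), np.nan)
        x_u = np.where(ok, (W * Srs - A * Sr) / np.where(ok, det, 1.0), np.nan)
        safeW = np.where(W > 0, W, 1.0)
        if not constrained:
            p_u = np.where(ok, p_u, np.maximum(Sr / safeW, 0.0))
            x_u = np.where(ok, x_u, 0.0)
            f = np.maximum(objective(p_u, x_u), 0.0)
            f = np.where(W > 0, f, np.inf)
            return x_u, p_u, f
        # boundary pieces of {p >= 0, 0 <= x <= length}, each solved exactly
        cand_p = np.empty((4, delta.shape[0]))
        cand_x = np.empty_like(cand_p)
        cand_p[0], cand_x[0] = p_u, x_u  # unconstrained stationary point
        cand_p[1], cand_x[1] = 0.0, np.clip(Srs / safeW, 0.0, length)
        cand_p[2], cand_x[2] = np.maximum(Sr / safeW, 0.0), 0.0
        cand_p[3], cand_x[3] = np.maximum((Sr - length * A) / safeW, 0.0), length
        f = objective(cand_p, cand_x)
        feasible = (
            np.isfinite(cand_p)
            & (cand_p >= 0)
            & (cand_x >= 0)
            & (cand_x <= length)
        )
        f = np.where(feasible, f, np.inf)
        best = f.argmin(axis=0)
        take = np.arange(delta.shape[0])
        x = cand_x[best, take]
        p = cand_p[best, take]
        lse = np.maximum(f[best, take], 0.0)
        lse = np.where(W > 0, lse, np.inf)
        return x, p, lse


def edge_fit(edge_num: int, delta, weights, tree: BackboneTree, constrained=True):
    """Fit one edge for a single distance vector.

    Returns ``(x, p, lse)`` with ``x`` measured from the proximal (parent)
    endpoint.  The LSE is re-evaluated from residuals so it equals the
    objective at the returned point to machine precision.
    """
    delta = np.asarray(delta, dtype=float)
    w = np.asarray(weights, dtype=float)
    usable = (w > 0) & np.isfinite(delta)
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable distances for edge fit")
    length = tree.edge_length(edge_num)
    offs = tree.offsets[edge_num]
    signs = tree.signs[edge_num]
    x, p, _ = _fit_edge_batch(
        length, offs, signs, delta[None, :], w[None, :], constrained=constrained
    )
    d_model = p[0] + signs * x[0] + offs
    resid = np.where(usable, delta - d_model, 0.0)
    lse = float(np.sum(w * resid * resid))
    return float(x[0]), float(p[0]), lse


def place_replicates(delta, tree: BackboneTree, config: Optional[PlacementConfig] = None):
    """Place ``R`` replicate distance rows on a fixed tree.

    Returns ``(edges, x, p, lse)`` arrays of shape (R,); rows with fewer
    than 2 valid distances get edge ``-1`` and NaN geometry.
    """
    config = config or PlacementConfig()
    delta = np.atleast_2d(np.asarray(delta, dtype=float))
    R, n = delta.shape
    if n != tree.n_leaves:
        raise ValueError("distance vector length does not match leaf count")
    w = weights_from_distances(delta, config.weight_exponent)
    row_ok = (w > 0).sum(axis=1) >= 2
    E = tree.n_edges
    all_lse = np.full((E, R), np.inf)
    all_x = np.zeros((E, R))
    all_p = np.zeros((E, R))
    for e in range(E):
        x, p, f = _fit_edge_batch(
            tree.edge_lengths[e],
            tree.offsets[e],
            tree.signs[e],
            delta,
            w,
            constrained=config.nonneg_constraints,
        )
        all_x[e], all_p[e], all_lse[e] = x, p, f
    best = all_lse.min(axis=0)
    tied = all_lse <= best[None, :] * (1 + TIE_RTOL) + 1e-15
    edges = tied.argmax(axis=0)  # first (= smallest numbered) tied edge
    take = np.arange(R)
    x = all_x[edges, take]
    p = all_p[edges, take]
    lse = all_lse[edges, take]
    edges = np.where(row_ok & np.isfinite(lse), edges, -1)
    x = np.where(edges >= 0, x, np.nan)
    p = np.where(edges >= 0, p, np.nan)
    lse = np.where(edges >= 0, lse, np.nan)
    return edges, x, p, lse


def place_query(
    delta,
    tree: BackboneTree,
    config: Optional[PlacementConfig] = None,
    query_id: str = "query",
) -> Placement:
    """Solve the LSPP problem for one query by exhaustive per-edge fitting.

    Ties in the minimal LSE (within a relative tolerance of 1e-9) are
    broken deterministically by the smallest edge number.
    """
    config = config or PlacementConfig()
    delta = np.asarray(delta, dtype=float)
    if np.isfinite(delta).sum() < 2:
        raise ValueError("fewer than 2 valid distances; query cannot be placed")
    edges, x, p, _ = place_replicates(delta[None, :], tree, config)
    if edges[0] < 0:
        raise ValueError("no edge admitted a finite least-squares fit")
    e = int(edges[0])
    # recompute the objective from residuals for an exact LSE
    w = weights_from_distances(delta, config.weight_exponent)
    d_model = p[0] + tree.signs[e] * x[0] + tree.offsets[e]
    resid = np.where(w > 0, delta - d_model, 0.0)
    lse = float(np.sum(w * resid * resid))
    return Placement(
        query_id=query_id,
        edge_num=e,
        distal_length=float(x[0]),
        pendant_length=float(p[0]),
        lse=lse,
    )


# --------------------------------------------------------------------------
# branch-length re-estimation on a fixed topology
# --------------------------------------------------------------------------

def refit_from_distances(
    tree: BackboneTree,
    dist: np.ndarray,
    weight_exponent: float = 2.0,
    max_invalid_frac: float = 0.5,
) -> BackboneTree:
    """Non-negative WLS branch lengths from a leaf distance matrix.

    ``dist`` is ordered like ``tree.leaf_labels``; NaN entries (saturated
    or all-gap pairs) are excluded.  Raises if more than
    ``max_invalid_frac`` of the pairs are invalid.
    """
    n = tree.n_leaves
    if dist.shape != (n, n):
        raise ValueError("distance matrix does not match leaf count")
    iu, ju = np.triu_indices(n, k=1)
    d = dist[iu, ju]
    ok = np.isfinite(d)
    if ok.mean() < 1.0 - max_invalid_frac:
        raise ValueError(
            f"{(~ok).sum()} of {ok.size} pairwise distances invalid; refit aborted"
        )
    iu, ju, d = iu[ok], ju[ok], d[ok]
    # design matrix: edge e is on the path i..j iff exactly one endpoint
    # has e on its root path
    inc = tree.leaf_edge_incidence
    A = (inc[iu] ^ inc[ju]).astype(float)
    w = weights_from_distances(d, weight_exponent)
    sw = np.sqrt(w)
    lengths, _ = nnls(A * sw[:, None], d * sw)
    return tree.with_edge_lengths(lengths)


def refit_branch_lengths(
    tree: BackboneTree,
    alignment: Alignment,
    weight_exponent: float = 2.0,
    max_invalid_frac: float = 0.5,
) -> BackboneTree:
    """Re-estimate branch lengths on the fixed topology from an alignment
    of the backbone leaves (e.g. a bootstrap-resampled one).

    Pairwise corrected distances (JC69 or Scoredist by alphabet) are fitted
    to path lengths by non-negative weighted least squares with weights
    ``delta^-2``; topology and edge numbering are unchanged.  Pairs without
    mutually ungapped sites are excluded from the fit.
    """
    missing = [s for s in tree.leaf_labels if s not in alignment]
    if missing:
        raise ValueError(f"alignment missing backbone leaves: {missing[:5]}")
    dist = pairwise_corrected_distances(alignment, rows=tree.leaf_labels)
    return refit_from_distances(tree, dist, weight_exponent, max_invalid_frac)
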