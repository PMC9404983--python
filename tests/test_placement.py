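import numpy as np
import pytest

from helpers import oracle_edge_lse

from lsplace import (
    Alignment,
    BackboneTree,
    Placement,
    PlacementConfig,
    edge_fit,
    place_query,
    refit_branch_lengths,
)
from lsplace.placement import place_replicates, weights_from_distances
from lsplace.synthetic import evolve_jc69, make_queries, simulate_tree


def _delta_for(tree, labels_to_dist):
    return np.array([labels_to_dist[s] for s in tree.leaf_labels])


def _dummy_alignment(tree):
    return Alignment(list(tree.leaf_labels),
                     np.full((tree.n_leaves, 1), ord("A"), dtype=np.uint8), "dna")


# ------------------------------------------------------------------ edge_fit

def test_quartet_midpoint_recovery(quartet):
    """Additive distances for a query hung off the middle of the internal
    edge with pendant 0.5 are recovered exactly."""
    delta = _delta_for(quartet, {"A": 2.0, "B": 2.0, "C": 3.0, "D": 3.0})
    pl = place_query(delta, quartet)
    assert quartet.leafset_below(pl.edge_num) == frozenset({"A", "B"})
    assert pl.distal_length == pytest.approx(0.5, abs=1e-9)
    assert pl.pendant_length == pytest.approx(0.5, abs=1e-9)
    assert pl.lse <= 1e-12


def test_boundary_solution_pendant_only(quartet):
    """delta_i = dist(proximal endpoint, i) + 1 for every leaf forces the
    boundary optimum p=1, x=0."""
    e = next(e for e in range(quartet.n_edges)
             if quartet.leafset_below(e) == frozenset({"A", "B"}))
    # distances from the proximal endpoint (the root) of the internal edge
    d_root = {"A": 2.0, "B": 2.0, "C": 2.0, "D": 2.0}
    delta = _delta_for(quartet, {s: d_root[s] + 1.0 for s in d_root})
    w = np.ones(4)
    x, p, lse = edge_fit(e, delta, w, quartet)
    assert x == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0, abs=1e-9)
    assert lse <= 1e-18


def test_two_leaf_degenerate_backbone_exact():
    t = BackboneTree.from_newick("(A:1,B:2);")
    # query at x=0.4 from the root on A's edge with pendant 0.1
    delta = _delta_for(t, {"A": 0.1 + 0.6, "B": 0.1 + 0.4 + 2.0})
    pl = place_query(delta, t)
    assert pl.lse <= 1e-18
    assert t.leafset_below(pl.edge_num) == frozenset({"A"})


def test_edge_fit_requires_two_usable_distances(quartet):
    with pytest.raises(ValueError, match="fewer than 2"):
        edge_fit(0, np.array([1.0, np.nan, np.nan, np.nan]),
                 np.array([1.0, 0, 0, 0]), quartet)


def test_lse_equals_objective_at_solution(quartet):
    rng = np.random.default_rng(0)
    delta = rng.uniform(0.5, 4.0, size=4)
    w = weights_from_distances(delta, 2.0)
    for e in range(quartet.n_edges):
        x, p, lse = edge_fit(e, delta, w, quartet)
        m = np.where(quartet.signs[e] > 0,
                     p + x + quartet.offsets[e],
                     p - x + quartet.offsets[e])
        assert lse == pytest.approx(float(np.sum(w * (delta - m) ** 2)), abs=1e-9)


# ------------------------------------------------------------------ place_query

def test_exact_recovery_random_trees():
    """Pruned leaves with additive noise-free distances come back on the
    pruning edge with (numerically) zero error."""
    rng = np.random.default_rng(42)
    for rep in range(12):
        n = int(rng.integers(8, 33))
        tree = simulate_tree(n, branch_scale=0.3, seed=int(rng.integers(2**31 - 1)))
        backbone, _, _, truth = make_queries(
            tree, _dummy_alignment(tree), 1, seed=int(rng.integers(2**31 - 1))
        )
        (qid, true_edge), = truth.items()
        delta = tree.path_distance_matrix([qid] + backbone.leaf_labels)[0, 1:]
        pl = place_query(delta, backbone, query_id=qid)
        assert pl.edge_num == true_edge
        assert pl.lse <= 1e-10


def test_per_edge_fits_match_convex_oracle():
    """Constrained per-edge optima agree with an independent brute-force
    optimizer (graph distances + bounded 1-D search)."""
    rng = np.random.default_rng(11)
    for rep in range(8):
        tree = simulate_tree(8, branch_scale=0.5, seed=int(rng.integers(2**31 - 1)))
        delta = rng.uniform(0.3, 3.0, size=tree.n_leaves)
        w = weights_from_distances(delta, 2.0)
        for e in range(tree.n_edges):
            _, _, lse = edge_fit(e, delta, w, tree)
            ref = oracle_edge_lse(tree, e, delta, w)
            assert lse == pytest.approx(ref, abs=2e-6)


def test_tie_broken_by_smallest_edge_num(quartet):
    """A query equidistant from everything fits the two mirrored pendant
    edges equally well; the smaller edge number must win."""
    delta = _delta_for(quartet, {"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0})
    pl = place_query(delta, quartet, PlacementConfig(weight_exponent=0))
    edges, _, _, lse = place_replicates(delta[None, :], quartet,
                                        PlacementConfig(weight_exponent=0))
    ties = [e for e in range(quartet.n_edges)
            if edge_fit(e, delta, np.ones(4), quartet)[2] <= lse[0] * (1 + 1e-9) + 1e-15]
    assert pl.edge_num == min(ties)


def test_weight_exponent_zero_is_ols_on_star_tree():
    star = BackboneTree.from_newick("(A:0.5,B:0.5,C:0.7,D:0.9);")
    e = next(e for e in range(star.n_edges) if star.leafset_below(e) == frozenset({"A"}))
    rng = np.random.default_rng(5)
    delta = np.array([0.6, 1.0, 1.2, 1.4]) + rng.normal(0, 0.05, 4)
    x, p, lse = edge_fit(e, delta, np.ones(4), star, constrained=False)
    # closed-form OLS: d_i = p + s_i x + b_i
    design = np.column_stack([np.ones(4), star.signs[e]])
    coef, *_ = np.linalg.lstsq(design, delta - star.offsets[e], rcond=None)
    assert p == pytest.approx(coef[0], abs=1e-9)
    assert x == pytest.approx(coef[1], abs=1e-9)


def test_invalid_distances_get_zero_weight(quartet):
    delta = _delta_for(quartet, {"A": 2.0, "B": 2.0, "C": np.nan, "D": 3.0})
    pl = place_query(delta, quartet)
    assert np.isfinite(pl.lse)
    with pytest.raises(ValueError, match="fewer than 2 valid"):
        place_query(np.array([np.nan, np.nan, np.nan, 1.0]), quartet)


def test_batch_and_scalar_placements_agree(quartet):
    rng = np.random.default_rng(9)
    delta = rng.uniform(0.5, 4.0, size=(20, 4))
    edges, x, p, lse = place_replicates(delta, quartet)
    for i in range(20):
        pl = place_query(delta[i], quartet)
        assert pl.edge_num == edges[i]
        assert pl.lse == pytest.approx(lse[i], abs=1e-9)


# ------------------------------------------------------------------ refit

def test_refit_recovers_simulated_branch_lengths():
    tree = simulate_tree(16, branch_scale=0.1, seed=77)
    aln = evolve_jc69(tree, 5000, seed=78)
    refit = refit_branch_lengths(tree, aln)
    assert refit.n_edges == tree.n_edges
    true_len = tree.edge_lengths
    est = refit.edge_lengths
    big = true_len >= 0.05
    rel = np.abs(est[big] - true_len[big]) / true_len[big]
    assert np.all(rel < 0.15)


def test_refit_is_deterministic():
    tree = simulate_tree(10, branch_scale=0.1, seed=3)
    aln = evolve_jc69(tree, 800, seed=4)
    a = refit_branch_lengths(tree, aln).edge_lengths
    b = refit_branch_lengths(tree, aln).edge_lengths
    assert np.array_equal(a, b)


def test_refit_excludes_all_gap_pairs():
    tree = BackboneTree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
    L = 400
    aln0 = evolve_jc69(tree, L, seed=10)
    mat = aln0.matrix.copy()
    ids = list(aln0.ids)
    # A and B observed on disjoint halves: the A-B pair has no overlap
    mat[ids.index("A"), : L // 2] = ord("-")
    mat[ids.index("B"), L // 2 :] = ord("-")
    refit = refit_branch_lengths(tree, Alignment(ids, mat, "dna"))
    assert np.all(np.isfinite(refit.edge_lengths))


def test_refit_aborts_when_too_many_pairs_invalid():
    tree = BackboneTree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
    mat = np.full((4, 10), ord("-"), dtype=np.uint8)
    mat[0, :5] = ord("A")
    mat[1, 5:] = ord("A")
    mat[2, :5] = ord("C")
    mat[3, 5:] = ord("C")
    aln = Alignment(["A", "B", "C", "D"], mat, "dna")
    with pytest.raises(ValueError, match="invalid"):
        refit_branch_lengths(tree, aln, max_invalid_frac=0.3)
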