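import numpy as np
import pytest

from helpers import random_alignment

from lsplace import (
    build_profile,
    compute_support,
    distances_from_counts,
    fast_bootstrap_distances,
    jc69_expected_h,
    make_bootstrap_weights,
    make_subsample_weights,
    parametric_distances,
    slow_bootstrap,
    subsample_distances,
)
from lsplace.msa import Alignment
from lsplace.support import aggregate_support, default_subsample_size, query_seed
from lsplace.synthetic import evolve_jc69, naive_bootstrap_oracle, simulate_tree, make_queries


# ------------------------------------------------------------------ weights

def test_bootstrap_weights_invariants():
    w = make_bootstrap_weights(L=50, B=20, seed=1)
    assert w.matrix.shape == (21, 50)
    assert np.all(w.matrix[0] == 1)
    assert np.all(w.matrix[1:].sum(axis=1) == 50)
    assert np.all(w.matrix >= 0)
    again = make_bootstrap_weights(L=50, B=20, seed=1)
    assert np.array_equal(w.matrix, again.matrix)
    with pytest.raises(ValueError):
        make_bootstrap_weights(0, 5, 1)


def test_bootstrap_weights_multinomial_moments():
    w = make_bootstrap_weights(L=100, B=10_000, seed=2)
    means = w.matrix[1:].mean(axis=0)
    # per-site count variance L*(1/L)*(1-1/L) = 0.99
    se = np.sqrt(0.99 / 10_000)
    assert np.all(np.abs(means - 1.0) < 4 * se)
    assert abs(means.mean() - 1.0) < 1e-12  # rows sum to L exactly


def test_subsample_weights_invariants():
    w = make_subsample_weights(L=40, B=15, b=10, seed=3)
    assert set(np.unique(w.matrix)) <= {0, 1}
    assert np.all(w.matrix[1:].sum(axis=1) == 10)
    assert np.all(w.matrix[0] == 1)
    full = make_subsample_weights(L=12, B=4, b=12, seed=0)
    assert np.all(full.matrix == 1)
    with pytest.raises(ValueError):
        make_subsample_weights(L=10, B=2, b=11, seed=0)


def test_default_subsample_size():
    assert default_subsample_size(1000) == 501  # round(1000^0.9)
    assert default_subsample_size(2000) == 935


# ------------------------------------------------------------------ fast bootstrap vs naive

def test_fast_bootstrap_matches_naive_oracle_exactly():
    rng = np.random.default_rng(17)
    for rep in range(6):
        n = int(rng.integers(4, 9))
        L = int(rng.integers(20, 60))
        aln = random_alignment(rng, n, L, gap_frac=0.15)
        q = aln.matrix[0]
        prof = build_profile(q, aln)
        w = make_bootstrap_weights(L, B=8, seed=int(rng.integers(2**31 - 1)))
        fast = fast_bootstrap_distances(w, prof)
        for i in range(w.matrix.shape[0]):
            mism, valid = naive_bootstrap_oracle(aln, q, w.matrix[i])
            d_naive = distances_from_counts(mism[None, :].astype(float),
                                            valid[None, :].astype(float))
            assert np.array_equal(
                np.nan_to_num(fast.hamming[i], nan=-1),
                np.nan_to_num(d_naive.hamming[0], nan=-1),
            )
            assert np.array_equal(
                np.nan_to_num(fast.corrected[i], nan=-1),
                np.nan_to_num(d_naive.corrected[0], nan=-1),
            )


def test_identity_row_equals_direct_distances():
    rng = np.random.default_rng(8)
    aln = random_alignment(rng, 5, 30)
    prof = build_profile(aln.matrix[0], aln)
    w = make_bootstrap_weights(30, B=1, seed=0)
    fast = fast_bootstrap_distances(w, prof)
    mism, valid = naive_bootstrap_oracle(aln, aln.matrix[0], np.ones(30, dtype=int))
    assert np.array_equal(fast.valid_sites[0], valid)
    assert fast.hamming[0, 0] == 0.0


def test_all_zero_weight_row_flags_invalid():
    aln = Alignment(["r0", "r1"], np.frombuffer(b"ACGTACGT", np.uint8).reshape(2, 4), "dna")
    prof = build_profile("ACGT", aln)
    H = np.vstack([np.ones(4, int), np.zeros(4, int)])
    from lsplace.support import ReplicateWeights
    w = ReplicateWeights(kind="bootstrap", matrix=H, B=1, seed=0)
    fast = fast_bootstrap_distances(w, prof)
    assert not fast.valid[1].any()


# ------------------------------------------------------------------ subsampling

def test_subsample_full_size_reproduces_original_h():
    rng = np.random.default_rng(21)
    aln = random_alignment(rng, 5, 40)
    prof = build_profile(aln.matrix[0], aln)
    w = make_subsample_weights(40, B=6, b=40, seed=1)
    d = subsample_distances(w, prof)
    for i in range(7):
        assert np.allclose(d.hamming[i], d.hamming[0], equal_nan=True)


def test_subsample_correction_variance_theory():
    """The sqrt(b/n)-corrected Hamming variance equals the bootstrap
    variance times the finite-population term (n-b)/(n-1): without
    replacement, a size-b subsample of n sites has variance
    (sigma^2/b) * (n-b)/(n-1), so the corrected replicate variance is
    smaller than the bootstrap's sigma^2/n unless b << n.  At small b/n
    the two converge, which is the asymptotic regime the correction
    targets."""
    tree_h = jc69_expected_h(0.2)
    rng = np.random.default_rng(31)
    L = 2000
    q = np.frombuffer(b"A" * L, np.uint8).copy()
    ref = q.copy()
    flip = rng.random(L) < tree_h
    ref[flip] = ord("C")
    aln = Alignment(["ref"], ref[None, :], "dna")
    prof = build_profile(q, aln)
    B = 3000
    v_bs = np.nanvar(
        fast_bootstrap_distances(make_bootstrap_weights(L, B=B, seed=6), prof).hamming[1:, 0]
    )
    for b in (935, 45):  # default round(L^0.9), and a b << n regime
        v_sub = np.nanvar(
            subsample_distances(make_subsample_weights(L, B=B, b=b, seed=5), prof).hamming[1:, 0]
        )
        fpc = (L - b) / (L - 1)
        assert v_sub == pytest.approx(v_bs * fpc, rel=0.15)
    # and in the b << n regime the corrected variance matches the bootstrap
    assert v_sub == pytest.approx(v_bs, rel=0.15)


# ------------------------------------------------------------------ parametric

def test_binomial_and_poisson_moments():
    h_hat, l, B = np.array([0.25]), np.array([400]), 5000
    d_b = parametric_distances(h_hat, l, B, mode="binomial", seed=1)
    se = np.sqrt(0.25 * 0.75 / 400) / np.sqrt(B)
    assert abs(np.nanmean(d_b.hamming[1:, 0]) - 0.25) < 3 * se
    d_p = parametric_distances(h_hat, l, B, mode="poisson", seed=2)
    se_p = np.sqrt(0.25 / 400) / np.sqrt(B)  # Poisson var = lambda
    assert abs(np.nanmean(d_p.hamming[1:, 0]) - 0.25) < 3 * se_p


def test_parametric_degenerate_and_saturated():
    d = parametric_distances(np.array([0.0]), np.array([100]), 50, seed=0)
    assert np.all(d.corrected == 0.0)
    # one saturated reference among valid ones -> flagged, not fatal
    d2 = parametric_distances(np.array([0.8, 0.2]), np.array([100, 100]), 20, seed=0)
    assert not d2.valid[:, 0].any() and d2.valid[0, 1]
    with pytest.raises(ValueError, match="saturated"):
        parametric_distances(np.array([0.9]), np.array([100]), 10, seed=0)


# ------------------------------------------------------------------ aggregation / semantics

def test_aggregate_support_fractions():
    choices = np.array([1] * 75 + [2] * 25)
    support, n_inv = aggregate_support(choices)
    assert support == {1: 0.75, 2: 0.25} and n_inv == 0
    support2, n_inv2 = aggregate_support(np.array([3] * 10 + [-1] * 5))
    assert support2 == {3: 1.0} and n_inv2 == 5
    with pytest.raises(ValueError):
        aggregate_support(np.array([-1, -1]))


@pytest.fixture(scope="module")
def small_study():
    tree = simulate_tree(24, branch_scale=0.08, seed=100)
    aln = evolve_jc69(tree, 400, seed=101)
    backbone, backbone_aln, queries, truth = make_queries(tree, aln, 4, seed=102)
    return backbone, backbone_aln, queries, truth


@pytest.mark.parametrize("method", ["fast_bs", "subsample", "binomial", "poisson"])
def test_support_sums_to_one_and_is_deterministic(small_study, method):
    backbone, backbone_aln, queries, _ = small_study
    qid = queries.ids[0]
    a = compute_support(qid, queries.row(qid), backbone_aln, backbone,
                        method=method, B=30, seed=9)
    b = compute_support(qid, queries.row(qid), backbone_aln, backbone,
                        method=method, B=30, seed=9)
    assert abs(sum(a.support.values()) - 1.0) < 1e-9
    assert a.support == b.support
    assert a.placement.edge_num == b.placement.edge_num
    assert all(0 <= e < backbone.n_edges for e in a.support)


def test_single_replicate_gives_unit_support(small_study):
    backbone, backbone_aln, queries, _ = small_study
    qid = queries.ids[1]
    sp = compute_support(qid, queries.row(qid), backbone_aln, backbone,
                         method="fast_bs", B=1, seed=4)
    assert list(sp.support.values()) == [1.0]


def test_slow_bootstrap_without_refit_equals_fast(small_study):
    backbone, backbone_aln, queries, _ = small_study
    qid = queries.ids[2]
    H = make_bootstrap_weights(backbone_aln.n_sites, B=20, seed=13)
    fast = compute_support(qid, queries.row(qid), backbone_aln, backbone,
                           method="fast_bs", B=20, seed=13, weights=H)
    slow = slow_bootstrap(qid, queries.row(qid), backbone_aln, backbone,
                          B=20, seed=13, refit=False, weights=H)
    assert slow.support == fast.support
    assert slow.placement.edge_num == fast.placement.edge_num


def test_slow_bootstrap_with_refit_runs_and_is_deterministic(small_study):
    backbone, backbone_aln, queries, _ = small_study
    qid = queries.ids[3]
    a = slow_bootstrap(qid, queries.row(qid), backbone_aln, backbone, B=5, seed=3)
    b = slow_bootstrap(qid, queries.row(qid), backbone_aln, backbone, B=5, seed=3)
    assert a.support == b.support
    assert abs(sum(a.support.values()) - 1.0) < 1e-9


def test_signal_free_query_spreads_support(small_study):
    backbone, backbone_aln, _, _ = small_study
    rng = np.random.default_rng(55)
    junk = np.frombuffer(b"ACGT", np.uint8)[rng.integers(0, 4, backbone_aln.n_sites)]
    sp = compute_support("junk", junk, backbone_aln, backbone,
                         method="fast_bs", B=100, seed=7)
    assert len(sp.support) > 1
    assert max(sp.support.values()) < 1.0


def test_query_seed_is_stable_and_order_free():
    assert query_seed(42, "q1") == query_seed(42, "q1")
    assert query_seed(42, "q1") != query_seed(42, "q2")
    assert 0 <= query_seed(123456, "anything") < 2**31


def test_parametric_rank_agreement_with_bootstrap(small_study):
    """Parametric and nonparametric supports should broadly agree on which
    edges are plausible for the same query (they differ in calibration,
    not in ordering)."""
    backbone, backbone_aln, queries, _ = small_study
    qid = queries.ids[0]
    bs = compute_support(qid, queries.row(qid), backbone_aln, backbone,
                         method="fast_bs", B=100, seed=8)
    par = compute_support(qid, queries.row(qid), backbone_aln, backbone,
                          method="binomial", B=100, seed=8)
    top_bs = max(bs.support, key=bs.support.get)
    assert top_bs in par.support
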