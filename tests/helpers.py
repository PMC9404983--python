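"""Shared test utilities: random fixtures and independent oracles."""

import numpy as np
from scipy.optimize import minimize_scalar

from lsplace.msa import Alignment


def random_alignment(rng, n_rows, L, gap_frac=0.1, alphabet="dna", prefix="s"):
    chars = np.frombuffer(
        b"ACGT" if alphabet == "dna" else b"ACDEFGHIKLMNPQRSTVWY", np.uint8
    )
    mat = chars[rng.integers(0, chars.size, size=(n_rows, L))]
    gaps = rng.random((n_rows, L)) < gap_frac
    mat = np.where(gaps, ord("-"), mat)
    ids = [f"{prefix}{k}" for k in range(n_rows)]
    return Alignment(ids, mat, alphabet)


# ---------------------------------------------------------------------------
# independent placement oracle: graph path distances + 1-D convex search
# ---------------------------------------------------------------------------

def _graph_leaf_distances(tree, start_node):
    """Path distance from a node to every leaf by plain graph traversal
    (independent of the tree's precomputed geometry)."""
    adj = {}
    for nd in tree._tree.preorder_node_iter():
        adj.setdefault(id(nd), [])
        if nd.parent_node is not None:
            adj[id(nd)].append((nd.parent_node, nd.edge.length))
            adj.setdefault(id(nd.parent_node), []).append((nd, nd.edge.length))
    dist = {id(start_node): 0.0}
    stack = [start_node]
    while stack:
        cur = stack.pop()
        for nxt, w in adj[id(cur)]:
            if id(nxt) not in dist:
                dist[id(nxt)] = dist[id(cur)] + w
                stack.append(nxt)
    out = np.empty(tree.n_leaves)
    for nd in tree._tree.leaf_node_iter():
        out[tree._leaf_index[nd.taxon.label]] = dist[id(nd)]
    return out


def oracle_edge_lse(tree, edge_num, delta, weights):
    """Brute-force optimum of the per-edge weighted LSE.

    The attachment point at position x from the proximal endpoint is at
    path distance min(x + d_u(i), (len - x) + d_v(i)) from leaf i, with
    d_u/d_v plain graph distances; the pendant is optimized in closed form
    for each x (clamped at 0) and x by bounded search on [0, len] — the
    partially minimized objective is convex in x.
    """
    child = tree._edge_nodes[edge_num]
    parent = child.parent_node
    du = _graph_leaf_distances(tree, parent)
    dv = _graph_leaf_distances(tree, child)
    length = tree.edge_length(edge_num)
    w = np.asarray(weights, float)
    d = np.where(w > 0, np.asarray(delta, float), 0.0)
    wsum = w.sum()

    def f(x):
        m = np.minimum(x + du, (length - x) + dv)
        p = max(0.0, float(np.sum(w * (d - m)) / wsum))
        r = np.where(w > 0, d - p - m, 0.0)
        return float(np.sum(w * r * r))

    if length == 0:
        return f(0.0)
    res = minimize_scalar(f, bounds=(0.0, length), method="bounded",
                          options={"xatol": 1e-12})
    return min(res.fun, f(0.0), f(length))
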