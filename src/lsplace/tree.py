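"""Backbone tree with stable edge numbering, path geometry, and jplace I/O.

The reference tree is unrooted in spirit but stored in the rooted
representation produced by the Newick parser.  Every node except the seed
root defines one edge (the edge to its parent).  Edge numbers are assigned
by depth-first post-order of that representation, so serializing and
re-reading a tree reproduces the numbering exactly — the stability jplace
consumers rely on.

For placement the module precomputes, for every edge ``e`` with proximal
endpoint ``u`` (parent) and distal endpoint ``v`` (child):

* which leaves lie on the distal side of ``e`` (below ``v``), and
* the path length from the relevant endpoint to every leaf, so that a query
  attached at position ``x`` from ``u`` with pendant ``p`` has path distance
  ``p + x + c_i`` to proximal leaves and ``p + (len(e) - x) + c_i`` to
  distal leaves.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

import dendropy
import numpy as np

JPLACE_FIELDS = [
    "edge_num",
    "support",
    "least_squares_error",
    "distal_length",
    "pendant_length",
]


class BackboneTree:
    """Unrooted, leaf-labeled tree with non-negative branch lengths and a
    stable edge numbering (a bijection onto ``0..n_edges-1``)."""

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        root = dtree.seed_node
        if root is None or root.is_leaf():
            raise ValueError("tree must have at least one internal node")

        nodes = [nd for nd in dtree.postorder_node_iter() if nd is not root]
        if not nodes:
            raise ValueError("empty tree")
        for nd in nodes:
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("unlabeled leaf in tree")
            bl = nd.edge.length
            if bl is None:
                raise ValueError("missing branch length")
            if not math.isfinite(bl):
                raise ValueError("non-finite branch length")
            if bl < 0:
                raise ValueError(f"negative branch length {bl}")

        self._edge_nodes = nodes
        for k, nd in enumerate(nodes):
            nd.edge_num = k
        self.edge_lengths = np.array([nd.edge.length for nd in nodes], dtype=float)

        leaves = [nd for nd in dtree.postorder_node_iter() if nd.is_leaf()]
        self.leaf_labels = [nd.taxon.label for nd in leaves]
        if len(set(self.leaf_labels)) != len(self.leaf_labels):
            raise ValueError("duplicate leaf labels")
        self._leaf_index = {s: k for k, s in enumerate(self.leaf_labels)}
        n = len(leaves)

        all_nodes = list(dtree.postorder_node_iter())
        row = {id(nd): k for k, nd in enumerate(all_nodes)}
        dist = np.full((len(all_nodes), n), np.inf)
        # pass 1 (post-order): distances to leaves inside each subtree
        for nd in all_nodes:
            r = row[id(nd)]
            if nd.is_leaf():
                dist[r, self._leaf_index[nd.taxon.label]] = 0.0
            else:
                for ch in nd.child_nodes():
                    cr = row[id(ch)]
                    np.minimum(dist[r], dist[cr] + ch.edge.length, out=dist[r])
        below = np.isfinite(dist)  # leaf-below-node indicator
        # pass 2 (pre-order): fill distances to leaves outside the subtree
        for nd in dtree.preorder_node_iter():
            r = row[id(nd)]
            for ch in nd.child_nodes():
                cr = row[id(ch)]
                missing = ~np.isfinite(dist[cr])
                dist[cr, missing] = dist[r, missing] + ch.edge.length

        self._row = row
        self._node_leaf_dist = dist
        E = len(nodes)
        self.distal_mask = np.empty((E, n), dtype=bool)
        b_mat = np.empty((E, n))
        for k, nd in enumerate(nodes):
            r = row[id(nd)]
            pr = row[id(nd.parent_node)]
            dm = below[r]
            self.distal_mask[k] = dm
            # distal refs: offset = edge length + dist(child, leaf)
            # proximal refs: offset = dist(parent, leaf), path avoiding e
            b_mat[k] = np.where(dm, self.edge_lengths[k] + dist[r], dist[pr])
        self.offsets = b_mat
        self.signs = np.where(self.distal_mask, -1.0, 1.0)

        leaf_rows = [row[id(nd)] for nd in leaves]
        self.leaf_dist = dist[leaf_rows]  # (n, n) path distances

        # leaf -> edges on the path to the seed root (for WLS refitting)
        inc = np.zeros((n, E), dtype=bool)
        for nd in leaves:
            i = self._leaf_index[nd.taxon.label]
            cur = nd
            while cur is not root:
                inc[i, cur.edge_num] = True
                cur = cur.parent_node
        self.leaf_edge_incidence = inc

    # -- basic properties -------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_edges(self) -> int:
        return len(self._edge_nodes)

    def edge_length(self, edge_num: int) -> float:
        return float(self.edge_lengths[edge_num])

    def leafset_below(self, edge_num: int) -> frozenset:
        """Labels on the distal side of an edge."""
        mask = self.distal_mask[edge_num]
        return frozenset(s for s, m in zip(self.leaf_labels, mask) if m)

    def path_distance_matrix(self, labels=None) -> np.ndarray:
        """Leaf-to-leaf path distances, ordered like ``labels``
        (default: ``leaf_labels``)."""
        if labels is None:
            return self.leaf_dist.copy()
        idx = [self._leaf_index[s] for s in labels]
        return self.leaf_dist[np.ix_(idx, idx)]

    # -- construction / transformation ------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "BackboneTree":
        try:
            dt = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"unparseable Newick: {exc}") from exc
        return cls(dt)

    def with_edge_lengths(self, lengths) -> "BackboneTree":
        """Copy of the tree with branch lengths replaced, indexed by
        edge number.  Topology and edge numbering are unchanged."""
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != (self.n_edges,):
            raise ValueError("length vector does not match edge count")
        dt = self._tree.clone(depth=1)
        nodes = [nd for nd in dt.postorder_node_iter() if nd is not dt.seed_node]
        for k, nd in enumerate(nodes):
            nd.edge.length = float(lengths[k])
        return BackboneTree(dt)

    def copy(self) -> "BackboneTree":
        return BackboneTree(self._tree.clone(depth=1))

    # -- serialization -----------------------------------------------------
    def newick(self, edge_numbers: bool = False) -> str:
        """Serialize to Newick; with ``edge_numbers`` each branch length is
        followed by a jplace-style ``{edge_num}`` annotation."""

        def fmt(nd) -> str:
            if nd.is_leaf():
                s = nd.taxon.label
            else:
                s = "(" + ",".join(fmt(ch) for ch in nd.child_nodes()) + ")"
            if nd is self._tree.seed_node:
                return s
            s += f":{nd.edge.length:.12g}"
            if edge_numbers:
                s += f"{{{nd.edge_num}}}"
            return s

        return fmt(self._tree.seed_node) + ";"


def read_tree(path) -> BackboneTree:
    """Read a Newick file; edges are numbered by the canonical post-order
    traversal so that re-reading a written tree reproduces the numbering."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"empty tree file {path}")
    return BackboneTree.from_newick(text)


def write_tree(tree: BackboneTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


# --------------------------------------------------------------------------
# jplace
# --------------------------------------------------------------------------

def write_jplace(tree: BackboneTree, placements, path, invocation: str = "") -> None:
    """Write placements with support to a jplace (v3) JSON file.

    ``placements`` is an iterable of objects with attributes ``query_id``,
    ``support`` (edge_num -> fraction) and ``edge_fits``
    (edge_num -> (distal_length, pendant_length, lse)).  Rows for each query
    are sorted by descending support (ties by edge number).
    """
    plist = []
    for sp in placements:
        rows = []
        for edge, sup in sorted(sp.support.items(), key=lambda kv: (-kv[1], kv[0])):
            if not 0 <= edge < tree.n_edges:
                raise ValueError(f"unknown edge number {edge}")
            distal, pendant, lse = sp.edge_fits.get(
                edge, (float("nan"),) * 3
            )
            rows.append([int(edge), float(sup), float(lse), float(distal), float(pendant)])
        plist.append({"p": rows, "n": [sp.query_id]})
    doc = {
        "version": 3,
        "tree": tree.newick(edge_numbers=True),
        "placements": plist,
        "fields": JPLACE_FIELDS,
        "metadata": {"invocation": invocation},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_jplace(path):
    """Read a jplace file written by this package.

    Returns ``(tree, placements)`` where ``placements`` is a list of dicts
    with keys ``query_id``, ``support`` and ``edge_fits``.  Edge numbers are
    recomputed by the canonical traversal, which round-trips files written
    by :func:`write_jplace` exactly.
    """
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("version", "tree", "placements", "fields"):
        if key not in doc:
            raise ValueError(f"jplace file missing required key {key!r}")
    tree = BackboneTree.from_newick(re.sub(r"\{\d+\}", "", doc["tree"]))
    fields = doc["fields"]
    idx = {f: fields.index(f) for f in fields}
    out = []
    for entry in doc["placements"]:
        name = entry.get("n", entry.get("nm", ["?"]))[0]
        if isinstance(name, list):  # "nm" pairs [name, multiplicity]
            name = name[0]
        support, fits = {}, {}
        for rowvals in entry["p"]:
            e = int(rowvals[idx["edge_num"]])
            support[e] = float(rowvals[idx["support"]])
            fits[e] = (
                float(rowvals[idx["distal_length"]]),
                float(rowvals[idx["pendant_length"]]),
                float(rowvals[idx["least_squares_error"]]),
            )
        out.append({"query_id": name, "support": support, "edge_fits": fits})
    return tree, out


# --------------------------------------------------------------------------
# leaf pruning (tree surgery used to build backbones and truth tables)
# --------------------------------------------------------------------------

def _leafset(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _splice_out(dtree, node) -> None:
    """Remove a unifurcating internal ``node``, merging its two incident
    edges (lengths add)."""
    (child,) = node.child_nodes()
    parent = node.parent_node
    node.remove_child(child)
    child.edge.length += node.edge.length
    kids = parent.child_nodes()
    kids[kids.index(node)] = child
    parent.remove_child(node)
    parent.set_child_nodes(kids)


def prune_leaf(dtree: dendropy.Tree, label: str):
    """Remove one leaf from a (binary, trifurcating-rooted) dendropy tree
    in place, suppressing the resulting degree-2 node.

    Returns the node whose parent edge is the merged attachment edge — the
    edge onto which the removed leaf was attached.
    """
    leaf = None
    for nd in dtree.leaf_node_iter():
        if nd.taxon is not None and nd.taxon.label == label:
            leaf = nd
            break
    if leaf is None:
        raise KeyError(f"leaf {label!r} not in tree")
    parent = leaf.parent_node
    if parent is None:
        raise ValueError("cannot prune the only node of a tree")
    parent.remove_child(leaf)
    siblings = parent.child_nodes()
    if parent is not dtree.seed_node:
        if len(siblings) != 1:
            raise ValueError("pruning requires a binary internal node")
        tracked = siblings[0]
        _splice_out(dtree, parent)
        return tracked
    # parent is the (trifurcating) root
    if len(siblings) > 2:
        raise ValueError("cannot identify a single attachment edge at a multifurcating root")
    if len(siblings) < 2:
        raise ValueError("tree too small to prune")
    a, b = siblings
    # suppress the now degree-2 root: absorb an internal child into the root
    if b.is_leaf() and a.is_leaf():
        raise ValueError("tree too small to prune")
    if not b.is_leaf():
        absorb, keep = b, a
    else:
        absorb, keep = a, b
    parent.remove_child(absorb)
    parent.remove_child(keep)
    kids = absorb.child_nodes()
    for ch in list(kids):
        absorb.remove_child(ch)
    parent.set_child_nodes(kids + [keep])
    keep.edge.length += absorb.edge.length
    return keep


def pruned_without(tree: BackboneTree, labels) -> BackboneTree:
    """New :class:`BackboneTree` with the given leaves pruned (edge numbers
    are reassigned on the pruned tree)."""
    dt = tree._tree.clone(depth=1)
    for label in labels:
        prune_leaf(dt, label)
    return BackboneTree(dt)
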