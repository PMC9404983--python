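"""Synthetic fixtures with the statistical structure the method assumes.

Random unrooted binary trees with exponential branch lengths, alignments
evolved site-independently under JC69, queries created by pruning leaves
(with the true attachment edge tracked through the pruning), fragmentary
queries created by masking everything outside a random contiguous window,
and a deliberately naive string-resampling oracle that the matrix
bootstrap formulation must match exactly.

No indels are simulated: fragmentation is produced by masking, which is
exactly the missing-data pattern the distance computation has to handle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np

from .msa import Alignment, decode, encode, residue_table, write_alignment
from .distances import jc69_expected_h
from .tree import BackboneTree, prune_leaf, write_tree
from .evaluation import write_truth_table

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationScenario:
    """Parameters of one synthetic study.

    ``n_leaves`` counts the full simulated tree; ``n_queries`` of those
    leaves are pruned out, so the backbone keeps ``n_leaves - n_queries``.
    ``branch_scale`` is the mean of the exponential branch-length
    distribution in substitutions/site.  With ``fragment_length`` set, each
    query keeps only a random contiguous window of that many residues.
    """

    n_leaves: int = 300
    L: int = 2000
    n_queries: int = 200
    branch_scale: float = 0.05
    fragment_length: Optional[int] = None
    seed: int = 42

    def __post_init__(self):
        if self.n_queries >= self.n_leaves - 3:
            raise ValueError("n_queries must be < n_leaves - 3")
        if self.fragment_length is not None and self.fragment_length > self.L:
            raise ValueError("fragment_length exceeds alignment length")


def simulate_tree(n_leaves: int, branch_scale: float = 0.05, seed: int = 0) -> BackboneTree:
    """Random unrooted binary tree (trifurcating root representation) with
    i.i.d. exponential branch lengths; 2*n_leaves - 3 edges."""
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_leaves):
        nd = dendropy.Node()
        nd.taxon = taxa.new_taxon(f"L{i:04d}")
        nodes.append(nd)
    # random sequential coalescent-style joins down to a final trifurcation
    while len(nodes) > 3:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.exponential(branch_scale))
        b.edge.length = float(rng.exponential(branch_scale))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
        nd.edge.length = float(rng.exponential(branch_scale))
    dtree = dendropy.Tree(taxon_namespace=taxa)
    dtree.seed_node = root
    return BackboneTree(dtree)


def evolve_jc69(tree: BackboneTree, L: int, seed: int = 0) -> Alignment:
    """Evolve an alignment down the tree under JC69.

    The root sequence is uniform over {A,C,G,T}; along each branch of
    length t every site changes independently with probability
    ``jc69_expected_h(t)``, drawing the new state uniformly from the three
    alternatives.
    """
    rng = np.random.default_rng(seed)
    dtree = tree._tree
    states = {id(dtree.seed_node): rng.integers(0, 4, size=L)}
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        parent_state = states[id(nd.parent_node)]
        p = jc69_expected_h(nd.edge.length)
        child = parent_state.copy()
        hit = rng.random(L) < p
        if hit.any():
            # uniform over the 3 non-current states
            child[hit] = (child[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        states[id(nd)] = child
    ids, rows = [], []
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            ids.append(nd.taxon.label)
            rows.append(_DNA[states[id(nd)]])
    return Alignment(ids, np.vstack(rows), "dna")


def make_queries(
    tree: BackboneTree,
    alignment: Alignment,
    n_queries: int,
    seed: int = 0,
):
    """Prune ``n_queries`` random leaves to form the backbone, recording
    each query's true attachment edge in the pruned tree.

    Returns ``(backbone_tree, backbone_alignment, query_alignment, truth)``
    with ``truth`` mapping query id -> edge number of the backbone edge the
    query leaf was attached to.  The true edge is found by restricting the
    original tree to backbone leaves plus the query, pruning the query (the
    two suppressed branches merge), and matching the merged edge's leaf
    bipartition against the backbone's numbered edges.
    """
    if n_queries >= tree.n_leaves - 3:
        raise ValueError("too many queries for this tree")
    rng = np.random.default_rng(seed)
    labels = list(tree.leaf_labels)
    query_ids = [labels[int(k)] for k in rng.choice(len(labels), size=n_queries, replace=False)]
    qset = set(query_ids)

    backbone_dt = tree._tree.clone(depth=1)
    for q in query_ids:
        prune_leaf(backbone_dt, q)
    backbone_tree = BackboneTree(backbone_dt)
    below = {
        backbone_tree.leafset_below(e): e for e in range(backbone_tree.n_edges)
    }
    all_leaves = frozenset(backbone_tree.leaf_labels)

    truth = {}
    for q in query_ids:
        dt = tree._tree.clone(depth=1)
        for other in query_ids:
            if other != q:
                prune_leaf(dt, other)
        tracked = prune_leaf(dt, q)
        ls = frozenset(lf.taxon.label for lf in tracked.leaf_iter())
        edge = below.get(ls, below.get(all_leaves - ls))
        if edge is None:
            raise RuntimeError(f"could not map attachment edge for query {q}")
        truth[q] = edge

    backbone_aln = alignment.subset([s for s in alignment.ids if s not in qset])
    query_aln = alignment.subset(query_ids)
    return backbone_tree, backbone_aln, query_aln, truth


def fragment(query_row, fragment_length: int, seed: int = 0):
    """Keep a random contiguous window of ``fragment_length`` non-gap
    characters and replace every other non-gap character with a gap;
    alignment coordinates are preserved."""
    is_str = isinstance(query_row, str)
    row = encode(query_row) if is_str else np.asarray(query_row, dtype=np.uint8).copy()
    nongap = np.flatnonzero(row != ord("-"))
    if fragment_length > nongap.size:
        raise ValueError(
            f"fragment length {fragment_length} exceeds {nongap.size} non-gap characters"
        )
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, nongap.size - fragment_length + 1))
    keep = np.zeros(row.size, dtype=bool)
    keep[nongap[start : start + fragment_length]] = True
    row[(row != ord("-")) & ~keep] = ord("-")
    return decode(row) if is_str else row


def fragment_alignment(aln: Alignment, fragment_length: int, seed: int = 0) -> Alignment:
    """Fragment every row with a per-row derived seed."""
    rng = np.random.default_rng(seed)
    rows = [
        fragment(aln.matrix[k], fragment_length, seed=int(rng.integers(2**31 - 1)))
        for k in range(aln.n_rows)
    ]
    return Alignment(list(aln.ids), np.vstack(rows), aln.alphabet)


def naive_bootstrap_oracle(backbone: Alignment, query_row, weight_row):
    """Reference implementation of one bootstrap replicate: materialize the
    resampled alignment by repeating each column ``weight_row[j]`` times,
    then count mismatches and mutually ungapped sites by direct character
    comparison.  Deliberately naive; the matrix formulation must match it
    exactly.
    """
    q = encode(query_row) if isinstance(query_row, str) else np.asarray(query_row, dtype=np.uint8)
    weight_row = np.asarray(weight_row)
    if weight_row.shape != (backbone.n_sites,):
        raise ValueError("weight row length does not match alignment")
    resampled_q = np.repeat(q, weight_row)
    residue = residue_table(backbone.alphabet)
    mismatches = np.zeros(backbone.n_rows, dtype=np.int64)
    valid = np.zeros(backbone.n_rows, dtype=np.int64)
    for k in range(backbone.n_rows):
        ref = np.repeat(backbone.matrix[k], weight_row)
        for a, b in zip(resampled_q.tolist(), ref.tolist()):
            if residue[a] and residue[b]:
                valid[k] += 1
                if a != b:
                    mismatches[k] += 1
    return mismatches, valid


@dataclass
class SyntheticStudy:
    """Everything one run of the generator produces."""

    scenario: SimulationScenario
    full_tree: BackboneTree
    backbone_tree: BackboneTree
    backbone_alignment: Alignment
    queries: Alignment
    truth: dict


def simulate_scenario(scenario: SimulationScenario) -> SyntheticStudy:
    """Tree -> alignment -> pruned queries (optionally fragmented)."""
    rng = np.random.default_rng(scenario.seed)
    s_tree, s_aln, s_prune, s_frag = rng.integers(2**31 - 1, size=4)
    full_tree = simulate_tree(scenario.n_leaves, scenario.branch_scale, seed=int(s_tree))
    aln = evolve_jc69(full_tree, scenario.L, seed=int(s_aln))
    backbone_tree, backbone_aln, queries, truth = make_queries(
        full_tree, aln, scenario.n_queries, seed=int(s_prune)
    )
    if scenario.fragment_length is not None:
        queries = fragment_alignment(queries, scenario.fragment_length, seed=int(s_frag))
    return SyntheticStudy(
        scenario=scenario,
        full_tree=full_tree,
        backbone_tree=backbone_tree,
        backbone_alignment=backbone_aln,
        queries=queries,
        truth=truth,
    )


def write_fixture(study: SyntheticStudy, outdir) -> None:
    """Emit FASTA + Newick + truth TSV (+ manifest) so every module is
    testable from files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tree(study.backbone_tree, outdir / "backbone.nwk")
    write_alignment(study.backbone_alignment, outdir / "backbone.fasta")
    write_alignment(study.queries, outdir / "queries.fasta")
    write_truth_table(study.truth, outdir / "truth.tsv")
    sc = study.scenario
    manifest = {
        "n_leaves": sc.n_leaves,
        "L": sc.L,
        "n_queries": sc.n_queries,
        "branch_scale": sc.branch_scale,
        "fragment_length": sc.fragment_length,
        "seed": sc.seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
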