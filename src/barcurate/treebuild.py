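"""Surrogate tree construction from distance matrices.

The delimitation stage needs a rooted tree with branch lengths (for PTP)
and an ultrametric chronogram (for GMYC).  When the user does not supply
externally inferred trees, a neighbor-joining tree and a UPGMA chronogram
built from the K2P matrix stand in.  The chronogram follows a strict
clock: pairwise divergence accumulates at ``clock_rate`` per million
years (default 0.012, i.e. 1.2% pairwise per My, 0.6% per lineage), so a
node joining two tips at K2P distance d sits at age d / clock_rate My.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from barcurate.distmat import DistMatrix
from barcurate.partition import Partition
from barcurate.seqio import ReferenceLibrary

__all__ = [
    "nj_tree",
    "upgma_chronogram",
    "dedupe_tips",
    "expand_partition",
    "midpoint_root",
    "is_ultrametric",
    "node_ages",
    "read_newick",
    "write_newick",
    "canonicalize",
]

DEFAULT_CLOCK_RATE = 0.012  # pairwise K2P divergence per My


def nj_tree(D: DistMatrix) -> dendropy.Tree:
    """Neighbor joining (Saitou-Nei Q criterion) on a distance matrix.

    Negative branch lengths are clamped to zero with the deficit moved to
    the adjacent (sister) branch, preserving the joined pair's distance.
    Ties in the Q matrix resolve to the smallest (row, col) index, so the
    result is deterministic.  The returned tree is unrooted (trifurcating
    seed node for >3 taxa is avoided by keeping the final join binary);
    use :func:`midpoint_root` before PTP.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 records")
    if not np.all(np.isfinite(D.values)):
        raise ValueError("NJ requires finite distances (saturated pairs present)")

    taxon_namespace = dendropy.TaxonNamespace(D.ids)
    nodes: List[dendropy.Node] = []
    for rid in D.ids:
        nd = dendropy.Node()
        nd.taxon = taxon_namespace.get_taxon(rid)
        nodes.append(nd)

    size = 2 * n  # room for internal nodes
    d = np.zeros((size, size), dtype=float)
    d[:n, :n] = D.values
    active = list(range(n))
    next_idx = n

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)

        u = dendropy.Node()
        u.add_child(nodes[i])
        nodes[i].edge.length = vi
        u.add_child(nodes[j])
        nodes[j].edge.length = vj
        nodes.append(u)

        for ak in active:
            if ak in (i, j):
                continue
            duk = 0.5 * (d[i, ak] + d[j, ak] - dij)
            d[next_idx, ak] = d[ak, next_idx] = max(duk, 0.0)
        active = [a for a in active if a not in (i, j)]
        active.append(next_idx)
        next_idx += 1

    a, b = active
    # Seed the tree at an internal node (at least one exists for n >= 3).
    if nodes[a].is_leaf():
        a, b = b, a
    seed = nodes[a]
    seed.add_child(nodes[b])
    nodes[b].edge.length = max(d[a, b], 0.0)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace, seed_node=seed)
    tree.is_rooted = False
    return tree


def upgma_chronogram(
    D: DistMatrix, clock_rate: float = DEFAULT_CLOCK_RATE
) -> dendropy.Tree:
    """UPGMA (average linkage) tree rendered as an ultrametric chronogram.

    Branch lengths are in My under the strict clock: a merge at average
    pairwise distance d becomes a node of age d / clock_rate.  Node ages
    are stored on ``node.age``.
    """
    n = len(D.ids)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 records")
    if not np.all(np.isfinite(D.values)):
        raise ValueError("UPGMA requires finite distances")
    if clock_rate <= 0:
        raise ValueError("clock_rate must be positive")

    taxon_namespace = dendropy.TaxonNamespace(D.ids)
    nodes: List[dendropy.Node] = []
    for rid in D.ids:
        nd = dendropy.Node()
        nd.taxon = taxon_namespace.get_taxon(rid)
        nd.age = 0.0
        nodes.append(nd)

    Z = linkage(squareform(D.values, checks=False), method="average")
    for row in Z:
        left, right, dist = int(row[0]), int(row[1]), float(row[2])
        u = dendropy.Node()
        u.age = dist / clock_rate
        for child in (nodes[left], nodes[right]):
            u.add_child(child)
            child.edge.length = max(u.age - child.age, 0.0)
        nodes.append(u)

    tree = dendropy.Tree(taxon_namespace=taxon_namespace, seed_node=nodes[-1])
    tree.is_rooted = True
    tree.annotations.add_new("branch_length_units", "My")
    return tree


def dedupe_tips(
    library: ReferenceLibrary, D: Optional[DistMatrix] = None
) -> Tuple[List[str], Dict[str, str]]:
    """Collapse identical sequences to one representative each.

    Returns the representative ids (input order; first member of each
    identical-sequence class) and the expansion map id -> representative,
    covering every QC-passing record.  ``D`` is accepted for interface
    symmetry but identity is decided on the sequences themselves.
    """
    reps: List[str] = []
    by_seq: Dict[str, str] = {}
    expansion: Dict[str, str] = {}
    for rec in library.qc_passing():
        rep = by_seq.get(rec.sequence)
        if rep is None:
            by_seq[rec.sequence] = rec.record_id
            reps.append(rec.record_id)
            rep = rec.record_id
        expansion[rec.record_id] = rep
    return reps, expansion


def expand_partition(partition: Partition, expansion_map: Dict[str, str]) -> Partition:
    """Reapply a partition over representatives to all duplicate records."""
    out = {rid: partition.assignments[rep] for rid, rep in expansion_map.items()}
    return Partition(out, method=partition.method, score=partition.score)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-root a (copy of a) tree; returns the rooted copy."""
    t = tree.clone(depth=1)
    t.reroot_at_midpoint(update_bipartitions=False)
    t.is_rooted = True
    return t


def node_ages(tree: dendropy.Tree) -> Dict[dendropy.Node, float]:
    """Node ages (max distance to a descendant tip), computed bottom-up."""
    ages: Dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            ages[node] = max(
                ages[c] + (c.edge.length or 0.0) for c in node.child_nodes()
            )
    return ages


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-9) -> bool:
    """All root-to-tip path lengths equal within relative tolerance."""
    depths = []
    for leaf in tree.leaf_node_iter():
        depth = 0.0
        node = leaf
        while node.parent_node is not None:
            depth += node.edge.length or 0.0
            node = node.parent_node
        depths.append(depth)
    top = max(depths)
    if top == 0:
        return True
    return (top - min(depths)) / top <= rel_tol


def _min_tip_label(node: dendropy.Node) -> str:
    return min(
        leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon is not None
    )


def canonicalize(tree: dendropy.Tree) -> dendropy.Tree:
    """Sort children by smallest descendant tip label (stable newick)."""
    for node in tree.postorder_internal_node_iter():
        node._child_nodes.sort(key=_min_tip_label)
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    canonicalize(tree)
    s = tree.as_string(schema="newick", suppress_rooting=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def read_newick(source: str, is_path: bool = True) -> dendropy.Tree:
    if is_path:
        return dendropy.Tree.get(path=str(source), schema="newick")
    return dendropy.Tree.get(data=source, schema="newick")
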