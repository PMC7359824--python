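"""Consensus over partitions and partition comparison (ARI, diff lists)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import adjusted_rand_score

from barcurate.partition import Partition, relabel_canonical

__all__ = ["consensus_partition", "compare_partitions", "PartitionDiff"]


def consensus_partition(
    partitions: Sequence[Partition], min_agree: int = 2
) -> Partition:
    """Co-membership consensus: records are joined when at least
    ``min_agree`` input partitions place them in the same OTU; consensus
    OTUs are the connected components of that graph (so agreement is
    transitive)."""
    if len(partitions) < 2:
        raise ValueError("consensus needs at least 2 partitions")
    ids = list(partitions[0].assignments)
    idset = set(ids)
    for p in partitions[1:]:
        if set(p.assignments) != idset:
            raise ValueError("all partitions must cover the same id set")
    n = len(ids)
    votes = np.zeros((n, n), dtype=np.int32)
    for p in partitions:
        labels = np.array([p.assignments[i] for i in ids])
        votes += (labels[:, None] == labels[None, :]).astype(np.int32)
    adj = csr_matrix(votes >= min_agree)
    _, comp = connected_components(adj, directed=False)
    out = Partition(
        {rid: f"C{c}" for rid, c in zip(ids, comp)}, method="consensus"
    )
    return relabel_canonical(out)


@dataclass
class PartitionDiff:
    """Bookkeeping of how partition P2 reorganises P1's OTUs.

    ``matched`` maps each P1 OTU to the P2 OTU holding most of its
    members.  ``new_otus`` are P2 OTUs without any P1 member (e.g. OTUs
    made entirely of pooled queries).  ``merged`` lists P2 OTUs drawing
    shared members from several P1 OTUs; ``split`` lists P1 OTUs whose
    members scatter over several P2 OTUs.
    """

    matched: Dict[str, str]
    new_otus: List[str]
    merged: List[Tuple[str, Tuple[str, ...]]]
    split: List[Tuple[str, Tuple[str, ...]]]
    adjusted_rand_index: float

    @property
    def n_new_otus(self) -> int:
        return len(self.new_otus)


def compare_partitions(P1: Partition, P2: Partition) -> PartitionDiff:
    """Diff two partitions; P2's id set must contain P1's.

    OTU matching uses maximum overlap on the shared ids, ties broken by
    the smallest P2 OTU id; the adjusted Rand index is computed on the
    shared ids only.
    """
    shared = [i for i in P1.assignments if i in P2.assignments]
    if len(shared) != len(P1.assignments):
        raise ValueError("P2 must cover every id of P1")

    l1 = [P1.assignments[i] for i in shared]
    l2 = [P2.assignments[i] for i in shared]
    ari = float(adjusted_rand_score(l1, l2))

    # contingency on shared ids
    cross: Dict[str, Dict[str, int]] = {}
    for a, b in zip(l1, l2):
        cross.setdefault(a, {}).setdefault(b, 0)
        cross[a][b] += 1

    matched = {
        a: min((b for b in row if row[b] == max(row.values())))
        for a, row in cross.items()
    }

    p2_sources: Dict[str, set] = {}
    for a, row in cross.items():
        for b in row:
            p2_sources.setdefault(b, set()).add(a)

    new_otus = sorted(
        otu for otu in set(P2.assignments.values()) if otu not in p2_sources
    )
    merged = sorted(
        (b, tuple(sorted(srcs))) for b, srcs in p2_sources.items() if len(srcs) > 1
    )
    split = sorted(
        (a, tuple(sorted(row))) for a, row in cross.items() if len(row) > 1
    )
    return PartitionDiff(
        matched=matched,
        new_otus=new_otus,
        merged=merged,
        split=split,
        adjusted_rand_index=ari,
    )
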