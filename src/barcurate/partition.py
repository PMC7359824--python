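"""Partitions of records into OTUs: the common currency of delimitation.

A :class:`Partition` maps every record id to exactly one OTU label.  OTU
labels are opaque; two partitions are equivalent when they induce the
same grouping, regardless of label spelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

__all__ = ["Partition", "relabel_canonical"]


@dataclass
class Partition:
    """Total assignment of record ids to OTU ids.

    Parameters
    ----------
    assignments
        Mapping record id -> OTU id.  Every id of the underlying data set
        must appear exactly once.
    method
        Name of the delimitation method that produced the partition.
    score
        Optional log-likelihood (PTP / GMYC) of the partition.
    """

    assignments: Dict[str, str]
    method: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("a partition must cover at least one record")

    @property
    def ids(self) -> List[str]:
        return list(self.assignments)

    def n_otus(self) -> int:
        return len(set(self.assignments.values()))

    def otus(self) -> Dict[str, List[str]]:
        """OTU id -> member record ids (insertion order preserved)."""
        groups: Dict[str, List[str]] = {}
        for rid, otu in self.assignments.items():
            groups.setdefault(otu, []).append(rid)
        return groups

    def restrict(self, ids: Iterable[str]) -> "Partition":
        """Sub-partition over ``ids`` (all must be covered)."""
        sub = {}
        for rid in ids:
            if rid not in self.assignments:
                raise KeyError(f"record {rid!r} not covered by partition")
            sub[rid] = self.assignments[rid]
        return Partition(sub, method=self.method, score=None)

    def same_otu(self, a: str, b: str) -> bool:
        return self.assignments[a] == self.assignments[b]

    def equivalent(self, other: "Partition") -> bool:
        """Equality up to OTU relabeling, over identical id sets."""
        if set(self.assignments) != set(other.assignments):
            return False
        fwd: Dict[str, str] = {}
        rev: Dict[str, str] = {}
        for rid, otu in self.assignments.items():
            o2 = other.assignments[rid]
            if fwd.setdefault(otu, o2) != o2:
                return False
            if rev.setdefault(o2, otu) != otu:
                return False
        return True


def relabel_canonical(partition: Partition, prefix: str = "OTU") -> Partition:
    """Relabel OTUs deterministically as ``prefix_0001`` ... in order of
    first appearance of each OTU among the (insertion-ordered) record ids."""
    mapping: Dict[str, str] = {}
    out: Dict[str, str] = {}
    for rid, otu in partition.assignments.items():
        if otu not in mapping:
            mapping[otu] = f"{prefix}_{len(mapping) + 1:04d}"
        out[rid] = mapping[otu]
    return Partition(out, method=partition.method, score=partition.score)
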