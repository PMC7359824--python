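"""Poisson tree process delimitation on a rooted tree with branch lengths.

The tree's edges are classed as between-species or within-species by a
set of "cut" nodes whose subtrees are the species.  Branch lengths in a
class are modelled as exponential; in single-rate mode one rate serves
all within-species edges, in multi-rate mode every species subtree gets
its own rate.  The cut set is searched by greedy hill climbing from the
one-species start, with seeded random restarts to escape local optima.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, FrozenSet, List, Optional, Tuple

import dendropy
import numpy as np

from barcurate.partition import Partition, relabel_canonical

logger = logging.getLogger(__name__)

__all__ = ["ptp_partition"]

_MIN_BL = 1e-8  # floor applied to branch lengths in the likelihood
_ZERO_BL = 1e-9  # below this an edge counts as zero-length


def _exp_loglik(n: int, total: float) -> float:
    """Max log-likelihood of n exponential observations summing to total."""
    if n == 0:
        return 0.0
    return n * math.log(n / total) - n


class _PtpModel:
    def __init__(self, tree: dendropy.Tree, mode: str):
        self.mode = mode
        self.root = tree.seed_node
        self.children: Dict[int, List[int]] = {}
        self.node_of: Dict[int, dendropy.Node] = {}
        self.sub_sum: Dict[int, float] = {}
        self.sub_cnt: Dict[int, int] = {}
        self.edge_len: Dict[int, float] = {}
        self.parent: Dict[int, Optional[int]] = {}
        self.tips: Dict[int, List[str]] = {}
        for node in tree.postorder_node_iter():
            nid = id(node)
            self.node_of[nid] = node
            kids = [id(c) for c in node.child_nodes()]
            self.children[nid] = kids
            if node is not self.root:
                self.edge_len[nid] = max(node.edge.length or 0.0, _MIN_BL)
            if node.is_leaf():
                self.sub_sum[nid] = 0.0
                self.sub_cnt[nid] = 0
                self.tips[nid] = [node.taxon.label]
            else:
                self.sub_sum[nid] = sum(
                    self.edge_len[c] + self.sub_sum[c] for c in kids
                )
                self.sub_cnt[nid] = sum(1 + self.sub_cnt[c] for c in kids)
                self.tips[nid] = [t for c in kids for t in self.tips[c]]
        for node in tree.preorder_node_iter():
            for c in node.child_nodes():
                self.parent[id(c)] = id(node)
        self.parent[id(self.root)] = None
        self.total_sum = self.sub_sum[id(self.root)]
        self.total_cnt = self.sub_cnt[id(self.root)]

    def loglik(self, cuts: FrozenSet[int]) -> float:
        sum_w = sum(self.sub_sum[s] for s in cuts)
        cnt_w = sum(self.sub_cnt[s] for s in cuts)
        between = _exp_loglik(self.total_cnt - cnt_w, self.total_sum - sum_w)
        if self.mode == "single":
            return between + _exp_loglik(cnt_w, sum_w)
        return between + sum(
            _exp_loglik(self.sub_cnt[s], self.sub_sum[s]) for s in cuts
        )

    def neighbors(self, cuts: FrozenSet[int]) -> List[FrozenSet[int]]:
        out = []
        for s in cuts:
            kids = self.children[s]
            if kids:  # split a species at its root
                out.append(cuts - {s} | frozenset(kids))
        parents = {self.parent[s] for s in cuts if self.parent[s] is not None}
        for p in parents:  # merge sibling species
            kids = frozenset(self.children[p])
            if kids and kids <= cuts:
                out.append(cuts - kids | {p})
        return out

    def partition(self, cuts: FrozenSet[int]) -> Partition:
        assign = {}
        for i, s in enumerate(sorted(cuts, key=lambda s: min(self.tips[s]))):
            for t in self.tips[s]:
                assign[t] = f"P{i}"
        return Partition(assign, method="PTP")


def _hill_climb(
    model: _PtpModel,
    start: FrozenSet[int],
    rng: Optional[np.random.Generator],
) -> Tuple[FrozenSet[int], float]:
    cuts = start
    score = model.loglik(cuts)
    while True:
        nbrs = model.neighbors(cuts)
        scored = [(model.loglik(nb), nb) for nb in nbrs]
        improving = [(sc, nb) for sc, nb in scored if sc > score + 1e-9]
        if not improving:
            return cuts, score
        if rng is None:  # steepest ascent
            score, cuts = max(improving, key=lambda t: t[0])
        else:  # seeded random improving move
            k = int(rng.integers(len(improving)))
            score, cuts = improving[k]


def ptp_partition(
    tree: dendropy.Tree,
    mode: str = "multi",
    seed: int = 1,
    restarts: int = 10,
) -> Partition:
    """Delimit species on a rooted tree; returns a Partition whose
    ``score`` is the log-likelihood of the reported cut set.

    A tree dominated by (near-)zero branch lengths carries no rate signal;
    it yields the null one-species partition with a warning.
    """
    if mode not in ("single", "multi"):
        raise ValueError(f"unknown PTP mode {mode!r}")
    tips = [l for l in tree.leaf_node_iter()]
    if len(tips) < 4:
        raise ValueError("PTP needs at least 4 tips")
    model = _PtpModel(tree, mode)

    lengths = list(model.edge_len.values())
    if sum(1 for x in lengths if x <= _ZERO_BL) > 0.8 * len(lengths):
        logger.warning("tree dominated by zero-length branches; returning 1 OTU")
        null = frozenset({id(model.root)})
        part = model.partition(null)
        part.score = model.loglik(null)
        return relabel_canonical_keep_score(part)

    # climb from both extreme states: all-one-species (splitting down) and
    # all-singletons (merging up); random restarts alternate between them
    starts = [
        frozenset({id(model.root)}),
        frozenset(id(l) for l in tree.leaf_node_iter()),
    ]
    best_cuts, best_score = None, -math.inf
    for st in starts:
        cuts, score = _hill_climb(model, st, rng=None)
        if score > best_score:
            best_cuts, best_score = cuts, score
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        cuts, score = _hill_climb(model, starts[r % 2], rng)
        if score > best_score:
            best_cuts, best_score = cuts, score

    part = model.partition(best_cuts)
    part.score = best_score
    return relabel_canonical_keep_score(part)


def relabel_canonical_keep_score(part: Partition) -> Partition:
    out = relabel_canonical(part)
    out.score = part.score
    return out
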