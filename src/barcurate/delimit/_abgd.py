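"""Automatic barcode-gap discovery over a grid of prior divergence limits.

For each prior intraspecific limit p on a geometric grid, the ranked
pairwise distances are scanned for the first significant gap ending above
p: a gap qualifies when its width exceeds ``gap_width_x`` times a local
slope estimate (the mean of the neighboring inter-distance gaps).  Records
are then clustered by connectivity at the gap's lower edge, and the scan
recurses inside each group until no further significant gap is found.

The partition reported for the whole grid is chosen among the
*self-consistent* priors: the prior is by definition the assumed maximum
intraspecific divergence, so a partition whose realized maximum
within-group distance exceeds its own prior contradicts the assumption
that produced it (this is what happens at very small priors, which split
on intraspecific noise and would otherwise dominate the grid).  Among
self-consistent priors the modal group count marks the stable plateau,
and the partition at the largest such prior is selected.  If no prior is
self-consistent the plain modal rule over the whole grid applies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from barcurate.distmat import DistMatrix
from barcurate.partition import Partition, relabel_canonical

__all__ = ["abgd_partition", "AbgdResult"]

_SLOPE_WINDOW = 10  # gaps on each side used for the local slope estimate


def _first_significant_gap(
    dists: np.ndarray, prior_p: float, gap_width_x: float
) -> Optional[float]:
    """Lower edge of the first significant gap ending above ``prior_p``,
    or None.  ``dists`` must be sorted ascending."""
    if dists.size < 2:
        return None
    gaps = np.diff(dists)
    for i, g in enumerate(gaps):
        if g <= 0 or dists[i + 1] <= prior_p:
            continue
        lo = max(0, i - _SLOPE_WINDOW)
        neighborhood = np.concatenate(
            (gaps[lo:i], gaps[i + 1 : i + 1 + _SLOPE_WINDOW])
        )
        slope = float(neighborhood.mean()) if neighborhood.size else 0.0
        if g > gap_width_x * slope:
            return float(dists[i])
    return None


def _components_at(values: np.ndarray, threshold: float) -> np.ndarray:
    adj = csr_matrix(values <= threshold)
    _, comp = connected_components(adj, directed=False)
    return comp


def _split_once(
    values: np.ndarray, idx: List[int], prior_p: float, gap_width_x: float
) -> List[List[int]]:
    """One gap-detection pass over the records in ``idx``; returns the
    resulting groups (possibly just [idx])."""
    if len(idx) < 2:
        return [idx]
    sub = values[np.ix_(idx, idx)]
    tri = sub[np.triu_indices(len(idx), k=1)]
    tri = np.sort(tri[np.isfinite(tri)])
    thr = _first_significant_gap(tri, prior_p, gap_width_x)
    if thr is None:
        return [idx]
    comp = _components_at(sub, thr)
    if comp.max() == 0:
        return [idx]
    return [
        [idx[i] for i in range(len(idx)) if comp[i] == c]
        for c in range(comp.max() + 1)
    ]


def _recursive_groups(
    values: np.ndarray, idx: List[int], prior_p: float, gap_width_x: float
) -> List[List[int]]:
    groups = _split_once(values, idx, prior_p, gap_width_x)
    if len(groups) == 1:
        return groups
    out: List[List[int]] = []
    for g in groups:
        out.extend(_recursive_groups(values, g, prior_p, gap_width_x))
    return out


def _to_partition(ids: List[str], groups: List[List[int]], method: str) -> Partition:
    assign: Dict[str, str] = {}
    for gi, g in enumerate(groups):
        for i in g:
            assign[ids[i]] = f"G{gi}"
    ordered = {rid: assign[rid] for rid in ids}
    return relabel_canonical(Partition(ordered, method=method))


@dataclass
class AbgdResult:
    priors: List[float]
    initial: List[Partition]  # one-pass partition per prior
    recursive: List[Partition]  # fully recursed partition per prior
    selected: Partition

    @property
    def by_prior(self) -> List[Tuple[float, Partition]]:
        return list(zip(self.priors, self.recursive))


def abgd_partition(
    D: DistMatrix,
    p_min: float = 0.001,
    p_max: float = 0.1,
    steps: int = 10,
    gap_width_x: float = 1.5,
) -> AbgdResult:
    """Run the gap-discovery scan across the prior grid and select the
    modal-count partition (largest qualifying prior)."""
    n = len(D.ids)
    if n < 2:
        raise ValueError("ABGD needs at least 2 records")
    if not (0 < p_min < p_max):
        raise ValueError("need 0 < p_min < p_max")
    priors = list(np.geomspace(p_min, p_max, steps))
    idx = list(range(n))
    initial, recursive = [], []
    for p in priors:
        initial.append(
            _to_partition(D.ids, _split_once(D.values, idx, p, gap_width_x), "ABGD")
        )
        recursive.append(
            _to_partition(
                D.ids, _recursive_groups(D.values, idx, p, gap_width_x), "ABGD"
            )
        )
    counts = [part.n_otus() for part in recursive]
    consistent = [
        i
        for i, part in enumerate(recursive)
        if _max_intra(D, part) <= priors[i] + 1e-12
    ]
    pool = consistent if consistent else list(range(len(recursive)))
    # candidate counts must be realized at a self-consistent prior, but the
    # stability of a count is judged over the whole grid (the plateau width)
    grid_freq = Counter(counts)
    cand_counts = {counts[i] for i in pool}
    top = max(grid_freq[c] for c in cand_counts)
    candidates = {c for c in cand_counts if grid_freq[c] == top}
    sel_i = max(i for i in pool if counts[i] in candidates)
    return AbgdResult(
        priors=priors, initial=initial, recursive=recursive, selected=recursive[sel_i]
    )


def _max_intra(D: DistMatrix, part: Partition) -> float:
    """Largest realized within-group distance of a partition."""
    idx = {rid: i for i, rid in enumerate(D.ids)}
    worst = 0.0
    for members in part.otus().values():
        if len(members) < 2:
            continue
        ii = [idx[m] for m in members]
        sub = D.values[np.ix_(ii, ii)]
        finite = sub[np.isfinite(sub)]
        if finite.size:
            worst = max(worst, float(finite.max()))
    return worst
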