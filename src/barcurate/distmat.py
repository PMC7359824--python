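"""Kimura two-parameter distances and barcode-gap statistics.

The K2P model corrects observed divergence for multiple hits while
distinguishing transitions (A<->G, C<->T, proportion P) from
transversions (proportion Q):

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence carries a gap or an ambiguity code are
excluded pair by pair.  Saturated pairs (non-positive log argument) get
an infinite sentinel distance and are excluded from median statistics.

The barcode gap of an OTU is the excess of its nearest-neighbor distance
(smallest distance from any of its members to any member of another OTU)
over its maximum intraspecific distance.  The gap table summarises both
per OTU and globally via medians and their fold ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from barcurate.partition import Partition
from barcurate.seqio import ReferenceLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "DistMatrix",
    "GapTable",
    "k2p_distance",
    "pairwise_matrix",
    "gap_table",
    "fold_ratio",
]

# A,G are purines (even codes); C,T pyrimidines (odd codes).  A mismatch
# with equal parity is a transition, unequal parity a transversion.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("AGCT"):
    _CODE[ord(_b)] = (0, 2, 1, 3)[_i]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class DistMatrix:
    """Symmetric K2P distance matrix over record ids."""

    ids: List[str]
    values: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match ids")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, ids: List[str]) -> "DistMatrix":
        idx = [self._index[i] for i in ids]
        return DistMatrix(
            ids=list(ids),
            values=self.values[np.ix_(idx, idx)].copy(),
            comparable_sites=self.comparable_sites[np.ix_(idx, idx)].copy(),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, rid in enumerate(self.ids):
                row = " ".join(f"{v:.8f}" for v in self.values[i])
                fh.write(f"{rid}  {row}\n")


def k2p_distance(seq_a: str, seq_b: str) -> Tuple[float, float, float, int]:
    """K2P distance between two aligned sequences.

    Returns ``(d, P, Q, n_sites)`` where P and Q are the transition and
    transversion proportions over the pairwise-comparable sites.  A
    saturated pair yields ``d = inf``.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = _encode(seq_a.upper())
    b = _encode(seq_b.upper())
    ok = (a != 255) & (b != 255)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable sites between the two sequences")
    aa, bb = a[ok], b[ok]
    diff = aa != bb
    ts = int((diff & ((aa & 1) == (bb & 1))).sum())
    tv = int(diff.sum()) - ts
    P = ts / n
    Q = tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return math.inf, P, Q, n
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return d, P, Q, n


def pairwise_matrix(library: ReferenceLibrary) -> DistMatrix:
    """Full symmetric K2P matrix over the QC-passing records."""
    recs = library.qc_passing()
    if len(recs) < 2:
        raise ValueError("need at least 2 QC-passing records")
    ids = [r.record_id for r in recs]
    enc = [_encode(r.sequence) for r in recs]
    n = len(recs)
    values = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=int)
    n_saturated = 0
    for i in range(n):
        sites[i, i] = int((enc[i] != 255).sum())
        for j in range(i + 1, n):
            a, b = enc[i], enc[j]
            ok = (a != 255) & (b != 255)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            aa, bb = a[ok], b[ok]
            diff = aa != bb
            ts = int((diff & ((aa & 1) == (bb & 1))).sum())
            tv = int(diff.sum()) - ts
            P, Q = ts / m, tv / m
            w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
            if w1 <= 0 or w2 <= 0:
                d = math.inf
                n_saturated += 1
            else:
                d = -0.5 * math.log(w1 * math.sqrt(w2))
            values[i, j] = values[j, i] = d
            sites[i, j] = sites[j, i] = m
    if n_saturated:
        logger.warning("%d saturated pairs reported as inf", n_saturated)
    return DistMatrix(ids=ids, values=values, comparable_sites=sites)


@dataclass
class GapTable:
    """Per-OTU barcode-gap rows plus global median summary."""

    per_otu: pd.DataFrame  # otu_id, max_intraspecific, nn_otu, nn_distance, has_gap
    median_max_intra: float
    median_nn: float
    fold_ratio: Optional[float]
    single_otu: bool = False

    def to_tsv(self, path) -> None:
        self.per_otu.to_csv(path, sep="\t", index=False)


def fold_ratio(median_nn: float, median_max_intra: float) -> Optional[float]:
    """median nearest-neighbor / median max-intraspecific distance."""
    if median_max_intra <= 0:
        return None
    return median_nn / median_max_intra


def gap_table(D: DistMatrix, partition: Partition) -> GapTable:
    """Barcode-gap statistics for every OTU of ``partition``.

    Singleton OTUs have ``max_intraspecific = 0``.  The nearest-neighbor
    distance is the smallest distance from any member to any member of
    another OTU; ties between OTUs are broken by the lexicographically
    smallest neighbor id.  Infinite (saturated) distances are excluded
    from the medians.
    """
    missing = set(D.ids) - set(partition.assignments)
    if missing:
        raise ValueError(f"partition does not cover matrix ids: {sorted(missing)[:3]}")
    groups = partition.restrict(D.ids).otus()
    otu_ids = sorted(groups)
    single = len(otu_ids) == 1
    idx = {rid: i for i, rid in enumerate(D.ids)}

    rows = []
    for otu in otu_ids:
        members = [idx[r] for r in groups[otu]]
        if len(members) > 1:
            sub = D.values[np.ix_(members, members)]
            finite = sub[np.isfinite(sub)]
            max_intra = float(finite.max()) if finite.size else math.inf
        else:
            max_intra = 0.0
        nn_otu, nn_dist = None, math.nan
        if not single:
            best = (math.inf, None)
            for other in otu_ids:
                if other == otu:
                    continue
                omem = [idx[r] for r in groups[other]]
                d = float(D.values[np.ix_(members, omem)].min())
                if d < best[0] or (d == best[0] and best[1] is not None and other < best[1]):
                    best = (d, other)
            nn_dist, nn_otu = best
        rows.append(
            {
                "otu_id": otu,
                "max_intraspecific": max_intra,
                "nn_otu": nn_otu,
                "nn_distance": nn_dist,
                "has_gap": (nn_dist > max_intra) if not single else None,
            }
        )
    df = pd.DataFrame(rows)
    intra = df["max_intraspecific"].to_numpy(dtype=float)
    intra = intra[np.isfinite(intra)]
    med_intra = float(np.median(intra)) if intra.size else math.nan
    if single:
        med_nn = math.nan
        fr = None
    else:
        nn = df["nn_distance"].to_numpy(dtype=float)
        nn = nn[np.isfinite(nn)]
        med_nn = float(np.median(nn)) if nn.size else math.nan
        fr = fold_ratio(med_nn, med_intra)
    return GapTable(
        per_otu=df,
        median_max_intra=med_intra,
        median_nn=med_nn,
        fold_ratio=fr,
        single_otu=single,
    )
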