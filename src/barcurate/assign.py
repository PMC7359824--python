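"""Specimen assignment to reference OTUs with per-method probabilities.

Three methods mirror common barcode-identification practice:

* **FZ** — nearest reference representative by K2P distance; the
  probability is a Z-shaped fuzzy membership function (FMF) of the
  distance x, anchored at a = the selected OTU's intraspecific
  variability (theta1) and b = its distance to the nearest other OTU
  (theta2): 1 for x <= a, 0 for x >= b, quadratic shoulders meeting at
  0.5 in the middle.
* **FZKMER** — alignment-free: nearest representative in normalized
  k-mer frequency space, k chosen as the smallest value (up to k_max)
  maximizing leave-one-out self-assignment accuracy on the full
  reference library; the FMF anchors are the 95th percentile of
  intra-OTU and the 5th percentile of inter-OTU k-mer distances.
* **BP** — a one-hidden-layer backpropagation network (logistic hidden
  units, softmax output) on k-mer features, trained on all library
  members of each OTU; the probability is the winning softmax output.

A consensus verdict requires at least two methods to agree; the ratio
diagnostic (distance to the selected OTU over distance to the nearest
other OTU) flags candidate false positives when it exceeds 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from barcurate.distmat import k2p_distance, pairwise_matrix, gap_table
from barcurate.partition import Partition
from barcurate.seqio import BarcodeRecord, ReferenceLibrary

__all__ = [
    "AssignmentReference",
    "MethodEntry",
    "AssignmentOutcome",
    "build_reference",
    "fuzzy_membership",
    "assign_fz",
    "assign_fzkmer",
    "assign_bp",
    "consensus_assignment",
    "ratio_diagnostic",
    "assign_all",
]

_THETA1_DEFAULT = 0.005


@dataclass
class MethodEntry:
    """One method's verdict for one query."""

    selected_otu: str
    probability: float
    dist_to_selected: float
    nn_otu: Optional[str]
    dist_to_nn: float
    ratio: float
    note: str = ""


@dataclass
class AssignmentOutcome:
    query_id: str
    entries: Dict[str, MethodEntry]
    consensus_otu: str
    consensus_level: str  # "3/3", "2/3" or "none"
    mean_probability: float


@dataclass
class AssignmentReference:
    """One representative per OTU plus the FMF anchors theta1/theta2.

    theta1 and theta2 come from the *full* library distances, computed
    before the reduction to representatives.
    """

    representatives: Dict[str, BarcodeRecord]
    theta1: Dict[str, float]
    theta2: Dict[str, float]
    seed: int
    library: ReferenceLibrary
    partition: Partition
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def otu_ids(self) -> List[str]:
        return sorted(self.representatives)

    def k2p_to_representatives(self, query: BarcodeRecord) -> Dict[str, float]:
        return {
            otu: k2p_distance(query.sequence, rep.sequence)[0]
            for otu, rep in self.representatives.items()
        }


def build_reference(
    library: ReferenceLibrary, partition: Partition, seed: int = 1
) -> AssignmentReference:
    """Draw one representative per OTU (uniformly, seeded) and compute the
    per-OTU FMF anchors from the full library's K2P distances.

    Singleton OTUs take the global median of the multi-member OTUs'
    maximum intraspecific distances as theta1 (0.005 if there is none).
    """
    recs = {r.record_id: r for r in library.qc_passing()}
    part = partition.restrict(recs.keys())
    groups = part.otus()

    D = pairwise_matrix(library)
    gt = gap_table(D, part)
    by_otu = gt.per_otu.set_index("otu_id")

    multi = [
        float(by_otu.loc[o, "max_intraspecific"])
        for o, members in groups.items()
        if len(members) > 1
        and math.isfinite(float(by_otu.loc[o, "max_intraspecific"]))
    ]
    fallback = float(np.median(multi)) if multi else _THETA1_DEFAULT

    rng = np.random.default_rng(seed)
    representatives, theta1, theta2 = {}, {}, {}
    for otu in sorted(groups):
        members = sorted(groups[otu])
        representatives[otu] = recs[members[int(rng.integers(len(members)))]]
        t1 = float(by_otu.loc[otu, "max_intraspecific"])
        theta1[otu] = t1 if (len(members) > 1 and math.isfinite(t1)) else fallback
        nn = by_otu.loc[otu, "nn_distance"]
        theta2[otu] = float(nn) if not gt.single_otu else math.inf
    return AssignmentReference(
        representatives=representatives,
        theta1=theta1,
        theta2=theta2,
        seed=seed,
        library=library,
        partition=part,
    )


def fuzzy_membership(x: float, a: float, b: float) -> float:
    """Z-shaped FMF: 1 for x <= a, 0 for x >= b, quadratic shoulders with
    value 0.5 at the midpoint.  Degenerate b <= a collapses to a step at a."""
    if b <= a:
        return 1.0 if x <= a else 0.0
    if x <= a:
        return 1.0
    if x >= b:
        return 0.0
    if x <= (a + b) / 2:
        return 1.0 - 2.0 * ((x - a) / (b - a)) ** 2
    return 2.0 * ((x - b) / (b - a)) ** 2


def _nearest(dists: Dict[str, float]) -> str:
    """OTU at minimum distance, ties to the lexicographically smallest id."""
    best = min(dists.values())
    return min(o for o, d in dists.items() if d == best)


def _ratio(dists: Dict[str, float], selected: str) -> Tuple[Optional[str], float, float]:
    """(nearest other OTU, its distance, d_selected / d_nearest_other)."""
    others = {o: d for o, d in dists.items() if o != selected}
    if not others:
        return None, math.nan, math.nan
    nn = _nearest(others)
    d_nn = others[nn]
    d_sel = dists[selected]
    if d_nn == 0:
        ratio = 1.0 if d_sel == 0 else math.inf
    else:
        ratio = d_sel / d_nn
    return nn, d_nn, ratio


def assign_fz(query: BarcodeRecord, ref: AssignmentReference) -> MethodEntry:
    """Fuzzy-set nearest-neighbor assignment on K2P distances (K = 1)."""
    dists = ref.k2p_to_representatives(query)
    selected = _nearest(dists)
    x = dists[selected]
    prob = fuzzy_membership(x, ref.theta1[selected], ref.theta2[selected])
    nn, d_nn, ratio = _ratio(dists, selected)
    return MethodEntry(
        selected_otu=selected,
        probability=prob,
        dist_to_selected=x,
        nn_otu=nn,
        dist_to_nn=d_nn,
        ratio=ratio,
        note="uninformative" if nn is None else "",
    )


# --- k-mer machinery --------------------------------------------------------

_BASE_IDX = {c: i for i, c in enumerate("ACGT")}


def kmer_vector(sequence: str, k: int) -> np.ndarray:
    """Normalized frequency vector over the 4**k ACGT k-mers; windows
    containing gaps or ambiguity codes are skipped."""
    counts = np.zeros(4**k, dtype=float)
    seq = sequence.upper()
    code = [_BASE_IDX.get(c, -1) for c in seq]
    total = 0
    for i in range(len(seq) - k + 1):
        idx = 0
        ok = True
        for j in range(k):
            c = code[i + j]
            if c < 0:
                ok = False
                break
            idx = idx * 4 + c
        if ok:
            counts[idx] += 1
            total += 1
    if total == 0:
        raise ValueError("sequence has no unambiguous k-mers")
    return counts / total


def _library_kmer_state(ref: AssignmentReference, k_max: int):
    """LOO-selected k plus FMF anchors and representative vectors, cached."""
    key = ("kmer_state", k_max)
    if key in ref._cache:
        return ref._cache[key]
    recs = list(ref.library.qc_passing())
    labels = [ref.partition.assignments[r.record_id] for r in recs]
    best = None  # (accuracy, -k) maximized -> smallest k at max accuracy
    best_k, best_vecs = None, None
    for k in range(1, k_max + 1):
        vecs = np.array([kmer_vector(r.sequence, k) for r in recs])
        dist = np.sqrt(
            np.maximum(
                (vecs**2).sum(1)[:, None]
                + (vecs**2).sum(1)[None, :]
                - 2 * vecs @ vecs.T,
                0.0,
            )
        )
        np.fill_diagonal(dist, np.inf)
        nn = dist.argmin(axis=1)
        acc = float(np.mean([labels[i] == labels[j] for i, j in enumerate(nn)]))
        if best is None or (acc, -k) > best:
            best = (acc, -k)
            best_k, best_vecs = k, (vecs, dist)
    vecs, dist = best_vecs
    lab = np.array(labels)
    same = lab[:, None] == lab[None, :]
    iu = np.triu_indices(len(recs), k=1)
    intra = dist[iu][same[iu]]
    inter = dist[iu][~same[iu]]
    intra = intra[np.isfinite(intra)]
    inter = inter[np.isfinite(inter)]
    a = float(np.percentile(intra, 95)) if intra.size else 0.0
    b = float(np.percentile(inter, 5)) if inter.size else math.inf
    rep_vecs = {
        otu: kmer_vector(rep.sequence, best_k)
        for otu, rep in ref.representatives.items()
    }
    state = {"k": best_k, "a": a, "b": b, "rep_vecs": rep_vecs}
    ref._cache[key] = state
    return state


def assign_fzkmer(
    query: BarcodeRecord, ref: AssignmentReference, k_max: int = 5
) -> MethodEntry:
    """Alignment-free fuzzy assignment in k-mer frequency space."""
    if query.ungapped_length() < k_max:
        raise ValueError("query shorter than k_max")
    state = _library_kmer_state(ref, k_max)
    qv = kmer_vector(query.sequence, state["k"])
    kdists = {
        otu: float(np.linalg.norm(qv - v)) for otu, v in state["rep_vecs"].items()
    }
    selected = _nearest(kdists)
    prob = fuzzy_membership(kdists[selected], state["a"], state["b"])
    # distance/ratio diagnostics are reported on the common K2P scale
    dists = ref.k2p_to_representatives(query)
    nn, d_nn, ratio = _ratio(dists, selected)
    note = "uninformative" if len(ref.representatives) == 1 else ""
    if note:
        prob = 1.0
    return MethodEntry(
        selected_otu=selected,
        probability=prob,
        dist_to_selected=dists[selected],
        nn_otu=nn,
        dist_to_nn=d_nn,
        ratio=ratio,
        note=note,
    )


def _bp_model(
    ref: AssignmentReference,
    hidden_units: int,
    epochs: int,
    learning_rate: float,
    k_feat: int,
    seed: int,
):
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.neural_network import MLPClassifier

    key = ("bp", hidden_units, epochs, learning_rate, k_feat, seed)
    if key in ref._cache:
        return ref._cache[key]
    recs = list(ref.library.qc_passing())
    X = np.array([kmer_vector(r.sequence, k_feat) for r in recs])
    y = np.array([ref.partition.assignments[r.record_id] for r in recs])
    if len(set(y)) < 2:
        raise ValueError("BP needs at least 2 OTUs in the reference")
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden_units,),
        activation="logistic",
        learning_rate_init=learning_rate,
        max_iter=epochs,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        clf.fit(X, y)
    ref._cache[key] = clf
    return clf


def assign_bp(
    queries: Sequence[BarcodeRecord],
    ref: AssignmentReference,
    hidden_units: int = 10,
    epochs: int = 1000,
    learning_rate: float = 0.01,
    k_feat: int = 3,
    seed: int = 1,
) -> List[MethodEntry]:
    """Backpropagation-network assignment; deterministic under ``seed``."""
    clf = _bp_model(ref, hidden_units, epochs, learning_rate, k_feat, seed)
    if not queries:
        return []
    Xq = np.array([kmer_vector(q.sequence, k_feat) for q in queries])
    proba = clf.predict_proba(Xq)
    out = []
    for qi, q in enumerate(queries):
        j = int(np.argmax(proba[qi]))
        selected = str(clf.classes_[j])
        dists = ref.k2p_to_representatives(q)
        nn, d_nn, ratio = _ratio(dists, selected)
        out.append(
            MethodEntry(
                selected_otu=selected,
                probability=float(proba[qi, j]),
                dist_to_selected=dists[selected],
                nn_otu=nn,
                dist_to_nn=d_nn,
                ratio=ratio,
            )
        )
    return out


def consensus_assignment(
    entries: Dict[str, MethodEntry]
) -> Tuple[str, str, float]:
    """2-of-3 consensus: (consensus_otu or 'ambiguous', level, mean prob)."""
    if len(entries) != 3:
        raise ValueError("consensus needs exactly three method entries")
    picks = [e.selected_otu for e in entries.values()]
    mean_prob = float(np.mean([e.probability for e in entries.values()]))
    for otu in sorted(set(picks)):
        n = picks.count(otu)
        if n >= 2:
            return otu, ("3/3" if n == 3 else "2/3"), mean_prob
    return "ambiguous", "none", mean_prob


def ratio_diagnostic(
    query: BarcodeRecord, selected_otu: str, ref: AssignmentReference
) -> float:
    """d(query, selected representative) / d(query, nearest other OTU);
    values above 1 flag a selection that is not the nearest OTU."""
    if len(ref.representatives) < 2:
        raise ValueError("ratio diagnostic needs at least 2 OTUs")
    dists = ref.k2p_to_representatives(query)
    _, _, ratio = _ratio(dists, selected_otu)
    return ratio


def assign_all(
    queries: Sequence[BarcodeRecord],
    ref: AssignmentReference,
    hidden_units: int = 10,
    epochs: int = 1000,
    learning_rate: float = 0.01,
    k_feat: int = 3,
    k_max: int = 5,
    seed: int = 1,
) -> List[AssignmentOutcome]:
    """Run BP, FZ and FZKMER on every query and attach the consensus."""
    bp_entries = assign_bp(
        queries, ref, hidden_units, epochs, learning_rate, k_feat, seed
    )
    outcomes = []
    for q, bp in zip(queries, bp_entries):
        entries = {
            "BP": bp,
            "FZ": assign_fz(q, ref),
            "FZKMER": assign_fzkmer(q, ref, k_max=k_max),
        }
        otu, level, mean_prob = consensus_assignment(entries)
        outcomes.append(
            AssignmentOutcome(
                query_id=q.record_id,
                entries=entries,
                consensus_otu=otu,
                consensus_level=level,
                mean_probability=mean_prob,
            )
        )
    return outcomes
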