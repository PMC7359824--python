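"""Two-round iterative curation workflow.

Round 1 delimits the reference library with the four methods, builds the
consensus partition, and assigns every query with the three assignment
methods plus their 2-of-3 consensus.  Round 2 re-delimits the pooled set
(reference + queries): query-only consensus OTUs are "new" OTUs whose
one promoted representative joins the updated reference; merges and
splits are honored by rebuilding the assignment reference from the
pooled consensus; the remaining queries are reassigned.

A query's truth is its OTU in the pooled consensus, mapped onto the
round's reference OTUs by maximum overlap; consensus assignments that
match it are true positives, queries whose pooled OTU has no reference
member count as false positives (round 1), and ambiguous consensus
verdicts stay in the denominator of the percent-correct statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from barcurate.assign import (
    AssignmentOutcome,
    AssignmentReference,
    assign_all,
    build_reference,
)
from barcurate.delimit import (
    PartitionDiff,
    abgd_partition,
    compare_partitions,
    consensus_partition,
    gmyc_partition,
    ptp_partition,
    rsl_partition,
)
from barcurate.distmat import DistMatrix, GapTable, gap_table, pairwise_matrix
from barcurate.partition import Partition, relabel_canonical
from barcurate.seqio import BarcodeRecord, ReferenceLibrary
from barcurate.treebuild import (
    dedupe_tips,
    expand_partition,
    midpoint_root,
    nj_tree,
    read_newick,
    upgma_chronogram,
)

__all__ = [
    "PipelineConfig",
    "RoundReport",
    "DelimitationBundle",
    "delimit_library",
    "run_round1",
    "run_round2",
    "run_iterative",
    "classify_outcomes",
    "cryptic_excess",
]


@dataclass
class PipelineConfig:
    """Tunable knobs of the whole workflow (YAML-loadable)."""

    min_length: int = 500
    rsl_threshold: float = 0.022
    abgd_p_min: float = 0.001
    abgd_p_max: float = 0.1
    abgd_steps: int = 10
    abgd_gap_width_x: float = 1.5
    ptp_mode: str = "multi"
    ptp_restarts: int = 10
    gmyc_mode: str = "multi"
    gmyc_alpha: float = 0.05
    gmyc_df: int = 2
    clock_rate: float = 0.012
    min_agree: int = 2
    bp_hidden_units: int = 10
    bp_epochs: int = 1000
    bp_learning_rate: float = 0.01
    bp_k_feat: int = 3
    fzkmer_k_max: int = 5
    ml_tree_path: Optional[str] = None  # user newick for PTP
    chronogram_path: Optional[str] = None  # user ultrametric newick for GMYC

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class DelimitationBundle:
    partitions: Dict[str, Partition]  # per method
    consensus: Partition
    distance_matrix: DistMatrix
    scores: Dict[str, Optional[float]]
    gmyc_p_value: Optional[float] = None


def delimit_library(
    library: ReferenceLibrary, config: PipelineConfig, seed: int = 1
) -> DelimitationBundle:
    """Run all four delimiters on deduplicated haplotypes, expand the
    partitions back over duplicates, and build the consensus."""
    D = pairwise_matrix(library)
    reps, expansion = dedupe_tips(library)
    Dr = D.submatrix(reps)

    parts: Dict[str, Partition] = {}
    scores: Dict[str, Optional[float]] = {}

    p = rsl_partition(Dr, seed_threshold=config.rsl_threshold)
    parts["RSL"] = expand_partition(p, expansion)
    scores["RSL"] = None

    res = abgd_partition(
        Dr,
        p_min=config.abgd_p_min,
        p_max=config.abgd_p_max,
        steps=config.abgd_steps,
        gap_width_x=config.abgd_gap_width_x,
    )
    parts["ABGD"] = expand_partition(res.selected, expansion)
    scores["ABGD"] = None

    if config.ml_tree_path:
        ml = read_newick(config.ml_tree_path)
        ml.is_rooted = True
    else:
        ml = midpoint_root(nj_tree(Dr)) if len(reps) >= 3 else None
    if ml is not None and sum(1 for _ in ml.leaf_node_iter()) >= 4:
        p = ptp_partition(ml, mode=config.ptp_mode, seed=seed, restarts=config.ptp_restarts)
        scores["PTP"] = p.score
    else:
        p = Partition({r: "P0" for r in reps}, method="PTP")
        scores["PTP"] = None
    parts["PTP"] = expand_partition(p, expansion)

    if config.chronogram_path:
        chrono = read_newick(config.chronogram_path)
        chrono.is_rooted = True
    else:
        chrono = upgma_chronogram(Dr, clock_rate=config.clock_rate)
    g = gmyc_partition(
        chrono, mode=config.gmyc_mode, alpha=config.gmyc_alpha, df=config.gmyc_df
    )
    parts["GMYC"] = expand_partition(g.partition, expansion)
    scores["GMYC"] = g.logL

    cons = consensus_partition(list(parts.values()), min_agree=config.min_agree)
    return DelimitationBundle(
        partitions=parts,
        consensus=cons,
        distance_matrix=D,
        scores=scores,
        gmyc_p_value=g.p_value,
    )


@dataclass
class MethodTally:
    n_true_positive: int = 0
    n_false_positive: int = 0
    n_ambiguous: int = 0
    pct_correct: float = 0.0
    mean_prob_tp: float = math.nan
    mean_prob_fp: float = math.nan
    median_prob_tp: float = math.nan
    median_prob_fp: float = math.nan


@dataclass
class RoundReport:
    round_index: int
    n_queries: int
    per_method: Dict[str, MethodTally]
    consensus: MethodTally
    pct_consensus_3of3: float
    pct_consensus_2of3: float
    pct_consensus_total: float
    gap_table: Optional[GapTable] = None
    partition_diff: Optional[PartitionDiff] = None
    n_new_otus: int = 0
    promoted_representative_ids: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def tally(t: MethodTally) -> dict:
            return {k: (None if isinstance(v, float) and math.isnan(v) else v)
                    for k, v in asdict(t).items()}

        return {
            "round_index": self.round_index,
            "n_queries": self.n_queries,
            "per_method": {m: tally(t) for m, t in self.per_method.items()},
            "consensus": tally(self.consensus),
            "pct_consensus_3of3": self.pct_consensus_3of3,
            "pct_consensus_2of3": self.pct_consensus_2of3,
            "pct_consensus_total": self.pct_consensus_total,
            "n_new_otus": self.n_new_otus,
            "promoted_representative_ids": list(self.promoted_representative_ids),
            "fold_ratio": None
            if self.gap_table is None or self.gap_table.fold_ratio is None
            else self.gap_table.fold_ratio,
            "adjusted_rand_index": None
            if self.partition_diff is None
            else self.partition_diff.adjusted_rand_index,
        }


def _truth_map(
    pooled_consensus: Partition, reference_partition: Partition
) -> Dict[str, Optional[str]]:
    """Pooled-consensus OTU -> reference OTU by maximum overlap on the
    reference members (ties to the smallest reference OTU id); None when
    the pooled OTU holds no reference member."""
    out: Dict[str, Optional[str]] = {}
    ref_ids = set(reference_partition.assignments)
    for potu, members in pooled_consensus.otus().items():
        counts: Dict[str, int] = {}
        for rid in members:
            if rid in ref_ids:
                rotu = reference_partition.assignments[rid]
                counts[rotu] = counts.get(rotu, 0) + 1
        if not counts:
            out[potu] = None
        else:
            top = max(counts.values())
            out[potu] = min(o for o, c in counts.items() if c == top)
    return out


def _pct(numer: int, denom: int) -> float:
    return round(100.0 * numer / denom, 1) if denom else 0.0


def _prob_stats(probs: List[float]) -> Tuple[float, float]:
    if not probs:
        return math.nan, math.nan
    return float(np.mean(probs)), float(np.median(probs))


def classify_outcomes(
    outcomes: Sequence[AssignmentOutcome],
    pooled_consensus: Partition,
    reference_partition: Partition,
    round_index: int = 1,
    gap_table: Optional[GapTable] = None,
    partition_diff: Optional[PartitionDiff] = None,
    n_new_otus: int = 0,
    promoted_representative_ids: Sequence[str] = (),
) -> RoundReport:
    """Score assignment outcomes against the pooled delimitation truth."""
    truth_of_otu = _truth_map(pooled_consensus, reference_partition)
    n = len(outcomes)

    methods = sorted({m for oc in outcomes for m in oc.entries}) if n else []
    per_method: Dict[str, MethodTally] = {}
    for m in methods:
        tp = fp = 0
        tp_probs, fp_probs = [], []
        for oc in outcomes:
            truth = truth_of_otu.get(pooled_consensus.assignments[oc.query_id])
            e = oc.entries[m]
            if truth is not None and e.selected_otu == truth:
                tp += 1
                tp_probs.append(e.probability)
            else:
                fp += 1
                fp_probs.append(e.probability)
        mt, mdt = _prob_stats(tp_probs)
        mf, mdf = _prob_stats(fp_probs)
        per_method[m] = MethodTally(
            n_true_positive=tp,
            n_false_positive=fp,
            n_ambiguous=0,
            pct_correct=_pct(tp, n),
            mean_prob_tp=mt,
            mean_prob_fp=mf,
            median_prob_tp=mdt,
            median_prob_fp=mdf,
        )

    tp = fp = amb = n3 = n2 = 0
    tp_probs, fp_probs = [], []
    for oc in outcomes:
        if oc.query_id not in pooled_consensus.assignments:
            raise ValueError(f"query {oc.query_id!r} missing from pooled consensus")
        if oc.consensus_level == "3/3":
            n3 += 1
        elif oc.consensus_level == "2/3":
            n2 += 1
        truth = truth_of_otu.get(pooled_consensus.assignments[oc.query_id])
        if oc.consensus_otu == "ambiguous":
            amb += 1
        elif truth is not None and oc.consensus_otu == truth:
            tp += 1
            tp_probs.append(oc.mean_probability)
        else:
            fp += 1
            fp_probs.append(oc.mean_probability)
    mt, mdt = _prob_stats(tp_probs)
    mf, mdf = _prob_stats(fp_probs)
    consensus = MethodTally(
        n_true_positive=tp,
        n_false_positive=fp,
        n_ambiguous=amb,
        pct_correct=_pct(tp, n),
        mean_prob_tp=mt,
        mean_prob_fp=mf,
        median_prob_tp=mdt,
        median_prob_fp=mdf,
    )
    p3 = _pct(n3, n)
    p2 = _pct(n2, n)
    return RoundReport(
        round_index=round_index,
        n_queries=n,
        per_method=per_method,
        consensus=consensus,
        pct_consensus_3of3=p3,
        pct_consensus_2of3=p2,
        pct_consensus_total=round(p3 + p2, 1),
        gap_table=gap_table,
        partition_diff=partition_diff,
        n_new_otus=n_new_otus,
        promoted_representative_ids=list(promoted_representative_ids),
    )


@dataclass
class Round1Result:
    consensus: Partition
    bundle: DelimitationBundle
    reference: AssignmentReference
    outcomes: List[AssignmentOutcome]
    gap_table: GapTable


def run_round1(
    reference: ReferenceLibrary,
    queries: Sequence[BarcodeRecord],
    config: PipelineConfig,
    seed: int = 1,
) -> Round1Result:
    bundle = delimit_library(reference, config, seed=seed)
    gt = gap_table(bundle.distance_matrix, bundle.consensus)
    ref = build_reference(reference, bundle.consensus, seed=seed)
    outcomes = assign_all(
        list(queries),
        ref,
        hidden_units=config.bp_hidden_units,
        epochs=config.bp_epochs,
        learning_rate=config.bp_learning_rate,
        k_feat=config.bp_k_feat,
        k_max=config.fzkmer_k_max,
        seed=seed,
    )
    return Round1Result(
        consensus=bundle.consensus,
        bundle=bundle,
        reference=ref,
        outcomes=outcomes,
        gap_table=gt,
    )


@dataclass
class Round2Result:
    pooled_consensus: Partition
    bundle: DelimitationBundle
    updated_library: ReferenceLibrary
    updated_partition: Partition
    reference: AssignmentReference
    outcomes: List[AssignmentOutcome]
    diff: PartitionDiff
    new_otus: List[str]
    promoted_ids: List[str]
    gap_table: GapTable


def run_round2(
    reference: ReferenceLibrary,
    queries: Sequence[BarcodeRecord],
    round1: Round1Result,
    config: PipelineConfig,
    seed: int = 1,
) -> Round2Result:
    queries = list(queries)
    pooled = ReferenceLibrary(
        records=list(reference.records) + queries,
        alignment_length=reference.alignment_length,
    )
    bundle = delimit_library(pooled, config, seed=seed)
    pooled_cons = bundle.consensus
    gt = gap_table(bundle.distance_matrix, pooled_cons)
    diff = compare_partitions(round1.consensus, pooled_cons)

    ref_ids = set(r.record_id for r in reference.records)
    new_otus = sorted(
        otu
        for otu, members in pooled_cons.otus().items()
        if not any(m in ref_ids for m in members)
    )
    rng = np.random.default_rng(seed)
    by_id = {q.record_id: q for q in queries}
    promoted: List[str] = []
    for otu in new_otus:
        members = sorted(
            m for m in pooled_cons.otus()[otu] if m in by_id
        )
        promoted.append(members[int(rng.integers(len(members)))])

    updated_records = list(reference.records) + [by_id[rid] for rid in promoted]
    updated_partition = pooled_cons.restrict(r.record_id for r in updated_records)
    updated_library = ReferenceLibrary(
        records=updated_records,
        alignment_length=reference.alignment_length,
        partition=updated_partition,
    )
    ref2 = build_reference(updated_library, updated_partition, seed=seed)
    remaining = [q for q in queries if q.record_id not in set(promoted)]
    outcomes = assign_all(
        remaining,
        ref2,
        hidden_units=config.bp_hidden_units,
        epochs=config.bp_epochs,
        learning_rate=config.bp_learning_rate,
        k_feat=config.bp_k_feat,
        k_max=config.fzkmer_k_max,
        seed=seed,
    )
    return Round2Result(
        pooled_consensus=pooled_cons,
        bundle=bundle,
        updated_library=updated_library,
        updated_partition=updated_partition,
        reference=ref2,
        outcomes=outcomes,
        diff=diff,
        new_otus=new_otus,
        promoted_ids=promoted,
        gap_table=gt,
    )


def run_iterative(
    reference: ReferenceLibrary,
    queries: Sequence[BarcodeRecord],
    config: Optional[PipelineConfig] = None,
    seed: int = 1,
) -> Tuple[RoundReport, RoundReport, Round1Result, Round2Result]:
    """Full two-round workflow; round-1 outcomes are scored against the
    round-2 pooled delimitation, as the iterative design prescribes."""
    config = config or PipelineConfig()
    r1 = run_round1(reference, queries, config, seed=seed)
    r2 = run_round2(reference, queries, r1, config, seed=seed)
    report1 = classify_outcomes(
        r1.outcomes,
        r2.pooled_consensus,
        r1.consensus,
        round_index=1,
        gap_table=r1.gap_table,
    )
    report2 = classify_outcomes(
        r2.outcomes,
        r2.pooled_consensus,
        r2.updated_partition,
        round_index=2,
        gap_table=r2.gap_table,
        partition_diff=r2.diff,
        n_new_otus=len(r2.new_otus),
        promoted_representative_ids=r2.promoted_ids,
    )
    return report1, report2, r1, r2


def cryptic_excess(consensus: Partition, nominal_taxa) -> float:
    """Percent excess of delimited OTUs over distinct nominal taxa:
    100 * (n_OTUs - n_nominal) / n_nominal."""
    if hasattr(nominal_taxa, "values") and not isinstance(nominal_taxa, (list, set, tuple)):
        labels = list(nominal_taxa.values())
    else:
        labels = list(nominal_taxa)
    n_nominal = len({l for l in labels if l})
    if n_nominal == 0:
        raise ValueError("no nominal taxa supplied")
    return 100.0 * (consensus.n_otus() - n_nominal) / n_nominal
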