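"""Synthetic barcode libraries with known OTU truth.

The generator emulates the statistical structure the curation workflow
assumes: species-level clusters of low intraspecific divergence separated
from their nearest neighbors by a barcode gap.  A Yule species tree is
rescaled so the smallest between-species divergence is ``gap_factor``
times the intraspecific depth; sequences then evolve along the tree under
the K2P substitution process (transition/transversion rate ratio
``kappa``), and within each species the sampled records radiate from the
species ancestor.  On top of the clean structure the generator can plant
cryptic lineage pairs sharing one nominal name, query-only OTUs absent
from the reference, and mislabeled records — the scenarios an iterative
curation round must detect.

Everything is driven by a single integer seed; identical configurations
produce byte-identical output.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import dendropy
import numpy as np
from dendropy.simulate import treesim

from barcurate.distmat import pairwise_matrix, gap_table
from barcurate.partition import Partition
from barcurate.seqio import BarcodeRecord, ReferenceLibrary

__all__ = ["SimConfig", "SimTruth", "simulate_library", "realized_structure", "write_simulation"]

# base coding: A=0, G=2 (purines), C=1, T=3 (pyrimidines); the transition
# partner is base XOR 2, the transversion partners flip the low bit.
_BASES = np.array(list("AGCT"))
_ORDER = {"A": 0, "G": 2, "C": 1, "T": 3}
_DECODE = {0: "A", 1: "C", 2: "G", 3: "T"}


@dataclass
class SimConfig:
    n_species: int = 15
    n_per_species: int = 5
    seq_length: int = 538
    kappa: float = 2.0  # transition/transversion rate ratio
    intra_depth: float = 0.01  # expected max intra-species K2P distance
    gap_factor: float = 5.0  # min inter / max intra divergence
    max_inter_depth: float = 0.3  # largest pairwise between-species divergence
    n_cryptic: int = 0  # species-label pairs spanning 2 true OTUs
    n_unsampled_query_otus: int = 0
    n_queries_per_otu: int = 0  # queries contributed by every query-bearing OTU
    mislabel_rate: float = 0.0
    coalescent_intra: bool = False  # Kingman genealogy instead of a star
    seed: int = 1

    def validate(self) -> None:
        if self.gap_factor < 1:
            raise ValueError("gap_factor must be >= 1")
        if min(
            self.n_species,
            self.n_per_species,
            self.n_cryptic,
            self.n_unsampled_query_otus,
            self.n_queries_per_otu,
        ) < 0:
            raise ValueError("counts must be non-negative")
        if not (0 <= self.mislabel_rate < 1):
            raise ValueError("mislabel_rate must be in [0, 1)")
        if self.n_species < 1 or self.n_per_species < 1:
            raise ValueError("need at least 1 species with 1 sequence")


@dataclass
class RecordFlags:
    is_query: bool = False
    is_unsampled_otu: bool = False
    is_mislabeled: bool = False


@dataclass
class SimTruth:
    true_partition: Partition
    species_tree: dendropy.Tree
    flags: Dict[str, RecordFlags] = field(default_factory=dict)


_STOP_CODONS = ("TAA", "TAG", "AGA", "AGG")  # vertebrate mitochondrial code
_STOPS_ENC = {
    tuple(_ORDER[c] for c in codon) for codon in _STOP_CODONS
}


def _revert_stop_codons(seq: np.ndarray, parent: np.ndarray) -> np.ndarray:
    """Undo substitutions that created a frame-0 stop codon.

    The marker is protein coding: purifying selection removes lineages with
    premature stops, so the substitution process never fixes one.  Reverting
    the offending sites to the parental state emulates that constraint.
    """
    out = seq.copy()
    for i in range(0, len(out) - 2, 3):
        if tuple(out[i : i + 3]) in _STOPS_ENC:
            out[i : i + 3] = parent[i : i + 3]
    return out


def _evolve(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One K2P step of expected ``d`` substitutions/site along a branch,
    constrained to stay stop-codon-free in the reading frame."""
    if d <= 0:
        return seq.copy()
    bt = d / (kappa + 2.0)  # beta * t
    at = kappa * bt  # alpha * t
    e4b = math.exp(-4.0 * bt)
    e2ab = math.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv_each = 0.25 - 0.25 * e4b
    u = rng.random(seq.shape[0])
    out = seq.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv_each)
    tv2 = (u >= p_ts + p_tv_each) & (u < p_ts + 2 * p_tv_each)
    out[ts] = seq[ts] ^ 2  # transition partner
    out[tv1] = seq[tv1] ^ 1
    out[tv2] = seq[tv2] ^ 3
    return _revert_stop_codons(out, seq)


def _decode(seq: np.ndarray) -> str:
    return "".join(_DECODE[int(b)] for b in seq)


def _species_sequences(
    anc_seq: np.ndarray, n: int, config: SimConfig, rng: np.random.Generator
) -> List[np.ndarray]:
    """Sequences of ``n`` conspecific records descending from ``anc_seq``.

    ``intra_depth`` is the expected *realized* maximum intraspecific K2P
    distance.  At the default 538 sites the K2P estimator's binomial noise
    contributes roughly as much spread to the realized maximum as the true
    divergences do, so tip depths are drawn uniform on [0, intra_depth/4]:
    the deepest pair then has true divergence near intra_depth/2 and its
    realized estimate concentrates around intra_depth.  With
    ``coalescent_intra`` a Kingman genealogy is simulated instead (heights
    rescaled to the same cap) and sequences evolve along it.
    """
    half = config.intra_depth / 4.0
    if not config.coalescent_intra or n == 1:
        return [
            _evolve(anc_seq, float(d), config.kappa, rng)
            for d in rng.uniform(0.0, half, size=n)
        ]
    # Kingman genealogy: lineages as (height, sequence slot) trees
    nodes = [{"height": 0.0, "children": [], "tip": i} for i in range(n)]
    active = list(range(n))
    heights = []
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(len(active), size=2, replace=False).tolist())
        b = active.pop(j)
        a = active.pop(i)
        nodes.append({"height": t, "children": [a, b], "tip": None})
        active.append(len(nodes) - 1)
        heights.append(t)
    scale = half / heights[-1]
    out: List[Optional[np.ndarray]] = [None] * n

    def descend(idx: int, seq: np.ndarray) -> None:
        node = nodes[idx]
        if node["tip"] is not None:
            out[node["tip"]] = seq
            return
        for c in node["children"]:
            d = (node["height"] - nodes[c]["height"]) * scale
            descend(c, _evolve(seq, d, config.kappa, rng))

    descend(active[0], anc_seq)
    return [s for s in out]  # type: ignore[misc]


def simulate_library(
    config: SimConfig,
) -> Tuple[ReferenceLibrary, List[BarcodeRecord], SimTruth]:
    """Generate (reference library, query batch, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree_rng = random.Random(int(rng.integers(2**31)))

    n_total = config.n_species + config.n_unsampled_query_otus
    if n_total >= 2:
        tree = treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=n_total,
            rng=tree_rng,
        )
        # Remap node ages affinely so the youngest split sits at the barcode
        # gap (min between-species divergence = gap_factor * intra_depth) and
        # the root at max_inter_depth: the Yule topology and the relative
        # order of splits are kept, divergences stay in the COI range, and
        # the K2P estimator never saturates.
        from barcurate.treebuild import node_ages

        ages = node_ages(tree)
        internal_ages = [ages[n] for n in tree.preorder_node_iter() if not n.is_leaf()]
        a_min, a_max = min(internal_ages), max(internal_ages)
        lo = config.gap_factor * config.intra_depth / 2.0
        hi = max(config.max_inter_depth / 2.0, lo)
        new_age = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                new_age[node] = 0.0
            elif a_max == a_min:
                new_age[node] = lo
            else:
                new_age[node] = lo + (ages[node] - a_min) * (hi - lo) / (a_max - a_min)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = new_age[node.parent_node] - new_age[node]
    else:
        tree = dendropy.Tree()
        tree.seed_node.taxon = tree.taxon_namespace.new_taxon(label="T1")

    # ancestral sequence per species tip (stop-free in the reading frame)
    root_seq = rng.integers(0, 4, size=config.seq_length).astype(np.int64)
    for i in range(0, config.seq_length - 2, 3):
        while tuple(root_seq[i : i + 3]) in _STOPS_ENC:
            root_seq[i : i + 3] = rng.integers(0, 4, size=3)
    anc: Dict[dendropy.Node, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            anc[node] = root_seq
        else:
            anc[node] = _evolve(
                anc[node.parent_node], node.edge.length or 0.0, config.kappa, rng
            )
    tip_seqs = [anc[leaf] for leaf in tree.leaf_node_iter()]

    species_idx = list(range(n_total))
    unsampled = set(
        rng.choice(species_idx, size=config.n_unsampled_query_otus, replace=False).tolist()
        if config.n_unsampled_query_otus
        else []
    )
    sampled = [i for i in species_idx if i not in unsampled]

    labels = {i: f"Species_{i + 1:03d}" for i in species_idx}
    cryptic_pairs = []
    if config.n_cryptic:
        if 2 * config.n_cryptic > len(sampled):
            raise ValueError("not enough sampled species for the cryptic pairs")
        pool = rng.permutation(sampled).tolist()
        for _ in range(config.n_cryptic):
            a, b = pool.pop(), pool.pop()
            labels[b] = labels[a]  # two true OTUs share one nominal name
            cryptic_pairs.append((a, b))

    ref_records: List[BarcodeRecord] = []
    queries: List[BarcodeRecord] = []
    assignments: Dict[str, str] = {}
    flags: Dict[str, RecordFlags] = {}

    def make_record(si: int, seq: np.ndarray, tag: str, j: int, is_query: bool) -> BarcodeRecord:
        rid = f"{tag}{si + 1:03d}_{j + 1:02d}"
        rec = BarcodeRecord(
            record_id=rid, sequence=_decode(seq), nominal_taxon=labels[si]
        )
        assignments[rid] = f"SP{si + 1:03d}"
        flags[rid] = RecordFlags(
            is_query=is_query, is_unsampled_otu=si in unsampled
        )
        return rec

    for si in sampled:
        n_here = config.n_per_species + config.n_queries_per_otu
        seqs = _species_sequences(tip_seqs[si], n_here, config, rng)
        for j in range(config.n_per_species):
            ref_records.append(make_record(si, seqs[j], "REF", j, is_query=False))
        for j in range(config.n_queries_per_otu):
            queries.append(
                make_record(
                    si, seqs[config.n_per_species + j], "QRY",
                    config.n_per_species + j, is_query=True,
                )
            )
    for si in sorted(unsampled):
        seqs = _species_sequences(tip_seqs[si], config.n_queries_per_otu, config, rng)
        for j in range(config.n_queries_per_otu):
            queries.append(make_record(si, seqs[j], "QRY", j, is_query=True))

    sampled_labels = sorted({labels[i] for i in sampled})
    for rec in ref_records:
        if config.mislabel_rate and rng.random() < config.mislabel_rate:
            others = [l for l in sampled_labels if l != rec.nominal_taxon]
            if others:
                rec.nominal_taxon = others[int(rng.integers(len(others)))]
                flags[rec.record_id].is_mislabeled = True

    library = ReferenceLibrary(records=ref_records)
    truth = SimTruth(
        true_partition=Partition(dict(assignments), method="truth"),
        species_tree=tree,
        flags=flags,
    )
    return library, queries, truth


def realized_structure(library: ReferenceLibrary, truth: SimTruth):
    """Realized per-OTU max-intra / nearest-neighbor summary of a simulated
    reference library, for assertions about the generated gap."""
    part = truth.true_partition.restrict(r.record_id for r in library.qc_passing())
    D = pairwise_matrix(library)
    gt = gap_table(D, part)
    df = gt.per_otu
    if gt.single_otu:
        return {"per_otu": df, "min_inter": None, "max_intra": float(df["max_intraspecific"].max()), "gap_ratio": None, "single_otu": True}
    finite_intra = df["max_intraspecific"].to_numpy(dtype=float)
    finite_intra = finite_intra[np.isfinite(finite_intra)]
    max_intra = float(finite_intra.max())
    min_inter = float(df["nn_distance"].min())
    ratio = math.inf if max_intra == 0 else min_inter / max_intra
    return {
        "per_otu": df,
        "min_inter": min_inter,
        "max_intra": max_intra,
        "gap_ratio": ratio,
        "single_otu": False,
    }


def write_simulation(
    library: ReferenceLibrary,
    queries: List[BarcodeRecord],
    truth: SimTruth,
    out_dir,
) -> Dict[str, Path]:
    """Write reference FASTA/TSV, query FASTA/TSV, and the truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_fasta": out_dir / "reference.fasta",
        "reference_tsv": out_dir / "reference.tsv",
        "query_fasta": out_dir / "queries.fasta",
        "query_tsv": out_dir / "queries.tsv",
        "truth_tsv": out_dir / "truth.tsv",
    }

    def _write(records, fasta, tsv):
        with open(fasta, "w") as fh:
            for r in records:
                fh.write(f">{r.record_id}\n{r.sequence}\n")
        with open(tsv, "w") as fh:
            fh.write("record_id\tnominal_taxon\tlocality\n")
            for r in records:
                fh.write(f"{r.record_id}\t{r.nominal_taxon}\t{r.locality}\n")

    _write(library.records, paths["reference_fasta"], paths["reference_tsv"])
    _write(queries, paths["query_fasta"], paths["query_tsv"])
    with open(paths["truth_tsv"], "w") as fh:
        fh.write("record_id\ttrue_otu\tis_query\tis_unsampled_otu\tis_mislabeled\n")
        for rid, otu in truth.true_partition.assignments.items():
            fl = truth.flags[rid]
            fh.write(
                f"{rid}\t{otu}\t{int(fl.is_query)}\t{int(fl.is_unsampled_otu)}\t{int(fl.is_mislabeled)}\n"
            )
    return paths
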