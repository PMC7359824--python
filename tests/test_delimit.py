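"""ABGD, RSL, consensus and partition-diff behavior (PTP and GMYC have
their own oracle-backed test modules)."""

import itertools
import math

import numpy as np
import pytest

from barcurate.delimit import (
    abgd_partition,
    compare_partitions,
    consensus_partition,
    rsl_partition,
)
from barcurate.partition import Partition
from conftest import block_matrix, make_matrix


def threshold_components(values, thr):
    """Oracle: connected components joining pairs with d <= thr."""
    n = len(values)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if values[i, j] <= thr:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


class TestABGD:
    def test_all_identical_single_otu(self):
        D = make_matrix([f"r{i}" for i in range(6)], lambda i, j: 0.0)
        res = abgd_partition(D)
        assert all(p.n_otus() == 1 for p in res.recursive)
        assert res.selected.n_otus() == 1

    def test_two_blocks_split_for_priors_below_gap(self):
        D, truth = block_matrix([10, 10], intra=0.01, inter=0.05)
        res = abgd_partition(D)
        # oracle: any threshold in (0.01, 0.05) yields exactly 2 components
        assert threshold_components(D.values, 0.02) == 2
        assert res.selected.equivalent(truth)
        for prior, part in res.by_prior:
            if 0.011 < prior < 0.05:
                assert part.n_otus() == 2

    def test_uniform_ladder_no_gap(self):
        # distances increase uniformly: no qualifying gap anywhere
        ids = [f"r{i}" for i in range(8)]
        D = make_matrix(ids, lambda i, j: 0.01 * abs(i - j))
        res = abgd_partition(D)
        assert res.selected.n_otus() == 1

    def test_group_count_weakly_decreasing_in_prior(self):
        D, _ = block_matrix([6, 6, 6], intra=0.008, inter=0.06)
        res = abgd_partition(D)
        counts = [p.n_otus() for p in res.recursive]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_needs_two_records(self):
        D = make_matrix(["a"], lambda i, j: 0)
        with pytest.raises(ValueError):
            abgd_partition(D)


class TestRSL:
    def test_two_blocks_forced_at_seed_threshold(self):
        D, truth = block_matrix([5, 5], intra=0.01, inter=0.05)
        assert rsl_partition(D).equivalent(truth)

    def test_tight_block_not_split(self):
        D = make_matrix([f"r{i}" for i in range(6)], lambda i, j: 0.004)
        assert rsl_partition(D).n_otus() == 1

    def test_refinement_splits_chained_cluster(self):
        # two tight groups bridged by one intermediate record: single linkage
        # at 2.2% chains them; silhouette refinement must split where the
        # brute-force silhouette over the candidate cut improves
        ids = ["a1", "a2", "a3", "m", "c1", "c2", "c3"]

        def dist(i, j):
            ai, aj = ids[i], ids[j]
            side = lambda x: 0 if x.startswith("a") else (2 if x.startswith("c") else 1)
            si, sj = side(ai), side(aj)
            if si == sj:
                return 0.002
            if 1 in (si, sj):
                return 0.02
            return 0.04

        D = make_matrix(ids, dist)
        part = rsl_partition(D)
        assert part.n_otus() >= 2
        # a-records never co-cluster with c-records after refinement
        assert part.assignments["a1"] != part.assignments["c1"]

    def test_silhouette_oracle_prefers_the_returned_partition(self):
        from sklearn.metrics import silhouette_score

        D, _ = block_matrix([5, 5], intra=0.01, inter=0.05)
        part = rsl_partition(D)
        labels = np.array([part.assignments[r] for r in D.ids], dtype=object)
        base = silhouette_score(D.values, labels, metric="precomputed")
        # brute force: no 2-way regrouping of one cluster scores higher
        for grp in set(labels):
            members = np.where(labels == grp)[0]
            for k in range(1, len(members) // 2 + 1):
                for sub in itertools.combinations(members, k):
                    trial = labels.copy()
                    trial[list(sub)] = grp + "_x"
                    assert (
                        silhouette_score(D.values, trial, metric="precomputed")
                        <= base + 1e-12
                    )


class TestConsensus:
    def test_identical_partitions_returned(self):
        p = Partition({"a": "1", "b": "1", "c": "2"})
        cons = consensus_partition([p, p, p, p])
        assert cons.equivalent(p)

    def test_two_of_four_lump_wins(self):
        lump = Partition({"a": "x", "b": "x"})
        split = Partition({"a": "x", "b": "y"})
        cons = consensus_partition([lump, lump, split, split], min_agree=2)
        assert cons.n_otus() == 1

    def test_transitive_chain(self):
        p1 = Partition({"a": "1", "b": "1", "c": "2"})
        p2 = Partition({"a": "1", "b": "1", "c": "2"})
        p3 = Partition({"a": "1", "b": "2", "c": "2"})
        p4 = Partition({"a": "1", "b": "2", "c": "2"})
        # a-b joined by p1,p2; b-c joined by p3,p4; a-c never -> one OTU
        cons = consensus_partition([p1, p2, p3, p4], min_agree=2)
        assert cons.n_otus() == 1

    def test_mismatched_ids_error(self):
        with pytest.raises(ValueError):
            consensus_partition(
                [Partition({"a": "1"}), Partition({"b": "1"})]
            )


def brute_force_ari(l1, l2):
    """Independent ARI oracle from the contingency-table formula."""
    from math import comb

    cats1, cats2 = sorted(set(l1)), sorted(set(l2))
    table = np.zeros((len(cats1), len(cats2)), dtype=int)
    for x, y in zip(l1, l2):
        table[cats1.index(x), cats2.index(y)] += 1
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    n = table.sum()
    idx = sum(comb(int(v), 2) for v in table.flat)
    ea = sum(comb(int(v), 2) for v in a)
    eb = sum(comb(int(v), 2) for v in b)
    expected = ea * eb / comb(n, 2)
    maximum = (ea + eb) / 2
    if maximum == expected:
        return 1.0
    return (idx - expected) / (maximum - expected)


class TestCompare:
    def test_identity(self):
        p = Partition({"a": "1", "b": "1", "c": "2"})
        diff = compare_partitions(p, p)
        assert diff.adjusted_rand_index == 1.0
        assert not diff.new_otus and not diff.merged and not diff.split

    def test_one_split_detected(self):
        p1 = Partition({"a": "1", "b": "1", "c": "1", "d": "2"})
        p2 = Partition({"a": "x", "b": "x", "c": "y", "d": "z"})
        diff = compare_partitions(p1, p2)
        assert len(diff.split) == 1 and diff.split[0][0] == "1"

    def test_merged_and_new(self):
        p1 = Partition({"a": "1", "b": "2"})
        p2 = Partition({"a": "m", "b": "m", "q1": "new", "q2": "new"})
        diff = compare_partitions(p1, p2)
        assert diff.merged == [("m", ("1", "2"))]
        assert diff.new_otus == ["new"]

    def test_ari_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        ids = [f"r{i}" for i in range(12)]
        for _ in range(20):
            l1 = rng.integers(0, 4, size=12)
            l2 = rng.integers(0, 4, size=12)
            p1 = Partition({i: f"a{x}" for i, x in zip(ids, l1)})
            p2 = Partition({i: f"b{x}" for i, x in zip(ids, l2)})
            got = compare_partitions(p1, p2).adjusted_rand_index
            assert got == pytest.approx(brute_force_ari(l1.tolist(), l2.tolist()), abs=1e-12)

    def test_p2_must_cover_p1(self):
        with pytest.raises(ValueError):
            compare_partitions(
                Partition({"a": "1", "b": "1"}), Partition({"a": "1"})
            )
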