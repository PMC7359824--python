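import math

import pytest
import yaml

from barcurate.assign import AssignmentOutcome, MethodEntry
from barcurate.iterflow import (
    PipelineConfig,
    classify_outcomes,
    cryptic_excess,
    run_iterative,
    run_round1,
    run_round2,
)
from barcurate.partition import Partition
from barcurate.simlib import SimConfig, simulate_library


def fake_outcome(qid, consensus_otu, level, picks=None, prob=0.8):
    picks = picks or [consensus_otu] * 3
    entries = {
        m: MethodEntry(
            selected_otu=p,
            probability=prob,
            dist_to_selected=0.01,
            nn_otu="nn",
            dist_to_nn=0.05,
            ratio=0.2,
        )
        for m, p in zip(("BP", "FZ", "FZKMER"), picks)
    }
    return AssignmentOutcome(
        query_id=qid,
        entries=entries,
        consensus_otu=consensus_otu,
        consensus_level=level,
        mean_probability=prob,
    )


def synthetic_round(n_tp, n_fp, n_amb, n3, n2):
    """Outcomes plus matching pooled/reference partitions.

    True positives point at OTU 'T', false positives at OTU 'F'; every
    query truly belongs to 'T'.  Consensus levels are assigned 3/3 to the
    first n3 non-ambiguous outcomes and 2/3 to the next n2.
    """
    n = n_tp + n_fp + n_amb
    reference_partition = Partition({"ref_t": "T", "ref_f": "F"})
    pooled = {"ref_t": "PT", "ref_f": "PF"}
    outcomes = []
    levels = ["3/3"] * n3 + ["2/3"] * n2 + ["none"] * (n - n3 - n2)
    verdicts = ["T"] * n_tp + ["F"] * n_fp + ["ambiguous"] * n_amb
    for i, (v, lvl) in enumerate(zip(verdicts, levels)):
        qid = f"q{i}"
        pooled[qid] = "PT"
        outcomes.append(fake_outcome(qid, v, lvl))
    return outcomes, Partition(pooled), reference_partition


class TestClassifyArithmetic:
    def test_round1_percent_correct_and_consensus_totals(self):
        # 245 queries: 213 correct, 22 wrong, 10 without consensus;
        # 189 at 3/3 and 46 at 2/3
        outcomes, pooled, refpart = synthetic_round(213, 22, 10, n3=189, n2=46)
        rep = classify_outcomes(outcomes, pooled, refpart, round_index=1)
        assert rep.consensus.pct_correct == 86.9
        assert rep.pct_consensus_3of3 == 77.1
        assert rep.pct_consensus_2of3 == 18.8
        assert rep.pct_consensus_total == 95.9

    def test_round2_consensus_totals(self):
        # 237 queries: 230 at 3/3, 6 at 2/3
        outcomes, pooled, refpart = synthetic_round(236, 0, 1, n3=230, n2=6)
        rep = classify_outcomes(outcomes, pooled, refpart, round_index=2)
        assert rep.pct_consensus_3of3 == 97.0
        assert rep.pct_consensus_2of3 == 2.5
        assert rep.pct_consensus_total == 99.5

    def test_tally_invariants(self):
        outcomes, pooled, refpart = synthetic_round(7, 2, 1, n3=5, n2=3)
        rep = classify_outcomes(outcomes, pooled, refpart)
        c = rep.consensus
        assert c.n_true_positive + c.n_false_positive + c.n_ambiguous == rep.n_queries
        assert rep.pct_consensus_total == pytest.approx(
            rep.pct_consensus_3of3 + rep.pct_consensus_2of3, abs=0.1
        )

    def test_query_in_truthless_pooled_otu_counts_false_positive(self):
        # a query whose pooled OTU holds no reference member is a false
        # positive no matter what OTU was assigned
        refpart = Partition({"ref_t": "T"})
        pooled = Partition({"ref_t": "PT", "q0": "PNEW"})
        rep = classify_outcomes([fake_outcome("q0", "T", "3/3")], pooled, refpart)
        assert rep.consensus.n_false_positive == 1


class TestCrypticExcess:
    def test_published_scale(self):
        cons = Partition({f"r{i}": f"O{i % 113}" for i in range(226)})
        labels = [f"taxon{i % 102}" for i in range(226)]
        pct = cryptic_excess(cons, labels)
        assert pct == pytest.approx(100 * (113 - 102) / 102, abs=1e-9)
        assert pct > 10

    def test_equal_counts_zero(self):
        cons = Partition({"a": "1", "b": "2"})
        assert cryptic_excess(cons, ["x", "y"]) == 0.0

    def test_six_otus_four_taxa(self):
        cons = Partition({f"r{i}": f"O{i}" for i in range(6)})
        assert cryptic_excess(cons, ["a", "b", "c", "d"]) == 50.0

    def test_no_taxa_errors(self):
        with pytest.raises(ValueError):
            cryptic_excess(Partition({"a": "1"}), [])


@pytest.fixture(scope="module")
def small_workflow():
    cfg = SimConfig(
        n_species=10,
        n_per_species=5,
        n_unsampled_query_otus=2,
        n_queries_per_otu=2,
        seed=21,
    )
    lib, queries, truth = simulate_library(cfg)
    pcfg = PipelineConfig()
    rep1, rep2, r1, r2 = run_iterative(lib, queries, pcfg, seed=1)
    return lib, queries, truth, rep1, rep2, r1, r2


class TestWorkflow:
    def test_round1_consensus_and_outcome_counts(self, small_workflow):
        lib, queries, truth, rep1, rep2, r1, r2 = small_workflow
        assert len(r1.outcomes) == len(queries)
        assert r1.consensus.n_otus() == 10

    def test_zero_queries_valid(self):
        cfg = SimConfig(n_species=8, n_per_species=4, seed=5)
        lib, queries, _ = simulate_library(cfg)
        res = run_round1(lib, [], PipelineConfig(), seed=1)
        assert res.outcomes == []
        rep = classify_outcomes(res.outcomes, res.consensus, res.consensus)
        assert rep.n_queries == 0

    def test_new_otus_detected_and_promoted(self, small_workflow):
        lib, queries, truth, rep1, rep2, r1, r2 = small_workflow
        assert rep2.n_new_otus == 2
        assert len(rep2.promoted_representative_ids) == 2
        promoted = set(rep2.promoted_representative_ids)
        assert all(truth.flags[p].is_unsampled_otu for p in promoted)
        # promoted representatives leave the round-2 query pool
        assert rep2.n_queries == rep1.n_queries - len(promoted)

    def test_false_positives_drop_to_zero(self, small_workflow):
        *_, rep1, rep2, r1, r2 = small_workflow[2:]
        assert rep1.consensus.n_false_positive >= 1
        assert rep2.consensus.n_false_positive == 0
        assert rep2.consensus.pct_correct >= rep1.consensus.pct_correct

    def test_stable_delimitation_without_unsampled_otus(self):
        cfg = SimConfig(n_species=8, n_per_species=5, n_queries_per_otu=2, seed=6)
        lib, queries, truth = simulate_library(cfg)
        pcfg = PipelineConfig()
        r1 = run_round1(lib, queries, pcfg, seed=1)
        r2 = run_round2(lib, queries, r1, pcfg, seed=1)
        assert r2.new_otus == [] and r2.promoted_ids == []
        assert r2.diff.adjusted_rand_index == 1.0
        assert len(r2.outcomes) == len(queries)

    def test_end_to_end_reproducible(self, small_workflow):
        lib, queries, truth, rep1, rep2, r1, r2 = small_workflow
        rep1b, rep2b, r1b, r2b = run_iterative(lib, queries, PipelineConfig(), seed=1)
        assert r1b.consensus.assignments == r1.consensus.assignments
        assert [oc.mean_probability for oc in r1b.outcomes] == [
            oc.mean_probability for oc in r1.outcomes
        ]
        assert rep2b.to_dict() == rep2.to_dict()


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({"rsl_threshold": 0.03, "ptp_restarts": 3}))
        cfg = PipelineConfig.from_yaml(path)
        assert cfg.rsl_threshold == 0.03 and cfg.ptp_restarts == 3
        assert cfg.min_agree == 2  # untouched default

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({"nope": 1}))
        with pytest.raises(ValueError, match="nope"):
            PipelineConfig.from_yaml(path)
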