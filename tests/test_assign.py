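import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcurate.assign import (
    _library_kmer_state,
    _ratio,
    assign_all,
    assign_bp,
    assign_fz,
    assign_fzkmer,
    build_reference,
    consensus_assignment,
    fuzzy_membership,
    kmer_vector,
    ratio_diagnostic,
    MethodEntry,
)
from barcurate.partition import Partition
from barcurate.seqio import BarcodeRecord, ReferenceLibrary


def two_otu_reference(seed=1):
    """Two well-separated OTUs, 3 members each, 120 bp."""
    base_a = "ACGT" * 30
    base_b = ("ACGA" * 15 + "GCTT" * 15)  # far from A
    recs = []
    for i, var in enumerate((0, 4, 8)):
        sa = list(base_a)
        sa[var] = "G" if sa[var] != "G" else "A"
        recs.append(BarcodeRecord(f"A{i}", "".join(sa)))
    for i, var in enumerate((1, 5, 9)):
        sb = list(base_b)
        sb[var] = "C" if sb[var] != "C" else "T"
        recs.append(BarcodeRecord(f"B{i}", "".join(sb)))
    lib = ReferenceLibrary(records=recs)
    part = Partition({r.record_id: r.record_id[0] for r in recs})
    return build_reference(lib, part, seed=seed)


class TestFuzzyMembership:
    def test_anchors_and_midpoint(self):
        a, b = 0.01, 0.05
        assert fuzzy_membership(0.0, a, b) == 1.0
        assert fuzzy_membership(a, a, b) == 1.0
        assert fuzzy_membership(b, a, b) == 0.0
        assert fuzzy_membership(0.1, a, b) == 0.0
        assert fuzzy_membership((a + b) / 2, a, b) == pytest.approx(0.5)

    def test_degenerate_step(self):
        assert fuzzy_membership(0.01, 0.02, 0.01) == 1.0
        assert fuzzy_membership(0.03, 0.02, 0.01) == 0.0

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(0, 0.1), min_size=2, max_size=2).map(sorted))
    def test_non_increasing_in_distance(self, xs):
        x1, x2 = xs
        a, b = 0.005, 0.04
        assert fuzzy_membership(x1, a, b) >= fuzzy_membership(x2, a, b)


class TestBuildReference:
    def test_representatives_reproducible(self, clean_simulation):
        lib, _, truth = clean_simulation
        part = truth.true_partition.restrict(lib.ids)
        r1 = build_reference(lib, part, seed=5)
        r2 = build_reference(lib, part, seed=5)
        assert {o: r.record_id for o, r in r1.representatives.items()} == {
            o: r.record_id for o, r in r2.representatives.items()
        }
        assert set(r1.representatives) == set(part.otus())

    def test_singleton_theta1_fallback(self):
        recs = [
            BarcodeRecord("s1", "ACGT" * 30),
            BarcodeRecord("m1", "ACGA" * 30),
            BarcodeRecord("m2", "ACGA" * 15 + "ACGG" * 15),
        ]
        lib = ReferenceLibrary(records=recs)
        part = Partition({"s1": "S", "m1": "M", "m2": "M"})
        ref = build_reference(lib, part, seed=1)
        assert ref.representatives["S"].record_id == "s1"
        # singleton takes the median of multi-member max-intra values
        assert ref.theta1["S"] == pytest.approx(ref.theta1["M"])
        assert ref.theta2["S"] > 0

    def test_seed_changes_representatives_not_otus(self, clean_simulation):
        lib, _, truth = clean_simulation
        part = truth.true_partition.restrict(lib.ids)
        r1 = build_reference(lib, part, seed=1)
        r2 = build_reference(lib, part, seed=2)
        assert set(r1.representatives) == set(r2.representatives)


class TestFZ:
    def test_identical_query_probability_one(self):
        ref = two_otu_reference()
        rep = ref.representatives["A"]
        entry = assign_fz(rep, ref)
        assert entry.selected_otu == "A" and entry.probability == 1.0
        assert entry.dist_to_selected == 0.0

    def test_far_query_probability_zero(self):
        ref = two_otu_reference()
        far = BarcodeRecord("far", "TTTT" * 15 + "GGGG" * 15)
        entry = assign_fz(far, ref)
        if entry.dist_to_selected >= ref.theta2[entry.selected_otu]:
            assert entry.probability == 0.0

    def test_fz_always_selects_nearest_so_ratio_at_most_one(self, clean_simulation):
        lib, _, truth = clean_simulation
        part = truth.true_partition.restrict(lib.ids)
        ref = build_reference(lib, part, seed=1)
        for rec in lib.records[::5]:
            entry = assign_fz(rec, ref)
            assert entry.ratio <= 1.0 + 1e-12


class TestFZKMER:
    def test_identical_query_probability_one(self):
        ref = two_otu_reference()
        rep = ref.representatives["B"]
        entry = assign_fzkmer(rep, ref)
        assert entry.selected_otu == "B" and entry.probability == 1.0

    def test_k_choice_matches_brute_force_oracle(self):
        ref = two_otu_reference()
        state = _library_kmer_state(ref, k_max=5)
        recs = list(ref.library.qc_passing())
        labels = [ref.partition.assignments[r.record_id] for r in recs]

        def loo_accuracy(k):
            vecs = np.array([kmer_vector(r.sequence, k) for r in recs])
            acc = 0
            for i in range(len(recs)):
                d = [np.linalg.norm(vecs[i] - vecs[j]) if j != i else np.inf for j in range(len(recs))]
                acc += labels[int(np.argmin(d))] == labels[i]
            return acc / len(recs)

        accs = {k: loo_accuracy(k) for k in range(1, 6)}
        best = max(accs.values())
        assert state["k"] == min(k for k, a in accs.items() if a == best)

    def test_query_shorter_than_kmax_errors(self):
        ref = two_otu_reference()
        with pytest.raises(ValueError):
            assign_fzkmer(BarcodeRecord("q", "ACG"), ref, k_max=5)


class TestBP:
    def test_separable_fixture_and_determinism(self):
        ref = two_otu_reference()
        queries = [ref.representatives["A"], ref.representatives["B"]]
        entries = assign_bp(queries, ref, seed=3)
        # one-nearest-centroid oracle agrees on the separable fixture
        assert entries[0].selected_otu == "A" and entries[0].probability > 0.5
        assert entries[1].selected_otu == "B" and entries[1].probability > 0.5
        again = assign_bp(queries, ref, seed=3)
        assert [e.probability for e in entries] == [e.probability for e in again]

    def test_single_otu_reference_errors(self):
        from barcurate.assign import AssignmentReference

        recs = [BarcodeRecord("a", "ACGT" * 30), BarcodeRecord("b", "ACGT" * 30)]
        reference = AssignmentReference(
            representatives={"X": recs[0]},
            theta1={"X": 0.005},
            theta2={"X": math.inf},
            seed=1,
            library=ReferenceLibrary(records=recs),
            partition=Partition({"a": "X", "b": "X"}),
        )
        with pytest.raises(ValueError):
            assign_bp([recs[1]], reference, seed=1)


class TestConsensusAndRatio:
    @pytest.mark.parametrize(
        "picks,expected",
        [
            (("A", "A", "A"), ("A", "3/3")),
            (("A", "A", "B"), ("A", "2/3")),
            (("A", "B", "C"), ("ambiguous", "none")),
        ],
    )
    def test_consensus_rule(self, picks, expected):
        entries = {
            m: MethodEntry(
                selected_otu=p,
                probability=0.6,
                dist_to_selected=0.01,
                nn_otu="Z",
                dist_to_nn=0.05,
                ratio=0.2,
            )
            for m, p in zip(("BP", "FZ", "FZKMER"), picks)
        }
        otu, level, mean_prob = consensus_assignment(entries)
        assert (otu, level) == expected
        assert mean_prob == pytest.approx(0.6)

    def test_ratio_arithmetic(self):
        # forced wrong selection: d_selected = 0.04, d_nearest = 0.02
        nn, d_nn, ratio = _ratio({"X": 0.04, "Y": 0.02}, "X")
        assert (nn, d_nn) == ("Y", 0.02)
        assert ratio == pytest.approx(2.0)

    def test_ratio_tie_is_one(self):
        _, _, ratio = _ratio({"X": 0.03, "Y": 0.03}, "X")
        assert ratio == 1.0

    def test_ratio_diagnostic_flags_non_nearest(self):
        ref = two_otu_reference()
        query = ref.representatives["A"]
        assert ratio_diagnostic(query, "B", ref) > 1.0
        assert ratio_diagnostic(query, "A", ref) < 1.0


def test_assign_all_attaches_consensus(clean_simulation):
    lib, _, truth = clean_simulation
    part = truth.true_partition.restrict(lib.ids)
    ref = build_reference(lib, part, seed=1)
    queries = lib.records[:4]
    outcomes = assign_all(queries, ref, seed=1)
    assert len(outcomes) == 4
    for oc in outcomes:
        assert set(oc.entries) == {"BP", "FZ", "FZKMER"}
        probs = [e.probability for e in oc.entries.values()]
        assert oc.mean_probability == pytest.approx(float(np.mean(probs)))
        assert oc.consensus_level in {"3/3", "2/3", "none"}
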