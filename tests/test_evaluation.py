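import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ddiverify as dv

from conftest import make_candidate


def catalog(*member_sets):
    return dv.ComplexCatalog(
        tuple((f"K{i}", frozenset(m)) for i, m in enumerate(member_sets))
    )


class TestOverlapScore:
    def test_identical_sets(self):
        s = {"a", "b", "c", "d", "e"}
        assert dv.overlap_score(s, s) == 1.0

    def test_disjoint_sets(self):
        assert dv.overlap_score({"a", "b"}, {"x", "y"}) == 0.0

    def test_partial_overlap(self):
        pred = {"a", "b", "c", "d"}
        known = pred | {"e", "f", "g", "h"}
        assert dv.overlap_score(pred, known) == pytest.approx(16 / 32)

    def test_empty_set_is_hard_error(self):
        with pytest.raises(ValueError):
            dv.overlap_score(set(), {"a"})

    @settings(derandomize=True, max_examples=100)
    @given(
        st.sets(st.sampled_from("abcdefgh"), min_size=1),
        st.sets(st.sampled_from("abcdefgh"), min_size=1),
    )
    def test_symmetric_bounded_and_one_iff_identical(self, a, b):
        v = dv.overlap_score(a, b)
        assert v == dv.overlap_score(b, a)
        assert 0.0 <= v <= 1.0
        assert (v == 1.0) == (a == b)


class TestPrecisionRecall:
    def test_perfect_predictions(self):
        known = catalog({"a", "b", "c"}, {"x", "y", "z"})
        preds = [make_candidate(m) for m in known.member_sets]
        rep = dv.precision_recall(preds, known)
        assert rep.precision == 1.0 and rep.recall == 1.0

    def test_exact_threshold_is_unmatched(self):
        # V = 4 / (4*4) ... choose sets with V exactly 0.25: |inter|=2, sizes 4,4
        pred = {"a", "b", "x1", "x2"}
        known = catalog({"a", "b", "y1", "y2"})
        assert dv.overlap_score(pred, known.member_sets[0]) == 0.25
        rep = dv.precision_recall([make_candidate(pred)], known, threshold=0.25)
        assert rep.matched_predicted == 0 and rep.precision == 0.0

    def test_multiple_predictions_one_known(self):
        known = catalog({"a", "b", "c"}, {"x", "y", "z"})
        preds = [make_candidate({"a", "b", "c"}), make_candidate({"a", "b", "c", "d"})]
        rep = dv.precision_recall(preds, known)
        assert rep.precision == 1.0
        assert rep.recall == 0.5

    def test_empty_prediction_list_warns(self, caplog):
        with caplog.at_level("WARNING"):
            rep = dv.precision_recall([], catalog({"a", "b"}))
        assert rep.precision == 0.0 and rep.recall == 0.0

    def test_order_invariance(self):
        known = catalog({"a", "b", "c"}, {"x", "y", "z"}, {"m", "n", "o"})
        preds = [make_candidate(m) for m in
                 ({"a", "b"}, {"x", "y", "z", "w"}, {"m", "q", "r"})]
        rng = random.Random(0)
        base = dv.precision_recall(preds, known)
        for _ in range(5):
            rng.shuffle(preds)
            rep = dv.precision_recall(preds, known)
            assert (rep.precision, rep.recall) == (base.precision, base.recall)


class TestSameFunctionRatio:
    def go(self, mapping):
        return dv.GOAnnotation({k: frozenset(v) for k, v in mapping.items()})

    def test_all_share_one_term(self):
        go = self.go({p: {"GO:0000001"} for p in "abc"})
        assert dv.same_function_ratio([make_candidate(set("abc"))], go) == 1.0

    def test_one_of_three_pairs_shares(self):
        go = self.go({"a": {"GO:0000001"}, "b": {"GO:0000001"}, "c": {"GO:0000002"}})
        ratio = dv.same_function_ratio([make_candidate(set("abc"))], go)
        assert ratio == pytest.approx(1 / 3)

    def test_unknown_function_members_excluded(self):
        go = self.go({"a": {"GO:0003674"}, "b": {"GO:0003674"}, "c": {"GO:0005554"}})
        assert dv.same_function_ratio([make_candidate(set("abc"))], go) is None

    def test_unannotated_pairs_leave_denominator(self):
        go = self.go({"a": {"GO:0000001"}, "b": {"GO:0000001"}})  # c unannotated
        ratio = dv.same_function_ratio([make_candidate(set("abc"))], go)
        assert ratio == 1.0  # only the (a,b) pair is eligible


class TestFalseNegativeReport:
    def _inputs(self):
        known = catalog({"a", "b", "c"}, {"d", "e", "f"}, {"g", "h", "i"},
                        {"j", "k", "l"})
        dom = dv.DomainAnnotation.from_counts(
            {p: {"t": 1} for p in "abcdefghi"}  # j,k,l have no domains at all
        )
        cat = dv.DDICatalog.from_pairs([("t", "t")])
        return known, dom, cat

    def test_identical_predictions_give_zero_alpha(self):
        known, dom, cat = self._inputs()
        preds = [make_candidate(m) for m in known.member_sets]
        rep = dv.false_negative_report(preds, preds, known, dom, cat)
        assert rep.alpha == 0 and rep.ratio == 0.0

    def test_missed_complex_without_ddis_is_excluded(self):
        known, dom, cat = self._inputs()
        existing = [make_candidate(m) for m in known.member_sets]
        ours = existing[:3]  # miss {j,k,l}, which has no DDI annotation
        rep = dv.false_negative_report(existing, ours, known, dom, cat)
        assert rep.net_fn == 1 and rep.no_ddi_excluded == 1
        assert rep.alpha == 0

    def test_ratio_counts_ddi_annotated_misses(self):
        known, dom, cat = self._inputs()
        existing = [make_candidate(m) for m in known.member_sets]
        ours = [existing[0], existing[1], existing[3]]  # miss {g,h,i} (has DDIs)
        rep = dv.false_negative_report(existing, ours, known, dom, cat)
        assert rep.beta == 4
        assert rep.alpha == 1
        assert rep.ratio == pytest.approx(0.25)
        assert rep.alpha <= rep.fn_ours


class TestSuggestFunctions:
    def go(self, mapping):
        return dv.GOAnnotation({k: frozenset(v) for k, v in mapping.items()})

    def test_single_unknown_with_shared_term(self):
        go = self.go({
            "APL1": {"GO:0008565"}, "APS2": {"GO:0008565"},
            "APL3": {"GO:0008565"}, "APM4": {"GO:0003674"},
        })
        members = frozenset({"APL1", "APS2", "APM4", "APL3"})
        out = dv.suggest_functions([make_candidate(members)], go)
        assert out == [(members, "APM4", frozenset({"GO:0008565"}))]

    def test_two_unknown_proteins_no_suggestion(self):
        go = self.go({"a": {"GO:0003674"}, "b": {"GO:0005554"}, "c": {"GO:0000001"}})
        assert dv.suggest_functions([make_candidate(set("abc"))], go) == []

    def test_no_common_term_no_suggestion(self):
        go = self.go({"a": {"GO:0003674"}, "b": {"GO:0000001"}, "c": {"GO:0000002"}})
        assert dv.suggest_functions([make_candidate(set("abc"))], go) == []
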