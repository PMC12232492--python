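"""Span matching, P/R/F1, IAA and CV aggregation."""

import numpy as np
import pandas as pd
import pytest

from pdcmner.corpus import AnnotationSet, Corpus, Document, EntityMention
from pdcmner.evaluation import (
    MatchCounts,
    aggregate_cv,
    evaluate_corpus,
    f1_score,
    match_mentions,
    match_spans,
    max_matching_bruteforce,
    pairwise_iaa,
    prf,
)


def _random_mentions(rng, n, types=("biomarker", "treatment")):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, 30))
        e = s + int(rng.integers(1, 8))
        t = str(rng.choice(types))
        out.append(EntityMention(s, e, t, "x" * (e - s)))
    return out


class TestMatching:
    def test_partial_span_counts_only_in_overlap_mode(self):
        text = "patient-derived tumor xenograft (PDX) models"
        gold = [EntityMention(0, len(text), "model_type", text)]
        pred = [EntityMention(0, 37, "model_type", text[:37])]
        exact = match_mentions(gold, pred, "exact")
        assert exact.per_type["model_type"] == (0, 1, 1)
        overlap = match_mentions(gold, pred, "overlap")
        assert overlap.per_type["model_type"] == (1, 0, 0)

    def test_identical_sets_are_perfect_in_both_modes(self):
        rng = np.random.default_rng(0)
        ms = _random_mentions(rng, 5)
        for mode in ("exact", "overlap"):
            counts = match_mentions(ms, list(ms), mode)
            tp, fp, fn = counts.micro
            assert (tp, fp, fn) == (len(ms), 0, 0)

    def test_type_must_agree_in_both_modes(self):
        gold = [EntityMention(0, 3, "biomarker", "MEK")]
        pred = [EntityMention(0, 3, "treatment", "MEK")]
        for mode in ("exact", "overlap"):
            counts = match_mentions(gold, pred, mode)
            assert counts.micro == (0, 1, 1)

    def test_touching_spans_do_not_overlap(self):
        gold = [EntityMention(0, 3, "biomarker", "abc")]
        pred = [EntityMention(3, 6, "biomarker", "def")]
        assert match_spans(gold, pred, "overlap") == 0

    def test_greedy_equals_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            gold = _random_mentions(rng, int(rng.integers(0, 7)), types=("t",))
            pred = _random_mentions(rng, int(rng.integers(0, 7)), types=("t",))
            for mode in ("exact", "overlap"):
                assert match_spans(gold, pred, mode) == max_matching_bruteforce(
                    gold, pred, mode
                )


class TestPRF:
    @pytest.mark.parametrize(
        "p,r,expected",
        [(56.09, 45.89, 50.48), (76.96, 66.52, 71.36), (72.05, 71.55, 71.80)],
    )
    def test_harmonic_mean_reproduces_reported_scores(self, p, r, expected):
        assert round(f1_score(p, r), 2) == expected

    def test_zero_denominator_convention(self):
        s = prf((0, 0, 0))
        assert (s.precision, s.recall, s.f1) == (0.0, 0.0, 0.0)

    def test_f1_bounded_by_min_and_arithmetic_mean(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            tp, fp, fn = (int(x) for x in rng.integers(0, 20, size=3))
            s = prf((tp, fp, fn))
            assert min(s.precision, s.recall) - 1e-9 <= s.f1
            assert s.f1 <= (s.precision + s.recall) / 2 + 1e-9

    def test_overlap_f1_dominates_exact_f1(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            gold = _random_mentions(rng, int(rng.integers(0, 6)))
            pred = _random_mentions(rng, int(rng.integers(0, 6)))
            f1 = {
                mode: prf(match_mentions(gold, pred, mode)).f1
                for mode in ("exact", "overlap")
            }
            assert f1["overlap"] >= f1["exact"] - 1e-9


def _corpus_with(pred_by_doc):
    corpus = Corpus()
    gold = AnnotationSet("gold")
    pred = AnnotationSet("pred")
    for doc_id, (text, gms, pms) in pred_by_doc.items():
        corpus.add(Document(doc_id, text))
        gold.set_document(doc_id, gms)
        pred.set_document(doc_id, pms)
    return corpus, gold, pred


class TestEvaluateCorpus:
    def test_oracle_predictions_score_100_everywhere(self, small_corpus):
        corpus, gold, _ = small_corpus
        pred = AnnotationSet("pred", dict(gold.items()))
        report = evaluate_corpus(gold, pred, "exact")
        seen = report[report["n_gold"] > 0]
        assert (seen[["precision", "recall", "f1"]] == 100.0).all().all()

    def test_predictions_for_one_type_zero_recall_elsewhere(self):
        text = "MEK and cisplatin."
        gold_ms = [
            EntityMention(0, 3, "biomarker", "MEK"),
            EntityMention(8, 17, "treatment", "cisplatin"),
        ]
        pred_ms = [EntityMention(0, 3, "biomarker", "MEK")]
        _, gold, pred = _corpus_with({"d": (text, gold_ms, pred_ms)})
        report = evaluate_corpus(gold, pred, "exact")
        assert report.loc["biomarker", "f1"] == 100.0
        assert report.loc["treatment", "recall"] == 0.0

    def test_micro_counts_are_sums_of_per_type(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            text = "x" * 60
            gold_ms = _random_mentions(rng, 4)
            pred_ms = _random_mentions(rng, 4)
            # sanitize same-type overlaps
            ok_g, ok_p = [], []
            for m in sorted(gold_ms):
                if not any(k.type == m.type and k.overlaps(m) for k in ok_g):
                    ok_g.append(m)
            for m in sorted(pred_ms):
                if not any(k.type == m.type and k.overlaps(m) for k in ok_p):
                    ok_p.append(m)
            _, gold, pred = _corpus_with({"d": (text, ok_g, ok_p)})
            report = evaluate_corpus(gold, pred, "overlap")
            per_type = report.drop(index="micro")
            for col in ("tp", "fp", "fn", "n_gold"):
                assert report.loc["micro", col] == per_type[col].sum()

    def test_doc_coverage_mismatch_reported(self):
        _, gold, _ = _corpus_with({"d1": ("text one.", [], [])})
        pred = AnnotationSet("pred", {"d2": []})
        with pytest.raises(ValueError, match="d1"):
            evaluate_corpus(gold, pred, "exact")


class TestIAA:
    def test_identical_annotators_agree_perfectly(self, small_corpus):
        _, gold, _ = small_corpus
        a = AnnotationSet("a", dict(gold.items()))
        b = AnnotationSet("b", dict(gold.items()))
        iaa = pairwise_iaa([a, b])
        assert iaa.loc["micro", "iaa_f1"] == 100.0

    def test_pair_score_symmetric_under_role_swap(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            text = "y" * 50
            a_ms, b_ms = [], []
            for m in sorted(_random_mentions(rng, 4)):
                if not any(k.type == m.type and k.overlaps(m) for k in a_ms):
                    a_ms.append(m)
            for m in sorted(_random_mentions(rng, 4)):
                if not any(k.type == m.type and k.overlaps(m) for k in b_ms):
                    b_ms.append(m)
            a = AnnotationSet("a", {"d": a_ms})
            b = AnnotationSet("b", {"d": b_ms})
            ab = pairwise_iaa([a, b]).loc["micro", "iaa_f1"]
            ba = pairwise_iaa([b, a]).loc["micro", "iaa_f1"]
            assert ab == pytest.approx(ba)

    def test_three_annotators_mean_of_pairwise_scores(self):
        # constructed disagreements with hand-computed pairwise F1:
        # A and B agree on both mentions (F1=100); C misses one and has no
        # spurious extras: F1(A,C)=F1(B,C)=2/3*100. IAA = (100+66.67+66.67)/3.
        text = "MEK with cisplatin."
        m1 = EntityMention(0, 3, "biomarker", "MEK")
        m2 = EntityMention(9, 18, "treatment", "cisplatin")
        a = AnnotationSet("a", {"d": [m1, m2]})
        b = AnnotationSet("b", {"d": [m1, m2]})
        c = AnnotationSet("c", {"d": [m1]})
        iaa = pairwise_iaa([a, b, c]).loc["micro", "iaa_f1"]
        assert iaa == pytest.approx((100 + 200 / 3 + 200 / 3) / 3)

    def test_fewer_than_two_annotators_rejected(self):
        with pytest.raises(ValueError):
            pairwise_iaa([AnnotationSet("a")])


class TestAggregateCV:
    def _report(self, value):
        return pd.DataFrame(
            {"precision": [value], "recall": [value], "f1": [value]},
            index=pd.Index(["micro"], name="type"),
        )

    def test_identical_folds_have_zero_sd(self):
        agg = aggregate_cv([self._report(80.0)] * 5)
        assert agg.loc["micro", ("mean", "f1")] == 80.0
        assert agg.loc["micro", ("sd", "f1")] == 0.0

    def test_two_folds_closed_form(self):
        agg = aggregate_cv([self._report(40.0), self._report(60.0)])
        assert agg.loc["micro", ("mean", "f1")] == pytest.approx(50.0)
        assert agg.loc["micro", ("sd", "f1")] == pytest.approx(14.142135, abs=1e-4)

    def test_matches_direct_formula_on_random_folds(self):
        rng = np.random.default_rng(13)
        values = rng.uniform(0, 100, size=6)
        agg = aggregate_cv([self._report(v) for v in values])
        assert agg.loc["micro", ("mean", "f1")] == pytest.approx(values.mean())
        assert agg.loc["micro", ("sd", "f1")] == pytest.approx(values.std(ddof=1))

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cv([self._report(1.0)])
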