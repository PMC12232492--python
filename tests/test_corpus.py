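"""Standoff I/O, splitting and corpus statistics."""

import random

import pytest

from pdcmner.corpus import (
    AnnotationSet,
    Corpus,
    Document,
    EntityMention,
    FoldSpec,
    SplitSpec,
    StandoffError,
    corpus_stats,
    make_folds,
    read_jsonl,
    read_standoff,
    split_corpus,
    write_jsonl,
    write_standoff,
    _largest_remainder_sizes,
)
from pdcmner.synthetic import GeneratorConfig, generate_corpus

from conftest import ALK_SENTENCE


class TestMentionInvariants:
    def test_surface_text_checked_against_document(self):
        m = EntityMention(48, 51, "biomarker", "ALK")
        m.validate(ALK_SENTENCE)  # offsets match the substring
        with pytest.raises(StandoffError):
            EntityMention(48, 51, "biomarker", "XYZ").validate(ALK_SENTENCE)

    def test_degenerate_spans_rejected(self):
        with pytest.raises(ValueError):
            EntityMention(5, 5, "biomarker", "")
        with pytest.raises(ValueError):
            EntityMention(-1, 3, "biomarker", "abc")

    def test_same_type_overlap_rejected_cross_type_allowed(self):
        text = "Treated with MEK inhibitor therapy."
        aset = AnnotationSet("a")
        aset.set_document(
            "d1",
            [
                EntityMention(13, 26, "treatment", "MEK inhibitor"),
                EntityMention(13, 16, "biomarker", "MEK"),
            ],
        )
        with pytest.raises(StandoffError):
            aset.set_document(
                "d1",
                [
                    EntityMention(13, 26, "treatment", "MEK inhibitor"),
                    EntityMention(13, 16, "treatment", "MEK"),
                ],
            )


class TestBratIO:
    def test_t_line_parsed_to_offset_mention(self):
        doc, aset = read_standoff(
            ALK_SENTENCE, "T1\tbiomarker 48 51\tALK\n", doc_id="ex1"
        )
        assert aset.mentions_for("ex1") == [EntityMention(48, 51, "biomarker", "ALK")]

    def test_empty_ann_gives_zero_mentions(self):
        _, aset = read_standoff(ALK_SENTENCE, "", doc_id="ex1")
        assert len(aset) == 0

    def test_serialization_matches_brat_shape(self):
        doc = Document("ex1", ALK_SENTENCE)
        aset = AnnotationSet("gold", {"ex1": [EntityMention(48, 51, "biomarker", "ALK")]})
        assert write_standoff(doc, aset, "brat") == "T1\tbiomarker 48 51\tALK\n"

    def test_no_mentions_serializes_to_empty_body(self):
        doc = Document("ex1", ALK_SENTENCE)
        assert write_standoff(doc, AnnotationSet("gold", {"ex1": []}), "brat") == ""

    @pytest.mark.parametrize(
        "bad_line",
        [
            "T1\tbiomarker 48 300\tALK",          # out of range
            "T1\tbiomarker 48 51\tXYZ",           # surface mismatch
            "T1\tmystery_type 48 51\tALK",        # unknown type
            "T1\tbiomarker 48 50;60 62\tALK",     # discontinuous span
        ],
    )
    def test_malformed_annotations_rejected(self, bad_line):
        with pytest.raises(StandoffError):
            read_standoff(ALK_SENTENCE, bad_line, doc_id="ex1")

    def test_unknown_type_accepted_when_allowed(self):
        _, aset = read_standoff(
            ALK_SENTENCE, "T1\tmystery_type 48 51\tALK", doc_id="ex1",
            allow_unknown_types=True,
        )
        assert aset.mentions_for("ex1")[0].type == "mystery_type"

    def test_brat_round_trip_is_identity(self, small_corpus):
        corpus, gold, _ = small_corpus
        for doc in corpus:
            serialized = write_standoff(doc, gold, "brat")
            _, reread = read_standoff(doc.text, serialized, doc_id=doc.doc_id)
            assert reread.mentions_for(doc.doc_id) == gold.mentions_for(doc.doc_id)
            # second cycle is byte-identical (idempotence)
            again = write_standoff(doc, reread, "brat")
            assert again == serialized


class TestJsonlIO:
    def test_round_trip_is_identity(self, small_corpus):
        corpus, gold, _ = small_corpus
        payload = write_jsonl(corpus, [gold])
        corpus2, sets = read_jsonl(payload)
        assert corpus2.doc_ids == corpus.doc_ids
        assert sets["gold"] == gold
        assert write_jsonl(corpus2, [sets["gold"]]) == payload

    def test_multiple_sources_preserved(self, small_corpus):
        corpus, gold, _ = small_corpus
        other = AnnotationSet("annotator2", {d: [] for d in corpus.doc_ids})
        _, sets = read_jsonl(write_jsonl(corpus, [gold, other]))
        assert set(sets) == {"gold", "annotator2"}


class TestSplitting:
    def test_standard_ratio_on_100_documents(self):
        corpus = Corpus(Document(f"d{i:03d}", "x. y.") for i in range(100))
        parts = split_corpus(corpus, SplitSpec((60, 20, 20), seed=1))
        assert (len(parts["train"]), len(parts["dev"]), len(parts["test"])) == (60, 20, 20)

    def test_split_is_deterministic_and_seed_sensitive(self):
        corpus = Corpus(Document(f"d{i}", "t.") for i in range(10))
        a = split_corpus(corpus, SplitSpec(seed=5))
        b = split_corpus(corpus, SplitSpec(seed=5))
        c = split_corpus(corpus, SplitSpec(seed=6))
        assert a == b
        assert a != c

    def test_split_is_a_partition(self):
        corpus = Corpus(Document(f"d{i}", "t.") for i in range(37))
        parts = split_corpus(corpus, SplitSpec(seed=0))
        ids = parts["train"] + parts["dev"] + parts["test"]
        assert sorted(ids) == sorted(corpus.doc_ids)
        assert len(set(ids)) == len(ids)

    def test_tiny_corpus_rejected(self):
        corpus = Corpus([Document("a", "t."), Document("b", "t.")])
        with pytest.raises(ValueError):
            split_corpus(corpus, SplitSpec())

    def test_largest_remainder_within_one_of_exact(self):
        rng = random.Random(0)
        for _ in range(1000):
            n = rng.randint(3, 5000)
            sizes = _largest_remainder_sizes(n, (60, 20, 20))
            assert sum(sizes) == n
            for s, r in zip(sizes, (60, 20, 20)):
                assert abs(s - n * r / 100) < 1

    def test_ratio_invariants(self):
        with pytest.raises(ValueError):
            SplitSpec((50, 30, 30))
        with pytest.raises(ValueError):
            SplitSpec((100, -10, 10))


class TestFolds:
    def test_five_folds_cover_97_of_100(self):
        corpus = Corpus(Document(f"d{i:03d}", "t.") for i in range(100))
        excluded = ("d000", "d001", "d002")
        folds = make_folds(corpus, FoldSpec((20, 20, 20, 20, 17), excluded, seed=0))
        assert [len(f) for f in folds] == [20, 20, 20, 20, 17]
        covered = sorted(d for f in folds for d in f)
        assert len(covered) == 97
        assert set(covered) | set(excluded) == set(corpus.doc_ids)

    def test_single_fold_is_whole_corpus(self):
        corpus = Corpus(Document(f"d{i}", "t.") for i in range(7))
        folds = make_folds(corpus, FoldSpec((7,), (), seed=0))
        assert sorted(folds[0]) == sorted(corpus.doc_ids)

    def test_size_mismatch_reported(self):
        corpus = Corpus(Document(f"d{i}", "t.") for i in range(10))
        with pytest.raises(ValueError, match="fold sizes"):
            make_folds(corpus, FoldSpec((5, 4), (), seed=0))

    def test_random_configurations_partition(self):
        rng = random.Random(2)
        for _ in range(50):
            n = rng.randint(5, 60)
            corpus = Corpus(Document(f"d{i}", "t.") for i in range(n))
            k = rng.randint(1, min(4, n - 1))
            excluded = tuple(rng.sample(corpus.doc_ids, k))
            remaining = n - k
            n_folds = rng.randint(1, min(5, remaining))
            base = remaining // n_folds
            sizes = tuple(
                base + (1 if i < remaining % n_folds else 0) for i in range(n_folds)
            )
            folds = make_folds(corpus, FoldSpec(sizes, excluded, seed=rng.randint(0, 99)))
            covered = [d for f in folds for d in f]
            assert len(covered) == len(set(covered)) == remaining
            assert set(covered) | set(excluded) == set(corpus.doc_ids)


class TestCorpusStats:
    def test_planted_counts_match_ledger(self, small_corpus):
        corpus, gold, ledger = small_corpus
        table = corpus_stats(corpus, gold)
        for t, n in ledger.items():
            assert table.loc[t, "all"] == n
        assert table.loc["total", "all"] == len(gold)

    def test_empty_annotation_set_gives_zero_table(self, small_corpus):
        corpus, _, _ = small_corpus
        empty = AnnotationSet("none", {d: [] for d in corpus.doc_ids})
        table = corpus_stats(corpus, empty)
        assert (table.to_numpy() == 0).all()

    def test_row_totals_equal_sum_of_split_cells(self):
        corpus, gold, _ = generate_corpus(GeneratorConfig(n_documents=12, seed=9))
        split = split_corpus(corpus, SplitSpec(seed=4))
        table = corpus_stats(corpus, gold, split)
        assert (
            table[["train", "dev", "test"]].sum(axis=1) == table["total"]
        ).all()
        grand = table.loc["total", "total"]
        assert grand == table.drop(index="total")["total"].sum() == len(gold)
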