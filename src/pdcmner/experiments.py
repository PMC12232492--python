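"""Experiment protocols: held-out evaluation, k-fold cross-validation with
mean +/- SD aggregation, and the learning curve over training-data
fractions.

Two system kinds are orchestrated.  A *direct* system wraps a generation
provider plus a prompt template and has no trainable state, so
cross-validation simply evaluates it fold by fold.  A *soft* system
retrains the soft prompt on the complement of each test fold.  Learning
curves subsample training data by whole abstracts (never by sentence, to
avoid leakage), retrain at each fraction, and evaluate on a fixed test
split in overlapping-match mode.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .backbone import TinyTransformerBackbone
from .bio_codec import BioLabelScheme
from .corpus import AnnotationSet, Corpus, FoldSpec, make_folds, write_jsonl
from .evaluation import aggregate_cv, evaluate_corpus
from .prompt_direct import GenerationProvider, PromptTemplate, annotate_corpus
from .segmenter import project_mentions, restore_mentions, segment
from .soft_prompt import (
    SentenceExample,
    SoftPromptState,
    TrainConfig,
    extract_entities,
    make_examples,
    train_soft_prompt,
)

__all__ = [
    "DirectSystem",
    "SoftSystem",
    "RunManifest",
    "doc_examples",
    "predict_annotation_set",
    "run_cross_validation",
    "run_learning_curve",
]


@dataclass
class DirectSystem:
    provider: GenerationProvider
    template: PromptTemplate
    kind: str = "direct"


@dataclass
class SoftSystem:
    backbone: TinyTransformerBackbone
    config: TrainConfig
    scheme: BioLabelScheme
    kind: str = "soft"


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically."""

    protocol: str
    seeds: dict[str, int]
    config: dict
    input_fingerprints: dict[str, str]
    timings_s: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def corpus_fingerprint(corpus: Corpus, gold: AnnotationSet) -> str:
    payload = write_jsonl(corpus, [gold])
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def doc_examples(
    corpus: Corpus,
    gold: AnnotationSet,
    doc_ids: Sequence[str],
    scheme: BioLabelScheme,
) -> list[SentenceExample]:
    """Sentence-level training examples for a set of documents."""
    pairs = []
    for doc_id in doc_ids:
        doc = corpus[doc_id]
        sentences = segment(doc)
        by_sent, _ = project_mentions(doc, sentences, gold.mentions_for(doc_id))
        for s in sentences:
            pairs.append((s.text, by_sent[s.sent_index]))
    return make_examples(pairs, scheme)


def predict_annotation_set(
    state: SoftPromptState,
    backbone: TinyTransformerBackbone,
    corpus: Corpus,
    doc_ids: Sequence[str],
    *,
    source_id: str = "soft-prompt",
) -> AnnotationSet:
    """Run the trained soft-prompt extractor over whole documents."""
    pred = AnnotationSet(source_id)
    for doc_id in doc_ids:
        doc = corpus[doc_id]
        mentions = []
        for s in segment(doc):
            local = extract_entities(state, backbone, s.text)
            mentions.extend(restore_mentions(s, local))
        pred.set_document(doc_id, mentions)
    return pred


def _fold_predictions(
    system: DirectSystem | SoftSystem,
    corpus: Corpus,
    gold: AnnotationSet,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
) -> AnnotationSet:
    if isinstance(system, DirectSystem):
        pred, _report = annotate_corpus(
            system.provider, system.template, corpus.subset(test_ids)
        )
        return pred
    train_examples = doc_examples(corpus, gold, train_ids, system.scheme)
    state, _log = train_soft_prompt(
        system.backbone, train_examples, [], system.config, scheme=system.scheme
    )
    return predict_annotation_set(state, system.backbone, corpus, test_ids)


def run_cross_validation(
    corpus: Corpus,
    gold: AnnotationSet,
    system: DirectSystem | SoftSystem,
    fold_spec: FoldSpec,
    modes: Sequence[str] = ("exact", "overlap"),
) -> dict:
    """Per-fold reports and mean/SD aggregates for each evaluation mode.

    Soft systems are retrained on the other folds for every test fold;
    direct systems are evaluated fold by fold without any training.
    """
    folds = make_folds(corpus, fold_spec)
    per_fold: dict[str, list[pd.DataFrame]] = {m: [] for m in modes}
    t0 = time.perf_counter()
    for i, test_ids in enumerate(folds):
        train_ids = [d for j, f in enumerate(folds) if j != i for d in f]
        pred = _fold_predictions(system, corpus, gold, train_ids, test_ids)
        gold_fold = gold.restricted_to(test_ids)
        for d in test_ids:  # ensure coverage even for unannotated docs
            if d not in gold_fold.doc_ids:
                gold_fold.set_document(d, [])
        for mode in modes:
            per_fold[mode].append(evaluate_corpus(gold_fold, pred, mode))
    aggregates = {m: aggregate_cv(reports) for m, reports in per_fold.items()}
    manifest = RunManifest(
        protocol="cross-validation",
        seeds={"fold_seed": fold_spec.seed},
        config={
            "system": system.kind,
            "fold_sizes": list(fold_spec.sizes),
            "excluded": list(fold_spec.excluded_doc_ids),
            "modes": list(modes),
        },
        input_fingerprints={"corpus": corpus_fingerprint(corpus, gold)},
        timings_s={"total": round(time.perf_counter() - t0, 3)},
    )
    return {"per_fold": per_fold, "aggregate": aggregates, "folds": folds,
            "manifest": manifest}


def run_learning_curve(
    corpus: Corpus,
    gold: AnnotationSet,
    system: SoftSystem,
    train_doc_ids: Sequence[str],
    test_doc_ids: Sequence[str],
    fractions: Sequence[float] = (0.05, 0.25, 0.5, 1.0),
    seeds: Sequence[int] = (0, 1),
) -> pd.DataFrame:
    """Mean overlap micro-F1 on a fixed test split per training fraction.

    Subsampling is by whole abstracts with a seeded draw; fraction 1.0
    uses the full training set and so reproduces the plain training run.
    """
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"fractions must be in (0, 1]: {f}")
        if int(round(f * len(train_doc_ids))) < 1:
            raise ValueError(f"fraction {f} yields zero training abstracts")
    test_gold = gold.restricted_to(test_doc_ids)
    rows = []
    for frac in fractions:
        n = max(1, int(round(frac * len(train_doc_ids))))
        for seed in seeds:
            rng = np.random.default_rng(seed)
            sample = sorted(rng.choice(list(train_doc_ids), size=n, replace=False))
            examples = doc_examples(corpus, gold, sample, system.scheme)
            state, _ = train_soft_prompt(
                system.backbone, examples, [], system.config, scheme=system.scheme
            )
            pred = predict_annotation_set(state, system.backbone, corpus, test_doc_ids)
            report = evaluate_corpus(test_gold, pred, "overlap")
            rows.append(
                {"fraction": frac, "seed": seed, "n_abstracts": n,
                 "f1": report.loc["micro", "f1"]}
            )
    df = pd.DataFrame(rows)
    means = df.groupby("fraction", sort=True)["f1"].mean().rename("mean_f1")
    return df.merge(means, on="fraction")
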