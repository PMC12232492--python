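"""Span-level scoring: exact and overlapping match, micro/per-type P/R/F1,
pairwise-F1 inter-annotator agreement, and cross-validation aggregation.

Two evaluation settings are supported.  *Exact match* credits a prediction
only when its span boundaries and type equal a gold mention's.
*Overlapping match* gives partial credit when a predicted span of the
correct type shares at least one character with a gold span (half-open
intervals; touching spans do not match).  Matching is one-to-one: each
gold and each predicted mention is used at most once, and the pairing
maximizes the number of true positives.

All scores are on the 0-100 scale.  Zero denominators yield 0 by
convention (this matters for rare types with no test instances).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import AnnotationSet, EntityMention
from .registry import DEFAULT_TYPE_NAMES, registry_index

__all__ = [
    "MatchCounts",
    "PRF",
    "match_spans",
    "match_mentions",
    "max_matching_bruteforce",
    "prf",
    "f1_score",
    "evaluate_corpus",
    "pairwise_iaa",
    "aggregate_cv",
]

MODES = ("exact", "overlap")


@dataclass
class MatchCounts:
    """TP/FP/FN tallies per type plus pooled (micro) totals."""

    per_type: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def add(self, type_name: str, tp: int, fp: int, fn: int) -> None:
        a, b, c = self.per_type.get(type_name, (0, 0, 0))
        self.per_type[type_name] = (a + tp, b + fp, c + fn)

    def merge(self, other: "MatchCounts") -> None:
        for t, (tp, fp, fn) in other.per_type.items():
            self.add(t, tp, fp, fn)

    @property
    def micro(self) -> tuple[int, int, int]:
        tp = sum(v[0] for v in self.per_type.values())
        fp = sum(v[1] for v in self.per_type.values())
        fn = sum(v[2] for v in self.per_type.values())
        return tp, fp, fn


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "PRF":
        p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        return cls(p, r, f1_score(p, r))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same scale as its inputs)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def prf(counts: MatchCounts | tuple[int, int, int]) -> PRF:
    """P/R/F1 on the 0-100 scale from pooled counts."""
    if isinstance(counts, MatchCounts):
        tp, fp, fn = counts.micro
    else:
        tp, fp, fn = counts
    return PRF.from_counts(tp, fp, fn)


def _compatible(g: EntityMention, p: EntityMention, mode: str) -> bool:
    if mode == "exact":
        return g.start == p.start and g.end == p.end
    if mode == "overlap":
        return g.start < p.end and p.start < g.end
    raise ValueError(f"unknown mode {mode!r}")


def match_spans(
    gold: Sequence[EntityMention], pred: Sequence[EntityMention], mode: str
) -> int:
    """Number of one-to-one (gold, pred) matches for mentions of ONE type.

    Greedy left-to-right: predictions are processed in order of (end,
    start); each takes the unmatched compatible gold with the smallest
    end.  For interval compatibility (shared character, or identity) this
    earliest-endpoint rule attains the maximum matching; it is checked
    against :func:`max_matching_bruteforce` in the test suite.
    """
    golds = sorted(gold, key=lambda m: (m.end, m.start))
    used = [False] * len(golds)
    tp = 0
    for p in sorted(pred, key=lambda m: (m.end, m.start)):
        for i, g in enumerate(golds):
            if not used[i] and _compatible(g, p, mode):
                used[i] = True
                tp += 1
                break
    return tp


def max_matching_bruteforce(
    gold: Sequence[EntityMention], pred: Sequence[EntityMention], mode: str
) -> int:
    """Exhaustive maximum one-to-one matching size (oracle; small inputs only)."""

    def best(gi: int, used_pred: int) -> int:
        if gi == len(gold):
            return 0
        # gold[gi] unmatched
        result = best(gi + 1, used_pred)
        for pi, p in enumerate(pred):
            if used_pred & (1 << pi):
                continue
            if _compatible(gold[gi], p, mode):
                result = max(result, 1 + best(gi + 1, used_pred | (1 << pi)))
        return result

    return best(0, 0)


def match_mentions(
    gold: Iterable[EntityMention], pred: Iterable[EntityMention], mode: str
) -> MatchCounts:
    """Per-type and micro TP/FP/FN for one document or sentence.

    Types must agree in both modes; matching runs independently per type.
    """
    gold_by_type: dict[str, list[EntityMention]] = {}
    pred_by_type: dict[str, list[EntityMention]] = {}
    for m in gold:
        gold_by_type.setdefault(m.type, []).append(m)
    for m in pred:
        pred_by_type.setdefault(m.type, []).append(m)
    counts = MatchCounts()
    for t in sorted(set(gold_by_type) | set(pred_by_type)):
        g = gold_by_type.get(t, [])
        p = pred_by_type.get(t, [])
        tp = match_spans(g, p, mode)
        counts.add(t, tp, len(p) - tp, len(g) - tp)
    return counts


def corpus_counts(
    gold_set: AnnotationSet, pred_set: AnnotationSet, mode: str
) -> MatchCounts:
    gold_docs = set(gold_set.doc_ids)
    pred_docs = set(pred_set.doc_ids)
    if gold_docs != pred_docs:
        diff = sorted(gold_docs.symmetric_difference(pred_docs))
        raise ValueError(f"gold/pred document coverage differs: {diff}")
    counts = MatchCounts()
    for doc_id in sorted(gold_docs):
        counts.merge(
            match_mentions(gold_set.mentions_for(doc_id), pred_set.mentions_for(doc_id), mode)
        )
    return counts


def evaluate_corpus(
    gold_set: AnnotationSet,
    pred_set: AnnotationSet,
    mode: str,
) -> pd.DataFrame:
    """Per-type rows plus a micro row: n_gold, precision, recall, F1.

    Rows follow registry order (unknown types appended alphabetically);
    scores are stored at full precision and rounded only for display.
    """
    counts = corpus_counts(gold_set, pred_set, mode)
    rows = []
    for t in DEFAULT_TYPE_NAMES:
        if t not in counts.per_type:
            counts.per_type[t] = (0, 0, 0)
    types = sorted(counts.per_type, key=lambda t: (registry_index(t), t))
    for t in types:
        tp, fp, fn = counts.per_type[t]
        s = PRF.from_counts(tp, fp, fn)
        rows.append(
            {"type": t, "n_gold": tp + fn, "tp": tp, "fp": fp, "fn": fn,
             "precision": s.precision, "recall": s.recall, "f1": s.f1}
        )
    tp, fp, fn = counts.micro
    s = PRF.from_counts(tp, fp, fn)
    rows.append(
        {"type": "micro", "n_gold": tp + fn, "tp": tp, "fp": fp, "fn": fn,
         "precision": s.precision, "recall": s.recall, "f1": s.f1}
    )
    return pd.DataFrame(rows).set_index("type")


def pairwise_iaa(annotation_sets: Sequence[AnnotationSet]) -> pd.DataFrame:
    """Inter-annotator agreement: mean pairwise F1 under exact matching.

    For each unordered annotator pair, F1 is computed with one member as
    reference (the score is symmetric under role swap); the reported IAA
    is the unweighted mean over all k(k-1)/2 pairs, per type and micro.
    """
    if len(annotation_sets) < 2:
        raise ValueError("IAA needs at least 2 annotators")
    per_pair: list[pd.DataFrame] = []
    for a, b in combinations(annotation_sets, 2):
        common = sorted(set(a.doc_ids) | set(b.doc_ids))
        a_full = AnnotationSet(a.source_id, {d: a.mentions_for(d) for d in common})
        b_full = AnnotationSet(b.source_id, {d: b.mentions_for(d) for d in common})
        per_pair.append(evaluate_corpus(a_full, b_full, "exact")[["f1"]])
    merged = pd.concat(per_pair, axis=1).fillna(0.0)
    return pd.DataFrame({"iaa_f1": merged.mean(axis=1)})


def aggregate_cv(per_fold_reports: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) per cell across fold reports."""
    if len(per_fold_reports) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    cols = ["precision", "recall", "f1"]
    stacked = pd.concat([r[cols] for r in per_fold_reports], keys=range(len(per_fold_reports)))
    grouped = stacked.groupby(level=1, sort=False)
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    out = pd.concat({"mean": mean, "sd": sd}, axis=1)
    # preserve the row order of the first report
    return out.loc[per_fold_reports[0].index]
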