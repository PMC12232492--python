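"""Documents, typed entity mentions, standoff annotation I/O and splitting.

Annotations are *standoff*: each mention is a half-open character interval
``[start, end)`` into the raw abstract text, together with its entity type
and surface string.  The surface string is stored redundantly and checked
against the document substring on every construction, which catches offset
drift early (a classic failure mode when text is re-encoded or trimmed).

Two on-disk dialects are supported: brat ``.txt``/``.ann`` pairs (T-lines
only) for interoperability, and a JSON-lines dialect (one object per
document) as the primary format.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .registry import DEFAULT_TYPE_NAMES, registry_index

__all__ = [
    "EntityMention",
    "Document",
    "Corpus",
    "AnnotationSet",
    "SplitSpec",
    "FoldSpec",
    "StandoffError",
    "read_standoff",
    "write_standoff",
    "read_jsonl",
    "write_jsonl",
    "split_corpus",
    "make_folds",
    "corpus_stats",
]


class StandoffError(ValueError):
    """Malformed or inconsistent standoff annotation input."""


@dataclass(frozen=True, order=True)
class EntityMention:
    """A typed character span; offsets are 0-based, half-open."""

    start: int
    end: int
    type: str
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    def validate(self, doc_text: str, *, doc_id: str = "?") -> None:
        if self.end > len(doc_text):
            raise StandoffError(
                f"{doc_id}: span ({self.start}, {self.end}) exceeds text length {len(doc_text)}"
            )
        actual = doc_text[self.start : self.end]
        if actual != self.text:
            raise StandoffError(
                f"{doc_id}: surface text {self.text!r} does not match document "
                f"substring {actual!r} at ({self.start}, {self.end})"
            )

    def overlaps(self, other: "EntityMention") -> bool:
        return self.start < other.end and other.start < self.end

    def shifted(self, delta: int) -> "EntityMention":
        return EntityMention(self.start + delta, self.end + delta, self.type, self.text)


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not self.text:
            raise ValueError(f"{self.doc_id}: document text must be non-empty")


class Corpus:
    """An ordered collection of documents with unique ids."""

    def __init__(self, documents: Iterable[Document] = ()):
        self._docs: dict[str, Document] = {}
        for doc in documents:
            self.add(doc)

    def add(self, doc: Document) -> None:
        if doc.doc_id in self._docs:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
        self._docs[doc.doc_id] = doc

    def __len__(self) -> int:
        return len(self._docs)

    def __iter__(self) -> Iterator[Document]:
        return iter(self._docs.values())

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._docs

    def __getitem__(self, doc_id: str) -> Document:
        return self._docs[doc_id]

    @property
    def doc_ids(self) -> list[str]:
        return list(self._docs)

    def subset(self, doc_ids: Iterable[str]) -> "Corpus":
        return Corpus(self._docs[d] for d in doc_ids)


def _check_same_type_overlaps(mentions: list[EntityMention], doc_id: str) -> None:
    by_type: dict[str, list[EntityMention]] = {}
    for m in mentions:
        by_type.setdefault(m.type, []).append(m)
    for t, ms in by_type.items():
        ms = sorted(ms, key=lambda m: (m.start, m.end))
        for a, b in zip(ms, ms[1:]):
            if a.overlaps(b):
                raise StandoffError(
                    f"{doc_id}: overlapping mentions of the same type {t!r}: "
                    f"({a.start},{a.end}) and ({b.start},{b.end})"
                )


class AnnotationSet:
    """All mentions for a corpus from one source (an annotator or a system).

    Mentions of *different* types may overlap (e.g. biomarker "MEK" inside
    treatment "MEK inhibitor"); same-type overlaps are rejected.
    """

    def __init__(
        self,
        source_id: str,
        mentions: Mapping[str, Iterable[EntityMention]] | None = None,
    ):
        self.source_id = source_id
        self._mentions: dict[str, list[EntityMention]] = {}
        if mentions:
            for doc_id, ms in mentions.items():
                self.set_document(doc_id, ms)

    def set_document(self, doc_id: str, mentions: Iterable[EntityMention]) -> None:
        ms = sorted(mentions, key=lambda m: (m.start, m.end, m.type))
        _check_same_type_overlaps(ms, doc_id)
        self._mentions[doc_id] = ms

    def add(self, doc_id: str, mention: EntityMention) -> None:
        self.set_document(doc_id, self._mentions.get(doc_id, []) + [mention])

    def mentions_for(self, doc_id: str) -> list[EntityMention]:
        return list(self._mentions.get(doc_id, []))

    @property
    def doc_ids(self) -> list[str]:
        return list(self._mentions)

    def __len__(self) -> int:
        return sum(len(v) for v in self._mentions.values())

    def items(self) -> Iterator[tuple[str, list[EntityMention]]]:
        return iter((k, list(v)) for k, v in self._mentions.items())

    def validate_against(self, corpus: Corpus) -> None:
        for doc_id, ms in self._mentions.items():
            if doc_id not in corpus:
                raise StandoffError(
                    f"annotation source {self.source_id!r} references unknown doc {doc_id!r}"
                )
            for m in ms:
                m.validate(corpus[doc_id].text, doc_id=doc_id)

    def restricted_to(self, doc_ids: Iterable[str]) -> "AnnotationSet":
        keep = set(doc_ids)
        return AnnotationSet(
            self.source_id,
            {d: ms for d, ms in self._mentions.items() if d in keep},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self._mentions == other._mentions


@dataclass(frozen=True)
class SplitSpec:
    """Train/dev/test ratios as integers summing to 100, plus a shuffle seed."""

    ratios: tuple[int, int, int] = (60, 20, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be three positive integers")
        if sum(self.ratios) != 100:
            raise ValueError(f"ratios must sum to 100, got {sum(self.ratios)}")


@dataclass(frozen=True)
class FoldSpec:
    """Cross-validation fold sizes over the corpus minus excluded documents."""

    sizes: tuple[int, ...] = (20, 20, 20, 20, 17)
    excluded_doc_ids: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sizes or any(s <= 0 for s in self.sizes):
            raise ValueError("fold sizes must be positive")


# ---------------------------------------------------------------------------
# standoff I/O


def _parse_brat_lines(
    lines: Iterable[str],
    text: str,
    doc_id: str,
    *,
    allow_unknown_types: bool = False,
) -> list[EntityMention]:
    mentions = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if not line.startswith("T"):
            # brat relation/event/note lines are out of scope; skip silently
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise StandoffError(f"{doc_id}:{lineno}: malformed T-line {line!r}")
        span_part, surface = parts[1], parts[2]
        if ";" in span_part:
            raise StandoffError(
                f"{doc_id}:{lineno}: discontinuous spans are unsupported: {line!r}"
            )
        fields = span_part.split()
        if len(fields) != 3:
            raise StandoffError(f"{doc_id}:{lineno}: malformed span field {span_part!r}")
        type_name, start_s, end_s = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise StandoffError(f"{doc_id}:{lineno}: non-integer offsets") from exc
        if not allow_unknown_types and type_name not in DEFAULT_TYPE_NAMES:
            raise StandoffError(f"{doc_id}:{lineno}: unknown entity type {type_name!r}")
        if not (0 <= start < end <= len(text)):
            raise StandoffError(
                f"{doc_id}:{lineno}: offsets ({start}, {end}) out of range for "
                f"text of length {len(text)}"
            )
        m = EntityMention(start, end, type_name, surface)
        m.validate(text, doc_id=f"{doc_id}:{lineno}")
        mentions.append(m)
    return mentions


def read_standoff(
    text_source: str | Path,
    ann_source: str | Path,
    *,
    doc_id: str | None = None,
    source_id: str = "gold",
    allow_unknown_types: bool = False,
) -> tuple[Document, AnnotationSet]:
    """Read a brat ``.txt`` + ``.ann`` pair.

    ``text_source``/``ann_source`` may be paths or raw content strings
    (a string containing a newline or not ending in ``.txt``/``.ann`` is
    treated as content).
    """

    def _load(src: str | Path, suffixes: tuple[str, ...]) -> tuple[str, str | None]:
        if isinstance(src, Path) or (
            "\n" not in str(src) and str(src).endswith(suffixes)
        ):
            p = Path(src)
            return p.read_text(encoding="utf-8"), p.stem
        return str(src), None

    text, stem = _load(text_source, (".txt",))
    ann, _ = _load(ann_source, (".ann",))
    did = doc_id or stem or "doc"
    doc = Document(did, text)
    mentions = _parse_brat_lines(
        ann.splitlines(), text, did, allow_unknown_types=allow_unknown_types
    )
    aset = AnnotationSet(source_id, {did: mentions} if mentions else {did: []})
    return doc, aset


def write_standoff(
    document: Document,
    annotation_set: AnnotationSet,
    dialect: str = "brat",
) -> str:
    """Serialize one document's annotations; ``dialect`` is brat or jsonl."""
    mentions = sorted(
        annotation_set.mentions_for(document.doc_id),
        key=lambda m: (m.start, m.end, m.type),
    )
    if dialect == "brat":
        lines = [
            f"T{i}\t{m.type} {m.start} {m.end}\t{m.text}"
            for i, m in enumerate(mentions, start=1)
        ]
        return "\n".join(lines) + ("\n" if lines else "")
    if dialect == "jsonl":
        obj = {
            "doc_id": document.doc_id,
            "text": document.text,
            "annotations": {
                annotation_set.source_id: [
                    {"start": m.start, "end": m.end, "type": m.type, "text": m.text}
                    for m in mentions
                ]
            },
        }
        return json.dumps(obj, ensure_ascii=False) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


def write_jsonl(
    corpus: Corpus,
    annotation_sets: Iterable[AnnotationSet] = (),
    path: str | Path | None = None,
) -> str:
    """Serialize a corpus (documents + any number of sources) to JSON lines."""
    sets = list(annotation_sets)
    out_lines = []
    for doc in corpus:
        obj = {
            "doc_id": doc.doc_id,
            "text": doc.text,
            "annotations": {
                s.source_id: [
                    {"start": m.start, "end": m.end, "type": m.type, "text": m.text}
                    for m in s.mentions_for(doc.doc_id)
                ]
                for s in sets
            },
        }
        out_lines.append(json.dumps(obj, ensure_ascii=False))
    payload = "\n".join(out_lines) + ("\n" if out_lines else "")
    if path is not None:
        Path(path).write_text(payload, encoding="utf-8")
    return payload


def read_jsonl(
    source: str | Path,
    *,
    allow_unknown_types: bool = False,
) -> tuple[Corpus, dict[str, AnnotationSet]]:
    """Read a JSON-lines corpus; returns (corpus, {source_id: AnnotationSet})."""
    if isinstance(source, Path) or ("\n" not in str(source) and str(source).endswith(".jsonl")):
        content = Path(source).read_text(encoding="utf-8")
    else:
        content = str(source)
    corpus = Corpus()
    sets: dict[str, AnnotationSet] = {}
    for lineno, line in enumerate(content.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise StandoffError(f"line {lineno}: invalid JSON") from exc
        doc = Document(obj["doc_id"], obj["text"])
        corpus.add(doc)
        for source_id, raw in obj.get("annotations", {}).items():
            mentions = []
            for r in raw:
                if not allow_unknown_types and r["type"] not in DEFAULT_TYPE_NAMES:
                    raise StandoffError(
                        f"{doc.doc_id}: unknown entity type {r['type']!r}"
                    )
                m = EntityMention(r["start"], r["end"], r["type"], r["text"])
                m.validate(doc.text, doc_id=doc.doc_id)
                mentions.append(m)
            sets.setdefault(source_id, AnnotationSet(source_id)).set_document(
                doc.doc_id, mentions
            )
    return corpus, sets


# ---------------------------------------------------------------------------
# splitting


def _largest_remainder_sizes(n: int, ratios: tuple[int, ...]) -> list[int]:
    """Apportion n items to ratio buckets; ties by bucket position."""
    total = sum(ratios)
    exact = [n * r / total for r in ratios]
    sizes = [int(e) for e in exact]
    remainder = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def split_corpus(corpus: Corpus, spec: SplitSpec) -> dict[str, list[str]]:
    """Deterministic shuffled train/dev/test split by document."""
    n = len(corpus)
    if n < 3:
        raise ValueError(f"corpus has {n} documents; need at least 3 to split")
    ids = sorted(corpus.doc_ids)
    random.Random(spec.seed).shuffle(ids)
    sizes = _largest_remainder_sizes(n, spec.ratios)
    train = ids[: sizes[0]]
    dev = ids[sizes[0] : sizes[0] + sizes[1]]
    test = ids[sizes[0] + sizes[1] :]
    return {"train": train, "dev": dev, "test": test}


def make_folds(corpus: Corpus, spec: FoldSpec) -> list[list[str]]:
    """Disjoint, exhaustive folds of the requested sizes after exclusions."""
    excluded = set(spec.excluded_doc_ids)
    missing = excluded - set(corpus.doc_ids)
    if missing:
        raise ValueError(f"excluded doc_ids not in corpus: {sorted(missing)}")
    ids = sorted(d for d in corpus.doc_ids if d not in excluded)
    if sum(spec.sizes) != len(ids):
        raise ValueError(
            f"fold sizes sum to {sum(spec.sizes)} but corpus has {len(ids)} "
            f"documents after excluding {len(excluded)}"
        )
    random.Random(spec.seed).shuffle(ids)
    folds, pos = [], 0
    for s in spec.sizes:
        folds.append(ids[pos : pos + s])
        pos += s
    return folds


def corpus_stats(
    corpus: Corpus,
    annotation_set: AnnotationSet,
    split_assignment: Mapping[str, Iterable[str]] | None = None,
):
    """Per-type x per-split mention count table with row/column totals.

    Returns a pandas DataFrame indexed by entity type (registry order, then
    any extra types alphabetically, then a ``total`` row) with one column
    per split plus a ``total`` column.
    """
    import pandas as pd

    if split_assignment is None:
        split_assignment = {"all": corpus.doc_ids}
    split_of: dict[str, str] = {}
    for split, doc_ids in split_assignment.items():
        for d in doc_ids:
            split_of[d] = split
    seen_types = {m.type for _, ms in annotation_set.items() for m in ms}
    types = [t for t in DEFAULT_TYPE_NAMES] + sorted(
        seen_types - set(DEFAULT_TYPE_NAMES)
    )
    splits = list(split_assignment)
    table = {t: {s: 0 for s in splits} for t in types}
    for doc_id, ms in annotation_set.items():
        s = split_of.get(doc_id)
        if s is None:
            continue
        for m in ms:
            table[m.type][s] += 1
    df = pd.DataFrame.from_dict(table, orient="index", columns=splits).fillna(0).astype(int)
    df["total"] = df.sum(axis=1)
    df.loc["total"] = df.sum(axis=0)
    return df
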