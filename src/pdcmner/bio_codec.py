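"""BIO token labeling: tokenization and span <-> label-sequence conversion.

Token classification is the standard formulation for entity extraction:
each token receives one label from ``{O} | {B-t, I-t}`` over the active
entity types, so 15 types yield 15 x 2 + 1 = 31 labels.  ``encode_bio``
turns character-span mentions into a label sequence; ``decode_bio`` is its
(lenient) inverse and never fails on malformed model output.

Cross-type overlapping mentions cannot coexist in one BIO sequence; the
longer mention wins and the inner one is dropped for encoding only (the
standoff gold keeps both).  Mention boundaries falling strictly inside a
token are expanded outward to token boundaries, which preserves recall.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus import EntityMention

logger = logging.getLogger(__name__)

__all__ = [
    "Token",
    "BioLabelScheme",
    "build_label_scheme",
    "tokenize",
    "encode_bio",
    "decode_bio",
    "to_conll",
]

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int


class BioLabelScheme:
    """Ordered label set {O, B-t1, I-t1, B-t2, I-t2, ...} with id maps."""

    def __init__(self, type_names: Sequence[str]):
        if len(set(type_names)) != len(type_names):
            raise ValueError("duplicate type names")
        self.type_names = tuple(type_names)
        labels = ["O"]
        for t in type_names:
            labels.append(f"B-{t}")
            labels.append(f"I-{t}")
        self.labels = tuple(labels)
        self.label_to_id = {lab: i for i, lab in enumerate(labels)}
        self.id_to_label = dict(enumerate(labels))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def outside_id(self) -> int:
        return 0

    def begin_id(self, type_name: str) -> int:
        return self.label_to_id[f"B-{type_name}"]

    def inside_id(self, type_name: str) -> int:
        return self.label_to_id[f"I-{type_name}"]

    def parse(self, label_id: int) -> tuple[str, str | None]:
        """Return (prefix, type) where prefix is 'O', 'B' or 'I'."""
        lab = self.id_to_label[label_id]
        if lab == "O":
            return "O", None
        prefix, type_name = lab.split("-", 1)
        return prefix, type_name


def build_label_scheme(type_names: Sequence[str]) -> BioLabelScheme:
    return BioLabelScheme(type_names)


def tokenize(text: str) -> list[Token]:
    """Whitespace tokenization with punctuation split off; offsets exact."""
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _select_encodable(mentions: Iterable[EntityMention]) -> list[EntityMention]:
    """Drop the inner member of any cross-type overlapping pair (longer wins)."""
    ms = sorted(mentions, key=lambda m: (-(m.end - m.start), m.start, m.type))
    kept: list[EntityMention] = []
    for m in ms:
        clash = next((k for k in kept if k.overlaps(m)), None)
        if clash is None:
            kept.append(m)
        else:
            logger.info(
                "BIO encoding: dropping mention (%d,%d,%s) overlapped by longer (%d,%d,%s)",
                m.start, m.end, m.type, clash.start, clash.end, clash.type,
            )
    return sorted(kept, key=lambda m: (m.start, m.end))


def encode_bio(
    tokens: Sequence[Token],
    mentions: Iterable[EntityMention],
    scheme: BioLabelScheme,
) -> list[int]:
    """One label id per token: B at a mention's first token, I inside, O elsewhere.

    Mentions whose boundaries fall inside a token are expanded to the
    covering tokens (logged, never an error).
    """
    labels = [scheme.outside_id] * len(tokens)
    for m in _select_encodable(mentions):
        covered = [
            i for i, tok in enumerate(tokens) if tok.start < m.end and m.start < tok.end
        ]
        if not covered:
            logger.warning("mention (%d,%d,%s) covers no token; skipped", m.start, m.end, m.type)
            continue
        first, last = covered[0], covered[-1]
        if tokens[first].start < m.start or tokens[last].end > m.end:
            logger.info(
                "mention (%d,%d,%s) not token-aligned; expanded to (%d,%d)",
                m.start, m.end, m.type, tokens[first].start, tokens[last].end,
            )
        labels[first] = scheme.begin_id(m.type)
        for i in covered[1:]:
            labels[i] = scheme.inside_id(m.type)
    return labels


def decode_bio(
    tokens: Sequence[Token],
    labels: Sequence[int],
    scheme: BioLabelScheme,
    text: str | None = None,
) -> list[EntityMention]:
    """Lenient inverse of :func:`encode_bio`.

    Maximal B/I runs of one type become mentions; an I with no preceding
    same-type B or I opens a new mention; O breaks runs.  Surface text is
    taken from ``text`` when given, else reconstructed from token texts
    and gaps are rendered as single spaces only when offsets are adjacent.
    """
    if len(labels) != len(tokens):
        raise ValueError(f"{len(labels)} labels for {len(tokens)} tokens")
    mentions: list[EntityMention] = []
    run_type: str | None = None
    run_start = run_end = 0

    def flush() -> None:
        nonlocal run_type
        if run_type is not None:
            surface = (
                text[run_start:run_end]
                if text is not None
                else _reconstruct(tokens, run_start, run_end)
            )
            mentions.append(EntityMention(run_start, run_end, run_type, surface))
        run_type = None

    for tok, lab in zip(tokens, labels):
        prefix, type_name = scheme.parse(lab)
        if prefix == "O":
            flush()
        elif prefix == "B" or (prefix == "I" and type_name != run_type):
            flush()
            run_type = type_name
            run_start, run_end = tok.start, tok.end
        else:  # I continuing the current run
            run_end = tok.end
    flush()
    return mentions


def _reconstruct(tokens: Sequence[Token], start: int, end: int) -> str:
    parts: list[str] = []
    prev_end: int | None = None
    for tok in tokens:
        if tok.start >= start and tok.end <= end:
            if prev_end is not None and tok.start > prev_end:
                parts.append(" " * (tok.start - prev_end))
            parts.append(tok.text)
            prev_end = tok.end
    return "".join(parts)


def to_conll(tokens: Sequence[Token], labels: Sequence[int], scheme: BioLabelScheme) -> str:
    """Two-column token\\tlabel export for inspection."""
    return "\n".join(
        f"{tok.text}\t{scheme.id_to_label[lab]}" for tok, lab in zip(tokens, labels)
    ) + ("\n" if tokens else "")
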