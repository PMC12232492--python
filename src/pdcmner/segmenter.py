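"""Rule-based sentence segmentation and mention projection.

Abstracts are processed one sentence at a time downstream, so mentions
annotated at document level must be re-based onto sentence-local
coordinates (and back).  The splitter is deliberately simple: a sentence
ends at ``.``, ``!`` or ``?`` followed by whitespace and an uppercase
letter or digit, unless the period belongs to a known abbreviation
("e.g.", "Fig.", "et al.", ...).  Sentences are trimmed of surrounding
whitespace; together they cover every non-whitespace character, and the
document text is reconstructable from the sentence spans plus gaps.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .corpus import Document, EntityMention

logger = logging.getLogger(__name__)

__all__ = ["Sentence", "segment", "project_mentions", "restore_mentions"]

# Tokens whose trailing period never ends a sentence.
ABBREVIATIONS = frozenset(
    {
        "e.g", "i.e", "cf", "vs", "al", "etc", "fig", "figs", "eq", "eqs",
        "ref", "refs", "no", "ca", "approx", "dr", "prof", "st", "mr",
        "mrs", "ms", "inc", "spp", "sp", "resp",
    }
)

_TERMINAL = ".!?"


@dataclass(frozen=True)
class Sentence:
    """A sentence span within a document; ``text == doc.text[start:end]``."""

    doc_id: str
    sent_index: int
    start: int
    end: int
    text: str


def _is_abbreviation(text: str, period_idx: int) -> bool:
    """Is the period at ``period_idx`` part of a known abbreviation?"""
    j = period_idx
    # Walk back over the word (letters and internal periods, e.g. "e.g.").
    i = j
    while i > 0 and (text[i - 1].isalpha() or text[i - 1] == "."):
        i -= 1
    word = text[i:j].rstrip(".").lower()
    if word in ABBREVIATIONS:
        return True
    # Single uppercase initial like "J." in author names.
    if len(word) == 1 and word.isalpha() and text[i].isupper():
        return True
    return False


def _boundaries(text: str) -> list[int]:
    """End offsets (exclusive) of sentence-terminating punctuation runs."""
    bounds = []
    n = len(text)
    i = 0
    while i < n:
        ch = text[i]
        if ch in _TERMINAL:
            # Consume a run of terminal punctuation plus closing quotes/parens.
            j = i + 1
            while j < n and text[j] in _TERMINAL + "\"')]":
                j += 1
            if ch == "." and _is_abbreviation(text, i):
                i += 1
                continue
            # Lookahead: whitespace then uppercase/digit (or end of text).
            k = j
            while k < n and text[k].isspace():
                k += 1
            if k == n or (k > j and (text[k].isupper() or text[k].isdigit())):
                bounds.append(j)
                i = j
                continue
        i += 1
    return bounds


def segment(document: Document) -> list[Sentence]:
    """Split a document into trimmed, ordered, non-overlapping sentences."""
    text = document.text
    bounds = _boundaries(text)
    if not bounds or bounds[-1] < len(text):
        bounds = bounds + [len(text)]
    sentences = []
    prev = 0
    for b in bounds:
        start, end = prev, b
        while start < end and text[start].isspace():
            start += 1
        while end > start and text[end - 1].isspace():
            end -= 1
        if start < end:
            sentences.append(
                Sentence(document.doc_id, len(sentences), start, end, text[start:end])
            )
        prev = b
    return sentences


def project_mentions(
    document: Document,
    sentences: list[Sentence],
    mentions: list[EntityMention],
) -> tuple[dict[int, list[EntityMention]], list[EntityMention]]:
    """Re-base document-level mentions onto sentence-local offsets.

    Returns ``(by_sentence, orphans)`` where ``by_sentence`` maps sentence
    index to mentions with sentence-local offsets and ``orphans`` are
    mentions not contained in any single sentence (these are logged and
    excluded downstream).
    """
    by_sentence: dict[int, list[EntityMention]] = {s.sent_index: [] for s in sentences}
    orphans: list[EntityMention] = []
    for m in mentions:
        home = None
        for s in sentences:
            if s.start <= m.start and m.end <= s.end:
                home = s
                break
        if home is None:
            logger.warning(
                "%s: mention (%d, %d, %s) crosses a sentence boundary; dropped",
                document.doc_id, m.start, m.end, m.type,
            )
            orphans.append(m)
        else:
            by_sentence[home.sent_index].append(m.shifted(-home.start))
    return by_sentence, orphans


def restore_mentions(
    sentence: Sentence, local_mentions: list[EntityMention]
) -> list[EntityMention]:
    """Inverse of :func:`project_mentions` for a single sentence."""
    return [m.shifted(sentence.start) for m in local_mentions]
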