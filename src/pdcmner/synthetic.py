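"""Synthetic corpora, annotator-noise simulation, and mock providers.

The generator emits templated English sentences with planted entity
mentions so that every pipeline stage — standoff I/O, segmentation, BIO
encoding, prompting, training, evaluation — runs end to end with no
network or model download.  It reproduces the statistical structure the
pipeline assumes rather than realistic prose:

* the 15-type frequency profile is heavily skewed (biomarker, treatment
  and diagnosis frequent; cancer_grade and cancer_stage rare), matching
  the released gold corpus distribution;
* mention surfaces come from a curated lexicon in which every word
  carries exactly one BIO label across the whole lexicon and the carrier
  phrases, so a per-token majority lexicon solves the task — a trained
  token classifier therefore must too;
* optional cross-type overlaps plant a biomarker inside a treatment
  ("MEK" in "MEK inhibitor"), the case that a single BIO sequence cannot
  represent (off by default, where every stage round-trips losslessly).

Annotator noise (boundary jitter, drops, spurious additions, type
confusion) turns the gold standard into realistic disagreeing annotators;
jittered spans are clamped so they always still overlap their source and
stay inside the host sentence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import TinyTransformerBackbone
from .bio_codec import tokenize
from .corpus import AnnotationSet, Corpus, Document, EntityMention
from .prompt_direct import extract_query, insert_tags
from .registry import DEFAULT_TYPE_NAMES, REFERENCE_TOTALS
from .segmenter import project_mentions, segment

__all__ = [
    "GeneratorConfig",
    "NoiseConfig",
    "generate_corpus",
    "perturb_annotations",
    "make_backbone_fixture",
    "oracle_provider",
    "OracleProvider",
    "SilentProvider",
    "DEFAULT_LEXICON",
]

# Curated lexicon: within these surfaces plus the carrier phrases below,
# every word occurs with exactly one BIO label (lexical separability).
DEFAULT_LEXICON: dict[str, tuple[str, ...]] = {
    "diagnosis": ("Ewing sarcoma", "lung adenocarcinoma", "glioblastoma", "TNBC"),
    "age_category": ("adult", "pediatric"),
    "genetic_effect": ("missense", "amplification", "deletion"),
    "model_type": ("PDX", "organoid", "cell line"),
    "molecular_char": ("RNA sequencing", "immunohistochemistry", "proteomics"),
    "biomarker": ("BRCA1", "IDH1", "KRAS", "ALK", "PTEN", "MEK"),
    "treatment": ("chemotherapy", "cisplatin", "erlotinib", "olaparib"),
    "response_to_treatment": ("partial response", "stable disease", "complete remission"),
    "sample_type": ("biopsy", "autopsy", "tissue fragment"),
    "tumor_type": ("primary", "recurrent", "metastatic"),
    "cancer_grade": ("grade 1", "grade 2", "grade 3"),
    "cancer_stage": ("stage I", "stage II", "stage III"),
    "clinical_trial": ("NCT02720029", "randomized controlled trial", "prospective trial"),
    "host_strain": ("NSG", "nude mice", "NOD SCID"),
    "model_id": ("PHLC402", "HCM1023", "PDM56"),
}

_OPENERS = (
    "Patients with",
    "We studied",
    "The cohort included",
    "Researchers evaluated",
    "This report describes",
    "The laboratory profiled",
)
_CONNECTORS = (
    "together with",
    "as well as",
    "in combination with",
    "alongside",
    "compared against",
    "and also",
)
_TAILS = (
    "in this cohort",
    "during follow up",
    "across all cases",
    "at enrollment",
    "under review",
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_documents: int = 50
    sentences_per_doc: tuple[int, int] = (6, 6)
    type_frequency: dict[str, float] = field(
        default_factory=lambda: {t: float(REFERENCE_TOTALS[t]) for t in DEFAULT_TYPE_NAMES}
    )
    lexicon: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_LEXICON))
    overlap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        weights = list(self.type_frequency.values())
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("type weights must be non-negative, not all zero")
        for t, w in self.type_frequency.items():
            if w > 0 and not self.lexicon.get(t):
                raise ValueError(f"empty lexicon for requested type {t!r}")
        if not (0.0 <= self.overlap_rate <= 1.0):
            raise ValueError("overlap_rate must be in [0, 1]")


@dataclass(frozen=True)
class NoiseConfig:
    jitter: int = 0
    drop_rate: float = 0.0
    add_rate: float = 0.0
    type_confusion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.drop_rate, self.add_rate, self.type_confusion_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


def _build_sentence(rng: np.random.Generator, config: GeneratorConfig):
    """One sentence string plus its sentence-local mentions."""
    types = [t for t, w in config.type_frequency.items() if w > 0]
    weights = np.array([config.type_frequency[t] for t in types], dtype=float)
    weights /= weights.sum()
    k = int(rng.choice([1, 2, 3], p=[0.3, 0.5, 0.2]))
    parts = [str(rng.choice(_OPENERS))]
    mentions: list[EntityMention] = []
    text = parts[0]
    for slot in range(k):
        chosen = str(rng.choice(types, p=weights))
        surface = str(rng.choice(config.lexicon[chosen]))
        text += " "
        start = len(text)
        text += surface
        mentions.append(EntityMention(start, start + len(surface), chosen, surface))
        if slot < k - 1:
            text += " " + str(rng.choice(_CONNECTORS))
    if config.overlap_rate > 0 and rng.random() < config.overlap_rate:
        text += " " + str(rng.choice(_CONNECTORS))
        text += " "
        start = len(text)
        inner = "MEK"
        outer = "MEK inhibitor"
        text += outer
        mentions.append(EntityMention(start, start + len(outer), "treatment", outer))
        mentions.append(EntityMention(start, start + len(inner), "biomarker", inner))
    if rng.random() < 0.5:
        text += " " + str(rng.choice(_TAILS))
    text += "."
    # reject same-type overlaps (possible only for repeated types in one slot
    # list; surfaces never overlap by construction, so this cannot trigger)
    return text, mentions


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[Corpus, AnnotationSet, dict[str, int]]:
    """Deterministic synthetic corpus with a ledger of planted counts.

    The ledger records exactly how many mentions of each type were
    planted; it always equals the corpus statistics of the returned gold
    annotation set, cell for cell.
    """
    rng = np.random.default_rng(config.seed)
    corpus = Corpus()
    gold = AnnotationSet("gold")
    ledger: dict[str, int] = {t: 0 for t in config.type_frequency}
    lo, hi = config.sentences_per_doc
    for i in range(config.n_documents):
        n_sent = int(rng.integers(lo, hi + 1))
        doc_text = ""
        doc_mentions: list[EntityMention] = []
        for _ in range(n_sent):
            if doc_text:
                doc_text += " "
            offset = len(doc_text)
            sent_text, sent_mentions = _build_sentence(rng, config)
            doc_text += sent_text
            for m in sent_mentions:
                doc_mentions.append(m.shifted(offset))
                ledger[m.type] = ledger.get(m.type, 0) + 1
        doc = Document(f"synth-{i:04d}", doc_text)
        corpus.add(doc)
        gold.set_document(doc.doc_id, doc_mentions)
    gold.validate_against(corpus)
    return corpus, gold, {t: n for t, n in ledger.items() if n or t in config.type_frequency}


# ---------------------------------------------------------------------------
# annotator noise


def _sentence_bounds(doc: Document) -> list[tuple[int, int]]:
    return [(s.start, s.end) for s in segment(doc)]


def _host_sentence(bounds: list[tuple[int, int]], m: EntityMention):
    for s, e in bounds:
        if s <= m.start and m.end <= e:
            return s, e
    return 0, None


def perturb_annotations(
    corpus: Corpus,
    gold: AnnotationSet,
    noise: NoiseConfig,
    *,
    source_id: str = "noisy",
) -> AnnotationSet:
    """Simulate an imperfect annotator from the gold standard.

    Mentions are dropped, type-confused and boundary-jittered at the
    configured rates; spurious single-token mentions are added.  Jittered
    spans always keep at least one character of their source span and
    never leave the host sentence, so overlap-mode agreement with gold is
    preserved whenever only jitter is applied.
    """
    rng = np.random.default_rng(noise.seed)
    noisy = AnnotationSet(source_id)
    all_types = list(DEFAULT_TYPE_NAMES)
    for doc in corpus:
        bounds = _sentence_bounds(doc)
        out: list[EntityMention] = []
        for m in gold.mentions_for(doc.doc_id):
            if rng.random() < noise.drop_rate:
                continue
            type_name = m.type
            if noise.type_confusion_rate > 0 and rng.random() < noise.type_confusion_rate:
                others = [t for t in all_types if t != m.type]
                type_name = str(rng.choice(others))
            start, end = m.start, m.end
            if noise.jitter > 0:
                s_lo, s_hi = _host_sentence(bounds, m)
                if s_hi is None:
                    s_lo, s_hi = 0, len(doc.text)
                start = int(m.start + rng.integers(-noise.jitter, noise.jitter + 1))
                end = int(m.end + rng.integers(-noise.jitter, noise.jitter + 1))
                start = max(s_lo, min(start, m.end - 1))  # keep overlap with source
                end = min(s_hi, max(end, m.start + 1))
                if start >= end:
                    start, end = m.start, m.end
            cand = EntityMention(start, end, type_name, doc.text[start:end])
            if any(k.type == cand.type and k.overlaps(cand) for k in out):
                # jitter collided with a neighbour: fall back to the source span
                cand = EntityMention(m.start, m.end, type_name, m.text)
                if any(k.type == cand.type and k.overlaps(cand) for k in out):
                    continue
            out.append(cand)
        if noise.add_rate > 0:
            tokens = [
                t for t in tokenize(doc.text)
                if any(s <= t.start and t.end <= e for s, e in bounds) and t.text.isalpha()
            ]
            n_add = rng.binomial(max(len(gold.mentions_for(doc.doc_id)), 1), noise.add_rate)
            for _ in range(n_add):
                if not tokens:
                    break
                tok = tokens[int(rng.integers(0, len(tokens)))]
                type_name = str(rng.choice(all_types))
                cand = EntityMention(tok.start, tok.end, type_name, tok.text)
                if any(k.type == cand.type and k.overlaps(cand) for k in out):
                    continue
                out.append(cand)
        noisy.set_document(doc.doc_id, out)
    noisy.validate_against(corpus)
    return noisy


# ---------------------------------------------------------------------------
# fixtures and mock providers


def make_backbone_fixture(
    seed: int = 0, dim: int = 32, vocab_size: int = 4096
) -> TinyTransformerBackbone:
    """Tiny deterministic transformer satisfying the backbone contract."""
    return TinyTransformerBackbone(seed=seed, dim=dim, vocab_size=vocab_size)


class OracleProvider:
    """Mock generation provider that answers with the gold tagging.

    Given a corpus and an annotation set (gold, or a corrupted copy), it
    returns ``insert_tags(sentence, mentions)`` for any known query
    sentence and the untagged sentence (flagged) for unknown ones.
    """

    def __init__(self, corpus: Corpus, annotations: AnnotationSet, name: str = "oracle"):
        self.name = name
        self.unknown_queries: list[str] = []
        self._tagged: dict[str, str] = {}
        for doc in corpus:
            sentences = segment(doc)
            by_sent, _orphans = project_mentions(
                doc, sentences, annotations.mentions_for(doc.doc_id)
            )
            for s in sentences:
                self._tagged[s.text] = insert_tags(s.text, by_sent[s.sent_index])

    def generate(self, prompt: str) -> str:
        query = extract_query(prompt)
        if query not in self._tagged:
            self.unknown_queries.append(query)
            return query
        return self._tagged[query]


class SilentProvider:
    """Provider that always returns an empty completion."""

    name = "silent"

    def generate(self, prompt: str) -> str:
        return ""


def oracle_provider(
    corpus: Corpus,
    gold: AnnotationSet,
    corruption: NoiseConfig | None = None,
    seed: int = 0,
) -> OracleProvider:
    """Oracle or noisy-oracle provider over a (possibly corrupted) gold set."""
    if corruption is None:
        return OracleProvider(corpus, gold, name="oracle")
    noise = NoiseConfig(
        jitter=corruption.jitter,
        drop_rate=corruption.drop_rate,
        add_rate=corruption.add_rate,
        type_confusion_rate=corruption.type_confusion_rate,
        seed=corruption.seed if corruption.seed else seed,
    )
    corrupted = perturb_annotations(corpus, gold, noise, source_id="oracle-corrupted")
    return OracleProvider(corpus, corrupted, name="noisy-oracle")
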