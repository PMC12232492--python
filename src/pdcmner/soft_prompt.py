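"""Prompt tuning: a trainable soft prompt plus a token-classification head
over a frozen backbone.

The soft prompt is a sequence of L continuous "virtual token" vectors
(default L = 30) prepended to the embedded input sentence.  Following the
label-word initialization of prompt tuning, the first rows are set to the
backbone embeddings of the entity-type names; remaining rows are drawn
from the embedding table at seeded random.  A linear head maps each
token's final hidden state to the 31 BIO labels.  During training only
the prompt and head parameters receive updates — the backbone fingerprint
is asserted unchanged — so the trainable parameter count is exactly
``L*d + (h+1)*|labels|``.

Optimization is Adam with the default learning rate 0.001 for 50 epochs;
the checkpoint with the best dev micro-F1 (overlapping match) is kept.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .backbone import TinyTransformerBackbone
from .bio_codec import BioLabelScheme, Token, decode_bio, encode_bio, tokenize
from .corpus import EntityMention
from .evaluation import MatchCounts, match_mentions, prf

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "SoftPromptState",
    "SentenceExample",
    "make_examples",
    "init_soft_prompt",
    "train_soft_prompt",
    "predict_labels",
    "extract_entities",
    "save_state",
    "load_state",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    learning_rate: float = 0.001
    seed: int = 0
    batch_size: int = 1
    prompt_length: int = 30

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.prompt_length < 1:
            raise ValueError("prompt_length must be >= 1")


@dataclass
class SoftPromptState:
    prompt: np.ndarray  # (L, d)
    head_w: np.ndarray  # (h, |labels|)
    head_b: np.ndarray  # (|labels|,)
    scheme: BioLabelScheme
    config: TrainConfig
    backbone_fingerprint: str = ""

    @property
    def n_trainable(self) -> int:
        return self.prompt.size + self.head_w.size + self.head_b.size

    def copy(self) -> "SoftPromptState":
        return SoftPromptState(
            self.prompt.copy(), self.head_w.copy(), self.head_b.copy(),
            self.scheme, self.config, self.backbone_fingerprint,
        )


@dataclass(frozen=True)
class SentenceExample:
    """A tokenized sentence with gold BIO labels and gold mentions."""

    text: str
    tokens: tuple[Token, ...]
    label_ids: tuple[int, ...]
    mentions: tuple[EntityMention, ...] = ()


def make_examples(
    sentences_with_mentions: Sequence[tuple[str, Sequence[EntityMention]]],
    scheme: BioLabelScheme,
) -> list[SentenceExample]:
    """Build training/dev examples from (sentence text, local mentions) pairs."""
    examples = []
    for text, mentions in sentences_with_mentions:
        tokens = tokenize(text)
        labels = encode_bio(tokens, mentions, scheme)
        examples.append(
            SentenceExample(text, tuple(tokens), tuple(labels), tuple(mentions))
        )
    return examples


def init_soft_prompt(
    backbone: TinyTransformerBackbone,
    scheme: BioLabelScheme,
    config: TrainConfig,
) -> SoftPromptState:
    """Label-word initialization of the prompt; seeded random head.

    Row k of the prompt equals the backbone embedding of the k-th entity
    type name (its first word piece) for k < #types; remaining rows are
    copies of random embedding-table rows.
    """
    rng = np.random.default_rng(config.seed)
    d = backbone.dim
    L = config.prompt_length
    prompt = np.empty((L, d))
    label_words = list(scheme.type_names)
    n_fixed = min(L, len(label_words))
    for k in range(n_fixed):
        tokens, ids = backbone.tokenize_with_offsets(label_words[k])
        prompt[k] = backbone.embed(ids[:1])[0]  # first piece of the label word
    if L > n_fixed:
        random_ids = rng.integers(0, backbone.vocab_size, size=L - n_fixed)
        prompt[n_fixed:] = backbone.embed(random_ids)
    head_w = rng.normal(0.0, 0.02, size=(backbone.hidden, len(scheme)))
    head_b = np.zeros(len(scheme))
    return SoftPromptState(
        prompt, head_w, head_b, scheme, config, backbone.fingerprint()
    )


def _forward(state, backbone, ids, *, want_cache=False):
    L = state.prompt.shape[0]
    inputs = np.concatenate([state.prompt, backbone.embed(ids)], axis=0)
    if want_cache:
        hidden, cache = backbone.encode(inputs, want_cache=True)
    else:
        hidden, cache = backbone.encode(inputs), None
    token_hidden = hidden[L:]
    logits = token_hidden @ state.head_w + state.head_b
    return logits, token_hidden, cache


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _dev_f1(state, backbone, dev: Sequence[SentenceExample]) -> float:
    counts = MatchCounts()
    for ex in dev:
        pred = extract_entities(state, backbone, ex.text, tokens=list(ex.tokens))
        counts.merge(match_mentions(list(ex.mentions), pred, "overlap"))
    return prf(counts).f1


def train_soft_prompt(
    backbone: TinyTransformerBackbone,
    train: Sequence[SentenceExample],
    dev: Sequence[SentenceExample],
    config: TrainConfig,
    scheme: BioLabelScheme | None = None,
) -> tuple[SoftPromptState, list[dict]]:
    """Train prompt + head; returns (best-dev state, per-epoch log).

    The backbone is frozen: its parameter fingerprint is checked before
    and after every epoch, and only input gradients are ever formed.
    """
    if not train:
        raise ValueError("empty training set")
    if scheme is None:
        raise ValueError("a BioLabelScheme must be provided")
    fingerprint_before = backbone.fingerprint()
    state = init_soft_prompt(backbone, scheme, config)
    L = config.prompt_length
    expected = L * backbone.dim + (backbone.hidden + 1) * len(scheme)
    assert state.n_trainable == expected, (state.n_trainable, expected)

    token_ids = [backbone.tokenize_with_offsets(ex.text)[1] for ex in train]
    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam([state.prompt.shape, state.head_w.shape, state.head_b.shape],
                config.learning_rate)
    best = state.copy()
    best_f1 = -1.0
    log: list[dict] = []
    n_labels = len(scheme)
    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        losses = []
        for batch_start in range(0, len(order), config.batch_size):
            batch = order[batch_start : batch_start + config.batch_size]
            g_prompt = np.zeros_like(state.prompt)
            g_w = np.zeros_like(state.head_w)
            g_b = np.zeros_like(state.head_b)
            for idx in batch:
                ex = train[idx]
                ids = token_ids[idx]
                if ids.size == 0:
                    continue
                logits, token_hidden, cache = _forward(
                    state, backbone, ids, want_cache=True
                )
                labels = np.array(ex.label_ids)
                shift = logits - logits.max(axis=1, keepdims=True)
                expl = np.exp(shift)
                probs = expl / expl.sum(axis=1, keepdims=True)
                n_tok = len(labels)
                loss = -np.mean(np.log(probs[np.arange(n_tok), labels] + 1e-12))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, example {idx}"
                    )
                losses.append(loss)
                dlogits = probs.copy()
                dlogits[np.arange(n_tok), labels] -= 1.0
                dlogits /= n_tok
                g_w += token_hidden.T @ dlogits
                g_b += dlogits.sum(axis=0)
                dhidden_tokens = dlogits @ state.head_w.T
                dhidden = np.zeros((L + n_tok, backbone.dim))
                dhidden[L:] = dhidden_tokens
                dinputs = backbone.encode_backward(dhidden, cache)
                g_prompt += dinputs[:L]
            scale = 1.0 / max(len(batch), 1)
            opt.step(
                [state.prompt, state.head_w, state.head_b],
                [g_prompt * scale, g_w * scale, g_b * scale],
            )
        dev_f1 = _dev_f1(state, backbone, dev) if dev else float("nan")
        log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "dev_f1": dev_f1}
        )
        if dev and dev_f1 > best_f1:
            best_f1 = dev_f1
            best = state.copy()
        if backbone.fingerprint() != fingerprint_before:
            raise RuntimeError("backbone parameters changed during training")
    if not dev:
        best = state
    best.backbone_fingerprint = fingerprint_before
    return best, log


def predict_labels(
    state: SoftPromptState,
    backbone: TinyTransformerBackbone,
    sentence: str,
    *,
    tokens: list[Token] | None = None,
) -> list[int]:
    """Argmax label id per word; prompt positions excluded; deterministic.

    Sentences longer than the backbone context are truncated (the tail
    receives the outside label) with a warning.
    """
    toks = tokens if tokens is not None else tokenize(sentence)
    if not toks:
        return []
    _, ids = backbone.tokenize_with_offsets(sentence)
    L = state.prompt.shape[0]
    limit = backbone.max_len - L
    truncated = 0
    if len(ids) > limit:
        truncated = len(ids) - limit
        logger.warning("sentence of %d tokens truncated to %d", len(ids), limit)
        ids = ids[:limit]
    logits, _, _ = _forward(state, backbone, ids)
    labels = list(np.argmax(logits, axis=1))
    labels.extend([state.scheme.outside_id] * truncated)
    return labels


def extract_entities(
    state: SoftPromptState,
    backbone: TinyTransformerBackbone,
    sentence: str,
    *,
    tokens: list[Token] | None = None,
) -> list[EntityMention]:
    """predict_labels composed with lenient BIO decoding."""
    toks = tokens if tokens is not None else tokenize(sentence)
    labels = predict_labels(state, backbone, sentence, tokens=toks)
    return decode_bio(toks, labels, state.scheme, text=sentence)


def save_state(state: SoftPromptState, path: str | Path) -> None:
    """Single-archive checkpoint: arrays plus a JSON manifest."""
    manifest = {
        "labels": list(state.scheme.labels),
        "type_names": list(state.scheme.type_names),
        "config": {
            "epochs": state.config.epochs,
            "learning_rate": state.config.learning_rate,
            "seed": state.config.seed,
            "batch_size": state.config.batch_size,
            "prompt_length": state.config.prompt_length,
        },
        "backbone_fingerprint": state.backbone_fingerprint,
    }
    np.savez(
        path,
        prompt=state.prompt,
        head_w=state.head_w,
        head_b=state.head_b,
        manifest=np.frombuffer(json.dumps(manifest).encode("utf-8"), dtype=np.uint8),
    )


def load_state(path: str | Path) -> SoftPromptState:
    data = np.load(path)
    manifest = json.loads(bytes(data["manifest"]).decode("utf-8"))
    scheme = BioLabelScheme(manifest["type_names"])
    cfg = TrainConfig(**manifest["config"])
    return SoftPromptState(
        data["prompt"], data["head_w"], data["head_b"], scheme, cfg,
        manifest["backbone_fingerprint"],
    )
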