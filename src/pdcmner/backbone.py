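"""Tiny frozen transformer backbone for soft-prompt training.

Prompt tuning needs three things from a language-model backbone: an
embedding table, an encoder mapping a sequence of input vectors (prompt
vectors prepended to token embeddings) to per-position hidden states, and
gradients of those hidden states with respect to the *inputs* only — the
backbone itself stays frozen, so no parameter gradients are ever needed.

This module implements that contract as a small causal transformer in
plain numpy with an explicit backward pass.  The default configuration
(2 layers, model width 32, < 1M parameters) trains on a laptop CPU in
seconds and is bit-reproducible from its seed; real LLM backbones can be
attached by implementing the same interface.

Tokenization is word-level (words and punctuation marks, with character
offsets), and vocabulary ids come from a stable content hash of the
lowercased token, so no vocabulary file is needed and ids are identical
across processes.  Every word is a single "piece"; the piece-to-word map
is therefore the identity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .bio_codec import Token, tokenize

__all__ = ["TinyTransformerBackbone", "token_id"]


def token_id(token_text: str, vocab_size: int) -> int:
    """Stable hash-based vocabulary id (case-insensitive)."""
    digest = hashlib.md5(token_text.lower().encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little") % vocab_size


def _layer_norm_forward(x: np.ndarray, eps: float = 1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x - mu) * inv
    return y, (y, inv)


def _layer_norm_backward(dy: np.ndarray, cache) -> np.ndarray:
    y, inv = cache
    d = y.shape[-1]
    dy_mean = dy.mean(axis=-1, keepdims=True)
    proj = (dy * y).mean(axis=-1, keepdims=True)
    return inv * (dy - dy_mean - y * proj)


_GELU_C = np.sqrt(2.0 / np.pi)


def _gelu_forward(x: np.ndarray):
    inner = _GELU_C * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    return 0.5 * x * (1.0 + t), (x, t)


def _gelu_backward(dy: np.ndarray, cache) -> np.ndarray:
    x, t = cache
    dinner = _GELU_C * (1.0 + 3 * 0.044715 * x**2)
    return dy * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner)


@dataclass
class _Block:
    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray
    wo: np.ndarray
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray


class TinyTransformerBackbone:
    """Deterministic causal transformer encoder over hash-embedded words."""

    def __init__(
        self,
        seed: int = 0,
        dim: int = 32,
        vocab_size: int = 4096,
        n_layers: int = 2,
        max_len: int = 512,
    ):
        if dim < 1 or vocab_size < 1:
            raise ValueError("dim and vocab_size must be >= 1")
        self.seed = int(seed)
        self.dim = int(dim)
        self.hidden = int(dim)  # hidden width equals model width
        self.vocab_size = int(vocab_size)
        self.n_layers = int(n_layers)
        self.max_len = int(max_len)
        rng = np.random.default_rng(seed)
        d = self.dim
        self.embedding = rng.normal(0.0, 1.0, size=(vocab_size, d))
        self.positional = self._sinusoidal(max_len, d)
        scale = d**-0.5
        out_scale = scale / np.sqrt(2.0 * n_layers)
        self.blocks: list[_Block] = []
        for _ in range(n_layers):
            self.blocks.append(
                _Block(
                    wq=rng.normal(0.0, scale, (d, d)),
                    wk=rng.normal(0.0, scale, (d, d)),
                    wv=rng.normal(0.0, scale, (d, d)),
                    wo=rng.normal(0.0, out_scale, (d, d)),
                    w1=rng.normal(0.0, scale, (d, 4 * d)),
                    b1=np.zeros(4 * d),
                    w2=rng.normal(0.0, out_scale, (4 * d, d)),
                    b2=np.zeros(d),
                )
            )

    @staticmethod
    def _sinusoidal(max_len: int, d: int) -> np.ndarray:
        pos = np.arange(max_len)[:, None]
        i = np.arange(d)[None, :]
        angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
        enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
        return enc

    # -- contract -----------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        n = self.embedding.size
        for b in self.blocks:
            n += sum(getattr(b, f).size for f in ("wq", "wk", "wv", "wo", "w1", "b1", "w2", "b2"))
        return n

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.embedding.tobytes())
        for b in self.blocks:
            for f in ("wq", "wk", "wv", "wo", "w1", "b1", "w2", "b2"):
                h.update(getattr(b, f).tobytes())
        return h.hexdigest()

    def tokenize_with_offsets(self, text: str) -> tuple[list[Token], np.ndarray]:
        """Word-level tokens with offsets and their vocabulary ids.

        Words are single pieces here, so the piece->word map is identity.
        """
        tokens = tokenize(text)
        ids = np.array([token_id(t.text, self.vocab_size) for t in tokens], dtype=np.int64)
        return tokens, ids

    def embed(self, ids: np.ndarray) -> np.ndarray:
        return self.embedding[np.asarray(ids, dtype=np.int64)]

    def encode(self, inputs: np.ndarray, *, want_cache: bool = False):
        """Hidden states for a sequence of input vectors (n, dim).

        Positional encodings are added to the whole sequence (prompt
        positions included); attention is causal.  With ``want_cache`` the
        intermediates needed by :meth:`encode_backward` are returned too.
        """
        x = np.asarray(inputs, dtype=np.float64)
        n, d = x.shape
        if d != self.dim:
            raise ValueError(f"expected input dim {self.dim}, got {d}")
        if n > self.max_len:
            raise ValueError(f"sequence length {n} exceeds max_len {self.max_len}")
        x = x + self.positional[:n]
        mask = np.tril(np.ones((n, n), dtype=bool))
        caches = []
        for blk in self.blocks:
            a, ln1 = _layer_norm_forward(x)
            q = a @ blk.wq
            k = a @ blk.wk
            v = a @ blk.wv
            scores = (q @ k.T) / np.sqrt(d)
            scores = np.where(mask, scores, -1e30)
            scores -= scores.max(axis=1, keepdims=True)
            attn = np.exp(scores)
            attn /= attn.sum(axis=1, keepdims=True)
            z = attn @ v
            x = x + z @ blk.wo
            b_in, ln2 = _layer_norm_forward(x)
            h1, gelu_cache = _gelu_forward(b_in @ blk.w1 + blk.b1)
            x = x + h1 @ blk.w2
            caches.append((ln1, q, k, v, attn, z, ln2, b_in, gelu_cache, h1))
        out, ln_f = _layer_norm_forward(x)
        if want_cache:
            return out, (caches, ln_f, mask)
        return out

    def encode_backward(self, grad_hidden: np.ndarray, cache) -> np.ndarray:
        """Gradient of a scalar loss w.r.t. the input vectors.

        Backbone parameters are frozen; only the input gradient is formed,
        which is all soft-prompt training requires.
        """
        caches, ln_f, mask = cache
        d = self.dim
        dx = _layer_norm_backward(np.asarray(grad_hidden, dtype=np.float64), ln_f)
        for blk, (ln1, q, k, v, attn, z, ln2, b_in, gelu_cache, h1) in zip(
            reversed(self.blocks), reversed(caches)
        ):
            # MLP sublayer
            dh1 = dx @ blk.w2.T
            dmlp_in = _gelu_backward(dh1, gelu_cache) @ blk.w1.T
            dx = dx + _layer_norm_backward(dmlp_in, ln2)
            # attention sublayer
            dz = dx @ blk.wo.T
            dattn = dz @ v.T
            dv = attn.T @ dz
            dscores = attn * (dattn - (dattn * attn).sum(axis=1, keepdims=True))
            dscores = np.where(mask, dscores, 0.0) / np.sqrt(d)
            dq = dscores @ k
            dk = dscores.T @ q
            da = dq @ blk.wq.T + dk @ blk.wk.T + dv @ blk.wv.T
            dx = dx + _layer_norm_backward(da, ln1)
        return dx
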