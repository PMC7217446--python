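"""Per-document encoders producing penultimate-layer document embeddings.

Both encoders map a tokenized report to a fixed-dimension embedding e_i —
the representation a classification head would consume. During encoder
pretraining a temporary softmax head sits on top; after training only the
penultimate embedding is kept and saved per report for the context modules.

* ``TextCnn`` — the word-level CNN: word embeddings convolved with windows
  of 3, 4, and 5 consecutive words, ReLU, max-over-time pooling per filter,
  and concatenation of the pooled feature maps.
* ``HiSanLite`` — a compact hierarchical self-attention encoder: multihead
  self-attention over the tokens of each line followed by attention pooling
  into line embeddings, then self-attention and attention pooling over the
  line embeddings. It is a faithful simplification of the hierarchical
  self-attention network family, not a port of any particular published
  configuration.

Encoders are strictly per-document: no report's embedding depends on any
other report.
"""

from __future__ import annotations

from typing import Sequence

import h5py
import numpy as np

from .autodiff import Tensor, concatenate, glorot, parameter, softmax, stack
from .context import SelfAttentionContext
from .preprocess import TokenizedDoc


def _distribute(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


class TextCnn:
    """Word-level CNN document encoder.

    ``output_dim`` pooled features are split as evenly as possible across the
    convolution windows, so the concatenated penultimate embedding has
    exactly ``output_dim`` dimensions.
    """

    def __init__(
        self,
        vocab_size: int,
        embed_dim: int = 300,
        output_dim: int = 300,
        windows: Sequence[int] = (3, 4, 5),
        pad_id: int = 0,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.vocab_size = vocab_size
        self.embed_dim = embed_dim
        self.output_dim = output_dim
        self.windows = tuple(windows)
        self.pad_id = pad_id
        self.embeddings = parameter(rng.normal(0.0, 0.1, size=(vocab_size, embed_dim)))
        self.filters = []
        for w, f in zip(self.windows, _distribute(output_dim, len(self.windows))):
            self.filters.append(
                {
                    "window": w,
                    "W": parameter(glorot(rng, w * embed_dim, f)),
                    "b": parameter(np.zeros(f)),
                }
            )

    def parameters(self) -> list[Tensor]:
        out = [self.embeddings]
        for f in self.filters:
            out.extend([f["W"], f["b"]])
        return out

    def _pad_batch(self, docs: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        max_w = max(self.windows)
        max_len = max(max(len(d) for d in docs), max_w)
        ids = np.full((len(docs), max_len), self.pad_id, dtype=np.int64)
        lengths = np.zeros(len(docs), dtype=np.int64)
        for i, d in enumerate(docs):
            d = np.asarray(d, dtype=np.int64)
            if d.size == 0:
                d = np.array([self.pad_id], dtype=np.int64)
            ids[i, : len(d)] = d
            lengths[i] = len(d)
        return ids, lengths

    def encode_batch(self, docs: Sequence[np.ndarray]) -> Tensor:
        """Embed a batch of token-id documents to (batch, output_dim)."""
        ids, lengths = self._pad_batch(docs)
        batch, max_len = ids.shape
        x = self.embeddings[ids]  # (batch, L, embed_dim)
        pooled = []
        for f in self.filters:
            w = f["window"]
            n_pos = max_len - w + 1
            # sliding windows flattened: (batch, n_pos, w * embed_dim)
            win = concatenate([x[:, j : j + n_pos, :] for j in range(w)], axis=2)
            conv = (win @ f["W"] + f["b"]).relu()
            # documents shorter than the window still get their zero-padded
            # window; longer documents mask window positions that start past
            # the last full window
            valid_until = np.maximum(lengths - w + 1, 1)
            pos_mask = np.arange(n_pos)[None, :] < valid_until[:, None]
            neg = np.where(pos_mask, 0.0, -np.inf)[:, :, None]
            pooled.append((conv + Tensor(neg)).max(axis=1))
        return concatenate(pooled, axis=1)

    def encode(self, doc: TokenizedDoc | np.ndarray) -> np.ndarray:
        ids = doc.token_ids if isinstance(doc, TokenizedDoc) else np.asarray(doc)
        return self.encode_batch([ids]).data[0]


class HiSanLite:
    """Hierarchical self-attention document encoder.

    Token embeddings within each line pass through unmasked multihead
    self-attention and are pooled with a learned attention query; the
    resulting line embeddings pass through a second self-attention layer and
    pooling to give the document embedding. Line structure comes from the
    preprocessing segmentation (50-token cap per line).
    """

    def __init__(
        self,
        vocab_size: int,
        output_dim: int = 300,
        heads: int = 6,
        max_line_tokens: int = 64,
        max_lines: int = 64,
        pad_id: int = 0,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.vocab_size = vocab_size
        self.output_dim = output_dim
        self.pad_id = pad_id
        self.max_line_tokens = max_line_tokens
        self.max_lines = max_lines
        self.embeddings = parameter(rng.normal(0.0, 0.1, size=(vocab_size, output_dim)))
        self.word_attention = SelfAttentionContext(
            dim=output_dim, heads=heads, causal=False,
            max_seq_len=max_line_tokens, seed=int(rng.integers(2**31)),
        )
        self.line_attention = SelfAttentionContext(
            dim=output_dim, heads=heads, causal=False,
            max_seq_len=max_lines, seed=int(rng.integers(2**31)),
        )
        self.word_query = parameter(rng.normal(0.0, 0.1, size=(output_dim,)))
        self.line_query = parameter(rng.normal(0.0, 0.1, size=(output_dim,)))

    def parameters(self) -> list[Tensor]:
        return (
            [self.embeddings, self.word_query, self.line_query]
            + self.word_attention.parameters()
            + self.line_attention.parameters()
        )

    def _attend_pool(
        self, x: Tensor, attention: SelfAttentionContext, query: Tensor,
        mask: np.ndarray,
    ) -> Tensor:
        """Self-attention then attention pooling over axis 1 of (B, n, d)."""
        ctx = attention.forward(x, mask)
        d = ctx.shape[-1]
        scores = (ctx @ query.reshape(d, 1)).reshape(ctx.shape[0], ctx.shape[1])
        scores = scores + Tensor(np.where(mask > 0, 0.0, -np.inf))
        weights = softmax(scores, axis=1)
        return (ctx * weights.reshape(weights.shape[0], weights.shape[1], 1)).sum(axis=1)

    def encode_batch(self, docs: Sequence[TokenizedDoc]) -> Tensor:
        out = []
        for doc in docs:
            if not doc.line_ranges:
                raise ValueError("document has no line ranges")
            lines = [
                doc.token_ids[s:e][: self.max_line_tokens]
                for s, e in doc.line_ranges[: self.max_lines]
            ]
            n_lines = len(lines)
            max_len = max(len(l) for l in lines)
            ids = np.full((n_lines, max_len), self.pad_id, dtype=np.int64)
            mask = np.zeros((n_lines, max_len))
            for i, l in enumerate(lines):
                ids[i, : len(l)] = l
                mask[i, : len(l)] = 1.0
            word_x = self.embeddings[ids]  # (lines, tokens, d)
            line_emb = self._attend_pool(word_x, self.word_attention, self.word_query, mask)
            doc_x = line_emb.reshape(1, n_lines, self.output_dim)
            doc_emb = self._attend_pool(
                doc_x, self.line_attention, self.line_query, np.ones((1, n_lines))
            )
            out.append(doc_emb.reshape(self.output_dim))
        return stack(out, axis=0)

    def encode(self, doc: TokenizedDoc) -> np.ndarray:
        return self.encode_batch([doc]).data[0]

    def line_embeddings(self, doc: TokenizedDoc) -> np.ndarray:
        """Per-line embeddings before document-level pooling (inference)."""
        lines = [doc.token_ids[s:e][: self.max_line_tokens] for s, e in doc.line_ranges]
        n_lines = len(lines)
        max_len = max(len(l) for l in lines)
        ids = np.full((n_lines, max_len), self.pad_id, dtype=np.int64)
        mask = np.zeros((n_lines, max_len))
        for i, l in enumerate(lines):
            ids[i, : len(l)] = l
            mask[i, : len(l)] = 1.0
        word_x = self.embeddings[ids]
        return self._attend_pool(word_x, self.word_attention, self.word_query, mask).data


def extract_embeddings(
    encoder, docs: dict[str, TokenizedDoc | np.ndarray], batch_size: int = 64
) -> tuple[list[str], np.ndarray]:
    """Run a trained encoder over a corpus, one embedding row per report.

    Deterministic in inference mode: running twice yields identical matrices.
    """
    report_ids = list(docs.keys())
    rows = []
    for start in range(0, len(report_ids), batch_size):
        chunk = report_ids[start : start + batch_size]
        batch = [docs[rid] for rid in chunk]
        if isinstance(encoder, TextCnn):
            batch = [
                d.token_ids if isinstance(d, TokenizedDoc) else np.asarray(d)
                for d in batch
            ]
        rows.append(encoder.encode_batch(batch).data)
    matrix = np.concatenate(rows, axis=0).astype(np.float32)
    return report_ids, matrix


def save_embeddings(path, report_ids: Sequence[str], matrix: np.ndarray) -> None:
    """Write an embedding store: datasets 'embeddings' (N x d) + 'report_ids'."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("embeddings", data=np.asarray(matrix, dtype=np.float32))
        fh.create_dataset(
            "report_ids", data=np.array(report_ids, dtype=h5py.string_dtype())
        )


def load_embeddings(path) -> tuple[list[str], np.ndarray]:
    with h5py.File(path, "r") as fh:
        ids = [s.decode() if isinstance(s, bytes) else s for s in fh["report_ids"][...]]
        return ids, fh["embeddings"][...]
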