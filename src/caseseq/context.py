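"""Case-level context mechanisms over document-embedding sequences.

Given per-report embeddings e_0..e_n of one case, a context mechanism emits
one context-aware output o_i per report. Three mechanism families are
implemented:

* concatenation — merge the reports' token sequences into one document and
  classify that (valid only when all reports in the case share a label);
* a GRU, optionally bidirectional, over the embedding sequence;
* single-layer multihead self-attention with learned absolute positional
  embeddings, optionally causally masked.

The unidirectional/causal variants model the online scenario where a report
must be classified before later reports exist, so their outputs are exactly
invariant to any change in future reports.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate, glorot, parameter, softmax, stack

DEFAULT_MAX_SEQ_LEN = 64


class GruContext:
    """Gated recurrent unit over a case's embedding sequence.

    Gates follow the standard formulation: update gate z_t and reset gate r_t
    are sigmoids of affine maps of [h_{t-1}, x_t]; the candidate c_t is a tanh
    of [r_t ∘ h_{t-1}, x_t]; the new state is (1-z_t) ∘ h_{t-1} + z_t ∘ c_t,
    with h_{-1} = 0. Bidirectional mode runs an independently parameterised
    reversed pass and concatenates, so the output dim doubles.
    """

    def __init__(
        self,
        input_dim: int,
        hidden_dim: int = 300,
        bidirectional: bool = False,
        seed: int = 0,
    ):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.bidirectional = bidirectional
        rng = np.random.default_rng(seed)
        self.directions = []
        for _ in range(2 if bidirectional else 1):
            cat = hidden_dim + input_dim
            self.directions.append(
                {
                    "W_z": parameter(glorot(rng, cat, hidden_dim)),
                    "W_r": parameter(glorot(rng, cat, hidden_dim)),
                    "W_c": parameter(glorot(rng, cat, hidden_dim)),
                    "b_z": parameter(np.zeros(hidden_dim)),
                    "b_r": parameter(np.zeros(hidden_dim)),
                    "b_c": parameter(np.zeros(hidden_dim)),
                }
            )

    @property
    def output_dim(self) -> int:
        return self.hidden_dim * (2 if self.bidirectional else 1)

    @property
    def causal(self) -> bool:
        return not self.bidirectional

    def parameters(self) -> list[Tensor]:
        return [p for d in self.directions for p in d.values()]

    def _run_direction(
        self, x: Tensor, mask: np.ndarray, params: dict, reverse: bool
    ) -> Tensor:
        batch, n, _ = x.shape
        h = Tensor(np.zeros((batch, self.hidden_dim)))
        order = range(n - 1, -1, -1) if reverse else range(n)
        outputs: dict[int, Tensor] = {}
        for t in order:
            x_t = x[:, t, :]
            hx = concatenate([h, x_t], axis=1)
            z = (hx @ params["W_z"] + params["b_z"]).sigmoid()
            r = (hx @ params["W_r"] + params["b_r"]).sigmoid()
            rx = concatenate([r * h, x_t], axis=1)
            c = (rx @ params["W_c"] + params["b_c"]).tanh()
            h_new = (1.0 - z) * h + z * c
            m = Tensor(mask[:, t : t + 1])  # carry state through padding
            h = m * h_new + (1.0 - m) * h
            outputs[t] = h
        return stack([outputs[t] for t in range(n)], axis=1)

    def forward(self, embeddings: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """Map (batch, n, input_dim) embeddings to (batch, n, output_dim)."""
        x = as_tensor(embeddings)
        if x.ndim != 3 or x.shape[-1] != self.input_dim:
            raise ValueError(
                f"expected (batch, n, {self.input_dim}) input, got {x.shape}"
            )
        if mask is None:
            mask = np.ones(x.shape[:2])
        mask = np.asarray(mask, dtype=np.float64)
        out = self._run_direction(x, mask, self.directions[0], reverse=False)
        if self.bidirectional:
            back = self._run_direction(x, mask, self.directions[1], reverse=True)
            out = concatenate([out, back], axis=2)
        return out

    __call__ = forward


class SelfAttentionContext:
    """Single-layer multihead self-attention over a case's embedding sequence.

    Q, K, V are window-1 1D convolutions (per-position affine maps) with ELU
    activation applied to X + P, where P is a learned absolute positional
    table. Per head, attention is the row-softmax of the scaled QKᵀ similarity
    matrix applied to V; head outputs are concatenated. With ``causal=True``
    position i attends only to positions ≤ i (the online scenario).

    ``attn_scale`` selects the similarity scaling: "sqrt_d" (default) divides
    by sqrt(d/h) per head, "d" divides by the full model dimension.
    """

    def __init__(
        self,
        dim: int = 300,
        heads: int = 6,
        causal: bool = False,
        max_seq_len: int = DEFAULT_MAX_SEQ_LEN,
        attn_scale: str = "sqrt_d",
        seed: int = 0,
    ):
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        if attn_scale not in ("sqrt_d", "d"):
            raise ValueError("attn_scale must be 'sqrt_d' or 'd'")
        self.dim = dim
        self.heads = heads
        self.causal = causal
        self.max_seq_len = max_seq_len
        self.attn_scale = attn_scale
        rng = np.random.default_rng(seed)
        self.W_q = parameter(glorot(rng, dim, dim))
        self.W_k = parameter(glorot(rng, dim, dim))
        self.W_v = parameter(glorot(rng, dim, dim))
        self.b_q = parameter(np.zeros(dim))
        self.b_k = parameter(np.zeros(dim))
        self.b_v = parameter(np.zeros(dim))
        self.positional = parameter(rng.normal(0.0, 0.1, size=(max_seq_len, dim)))

    @property
    def input_dim(self) -> int:
        return self.dim

    @property
    def output_dim(self) -> int:
        return self.dim

    def parameters(self) -> list[Tensor]:
        return [
            self.W_q,
            self.W_k,
            self.W_v,
            self.b_q,
            self.b_k,
            self.b_v,
            self.positional,
        ]

    def _scale(self) -> float:
        if self.attn_scale == "sqrt_d":
            return float(np.sqrt(self.dim / self.heads))
        return float(self.dim)

    def attention_weights(
        self, embeddings: np.ndarray, mask: np.ndarray | None = None
    ) -> np.ndarray:
        """The (heads, n, n) row-stochastic attention matrices (inference)."""
        x = np.asarray(embeddings, dtype=np.float64)[None, :, :]
        m = np.ones(x.shape[:2]) if mask is None else np.asarray(mask)[None, :]
        _, weights = self._forward(Tensor(x), m, return_weights=True)
        return weights[0]

    def _split_heads(self, t: Tensor, batch: int, n: int) -> Tensor:
        dh = self.dim // self.heads
        return t.reshape(batch, n, self.heads, dh).transpose(0, 2, 1, 3)

    def _forward(self, x: Tensor, mask: np.ndarray, return_weights: bool = False):
        batch, n, _ = x.shape
        if n > self.max_seq_len:
            raise ValueError(
                f"sequence length {n} exceeds positional table ({self.max_seq_len})"
            )
        xp = x + self.positional[:n]
        q = (xp @ self.W_q + self.b_q).elu()
        k = (xp @ self.W_k + self.b_k).elu()
        v = (xp @ self.W_v + self.b_v).elu()
        q, k, v = (self._split_heads(t, batch, n) for t in (q, k, v))
        scores = (q @ k.swapaxes(-1, -2)) / self._scale()  # (batch, h, n, n)
        neg = np.zeros((batch, 1, n, n))
        if self.causal:
            neg = neg + np.where(np.tril(np.ones((n, n))) > 0, 0.0, -np.inf)
        # keys at padded positions are unreachable; the diagonal stays open so
        # no softmax row is ever all -inf (padded query rows are loss-masked)
        key_pad = np.where(mask[:, None, None, :] > 0, 0.0, -np.inf)
        neg = np.broadcast_to(neg + key_pad, (batch, 1, n, n)).copy()
        diag = np.arange(n)
        neg[:, :, diag, diag] = 0.0
        weights = softmax(scores + Tensor(neg), axis=-1)
        out = weights @ v  # (batch, h, n, dh)
        out = out.transpose(0, 2, 1, 3).reshape(batch, n, self.dim)
        if return_weights:
            return out, weights.data
        return out

    def forward(self, embeddings: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """Map (batch, n, dim) embeddings to (batch, n, dim)."""
        x = as_tensor(embeddings)
        if x.ndim != 3 or x.shape[-1] != self.dim:
            raise ValueError(f"expected (batch, n, {self.dim}) input, got {x.shape}")
        if mask is None:
            mask = np.ones(x.shape[:2])
        return self._forward(x, np.asarray(mask, dtype=np.float64))

    __call__ = forward


class IdentityContext:
    """No-op context (the per-report baseline)."""

    def __init__(self, dim: int):
        self.dim = dim
        self.causal = True

    @property
    def output_dim(self) -> int:
        return self.dim

    def parameters(self) -> list[Tensor]:
        return []

    def forward(self, embeddings: Tensor, mask: np.ndarray | None = None) -> Tensor:
        return as_tensor(embeddings)

    __call__ = forward


def run_gru(
    embeddings: np.ndarray, gru: GruContext, mask: np.ndarray | None = None
) -> np.ndarray:
    """Run one (n, d) embedding sequence through a GRU context (inference)."""
    e = np.asarray(embeddings, dtype=np.float64)
    return gru.forward(Tensor(e[None]), None if mask is None else mask[None]).data[0]


def run_self_attention(
    embeddings: np.ndarray,
    attention: SelfAttentionContext,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Run one (n, d) embedding sequence through self-attention (inference)."""
    e = np.asarray(embeddings, dtype=np.float64)
    return attention.forward(
        Tensor(e[None]), None if mask is None else mask[None]
    ).data[0]


def concat_case(
    documents: Sequence[Sequence[int]],
    target_index: int,
    mode: str = "all",
    separator_id: int | None = None,
    labels: Sequence[int] | None = None,
) -> np.ndarray:
    """Concatenate a case's token-id documents for the target report.

    mode="all" joins every document regardless of the target (the offline
    scenario); mode="previous" joins documents 0..target_index inclusive —
    the target itself is always included so the first report still has input.
    Documents are joined with ``separator_id`` when given. Concatenation is
    only valid when all reports share one label, so differing ``labels``
    raise.
    """
    if mode not in ("all", "previous"):
        raise ValueError(f"unknown concatenation mode {mode!r}")
    if not 0 <= target_index < len(documents):
        raise IndexError("target_index outside the case")
    if labels is not None:
        distinct = {y for y in labels if y is not None}
        if len(distinct) > 1:
            raise ValueError(
                "concatenation is invalid when labels differ within a case"
            )
    docs = documents if mode == "all" else documents[: target_index + 1]
    pieces: list[np.ndarray] = []
    for i, doc in enumerate(docs):
        if i > 0 and separator_id is not None:
            pieces.append(np.array([separator_id], dtype=np.int64))
        pieces.append(np.asarray(doc, dtype=np.int64))
    return np.concatenate(pieces) if pieces else np.array([], dtype=np.int64)


def concat_case_docs(
    documents: Sequence,
    target_index: int,
    mode: str = "all",
    separator_id: int | None = None,
):
    """Like :func:`concat_case` but preserving line structure.

    Accepts tokenized documents with ``line_ranges`` and returns a merged
    document whose line ranges are the originals shifted to the merged
    coordinates; each separator token forms its own one-token line.
    """
    from .preprocess import TokenizedDoc

    if mode not in ("all", "previous"):
        raise ValueError(f"unknown concatenation mode {mode!r}")
    docs = documents if mode == "all" else documents[: target_index + 1]
    ids: list[np.ndarray] = []
    ranges: list[tuple[int, int]] = []
    offset = 0
    for i, doc in enumerate(docs):
        if i > 0 and separator_id is not None:
            ids.append(np.array([separator_id], dtype=np.int64))
            ranges.append((offset, offset + 1))
            offset += 1
        ids.append(np.asarray(doc.token_ids, dtype=np.int64))
        for s, e in doc.line_ranges:
            ranges.append((offset + s, offset + e))
        offset += len(doc.token_ids)
    return TokenizedDoc(token_ids=np.concatenate(ids), line_ranges=ranges)
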