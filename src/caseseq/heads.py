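"""Label-generation layers: per-report softmax and linear-chain CRF.

The softmax head scores each report independently. The CRF head scores a
whole label sequence: emission terms from each report's context output plus
a learned transition weight between adjacent labels, normalised by the
forward algorithm. On registry data where every report in a case shares the
aggregate label, the CRF can learn that switching labels mid-case is
vanishingly unlikely, which shows up as diagonal dominance of the learned
transition matrix.

All path computations run in log-space. There are no explicit start/stop
transition scores: the first label is scored by its emission alone.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, glorot, log_softmax, parameter, softmax


class SoftmaxHead:
    """Affine projection to class logits with softmax probabilities."""

    def __init__(self, input_dim: int, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.W = parameter(glorot(rng, input_dim, n_classes))
        self.b = parameter(np.zeros(n_classes))

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]

    def logits(self, outputs: Tensor) -> Tensor:
        return as_tensor(outputs) @ self.W + self.b

    def predict_proba(self, outputs: np.ndarray) -> np.ndarray:
        """Class distributions, rows summing to one (computed in log-space)."""
        logits = self.logits(Tensor(np.asarray(outputs, dtype=np.float64)))
        return np.exp(log_softmax(logits, axis=-1).data)

    def predict(self, outputs: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(Tensor(np.asarray(outputs))).data, axis=-1)

    def loss(self, outputs: Tensor, labels: np.ndarray, mask: np.ndarray) -> Tensor:
        """Mean masked cross-entropy over report positions.

        ``outputs`` is (batch, n, dim); ``labels`` (batch, n) int with
        arbitrary values at masked positions; ``mask`` (batch, n) in {0,1}.
        """
        logp = log_softmax(self.logits(outputs), axis=-1)
        batch, n = labels.shape
        bi, ti = np.meshgrid(np.arange(batch), np.arange(n), indexing="ij")
        picked = logp[bi, ti, np.where(mask > 0, labels, 0)]
        m = Tensor(np.asarray(mask, dtype=np.float64))
        total = float(mask.sum())
        return -(picked * m).sum() / max(total, 1.0)


class CrfHead:
    """Linear-chain CRF over context outputs.

    Emissions come from an affine projection of each o_i; a (K, K) transition
    matrix T scores adjacent label pairs. log P(y) = score(y) - logZ with
    score(y) = Σ_i emit(o_i, y_i) + Σ_{i≥1} T[y_{i-1}, y_i] and logZ from the
    forward algorithm.
    """

    def __init__(self, input_dim: int, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.W = parameter(glorot(rng, input_dim, n_classes))
        self.b = parameter(np.zeros(n_classes))
        self.transitions = parameter(np.zeros((n_classes, n_classes)))

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b, self.transitions]

    def emissions(self, outputs: Tensor) -> Tensor:
        return as_tensor(outputs) @ self.W + self.b

    def log_likelihood(self, outputs: Tensor, labels: np.ndarray) -> Tensor:
        """log P(label sequence | one case). ``outputs`` is (n, dim)."""
        labels = np.asarray(labels, dtype=np.int64)
        if labels.min() < 0 or labels.max() >= self.n_classes:
            raise ValueError("label outside the class set")
        emit = self.emissions(outputs)  # (n, K)
        n = labels.shape[0]
        score = emit[np.arange(n), labels].sum()
        if n > 1:
            score = score + self.transitions[labels[:-1], labels[1:]].sum()
        return score - self._log_partition(emit)

    def _log_partition(self, emit: Tensor) -> Tensor:
        n = emit.shape[0]
        alpha = emit[0]  # (K,)
        for t in range(1, n):
            # alpha_j = lse_i(alpha_i + T_ij) + emit_tj
            alpha = (
                alpha.reshape(self.n_classes, 1) + self.transitions
            ).logsumexp(axis=0) + emit[t]
        return alpha.logsumexp(axis=0)

    def loss(self, outputs: Tensor, labels: np.ndarray, mask: np.ndarray) -> Tensor:
        """Mean negative log-likelihood per report over a padded batch."""
        total = None
        n_reports = 0
        batch = labels.shape[0]
        for i in range(batch):
            length = int(mask[i].sum())
            if length == 0:
                continue
            ll = self.log_likelihood(outputs[i, :length, :], labels[i, :length])
            total = ll if total is None else total + ll
            n_reports += length
        if total is None:
            raise ValueError("empty batch")
        return -total / n_reports

    def decode(self, outputs: np.ndarray) -> np.ndarray:
        """Viterbi maximum-score label path for one case (n, dim)."""
        emit = self.emissions(Tensor(np.asarray(outputs, dtype=np.float64))).data
        return viterbi_decode(emit, self.transitions.data)

    def predict(self, outputs: np.ndarray) -> np.ndarray:
        return self.decode(outputs)


def crf_log_partition(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """Forward-algorithm logZ for plain numpy inputs (inference/oracle use)."""
    emit = Tensor(np.asarray(emissions, dtype=np.float64))
    head = CrfHead.__new__(CrfHead)
    head.n_classes = emissions.shape[1]
    head.transitions = Tensor(np.asarray(transitions, dtype=np.float64))
    return float(head._log_partition(emit).data)


def crf_sequence_score(
    emissions: np.ndarray, transitions: np.ndarray, labels: np.ndarray
) -> float:
    """Unnormalised path score: emissions plus adjacent-label transitions."""
    labels = np.asarray(labels, dtype=np.int64)
    s = float(emissions[np.arange(len(labels)), labels].sum())
    if len(labels) > 1:
        s += float(transitions[labels[:-1], labels[1:]].sum())
    return s


def crf_log_likelihood(
    emissions: np.ndarray, transitions: np.ndarray, labels: np.ndarray
) -> float:
    """log P(labels) under a linear-chain CRF with the given scores."""
    return crf_sequence_score(emissions, transitions, labels) - crf_log_partition(
        emissions, transitions
    )


def viterbi_decode(emissions: np.ndarray, transitions: np.ndarray) -> np.ndarray:
    """Maximum-score label path; ties break toward the lowest class index."""
    emissions = np.asarray(emissions, dtype=np.float64)
    transitions = np.asarray(transitions, dtype=np.float64)
    n, k = emissions.shape
    delta = emissions[0].copy()
    back = np.zeros((n, k), dtype=np.int64)
    for t in range(1, n):
        cand = delta[:, None] + transitions  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # first max -> lowest index
        delta = cand[back[t], np.arange(k)] + emissions[t]
    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def transition_diagnostic(transitions: np.ndarray) -> float:
    """Mean diagonal minus mean off-diagonal of a transition matrix."""
    t = np.asarray(transitions, dtype=np.float64)
    k = t.shape[0]
    diag = np.trace(t) / k
    off = (t.sum() - np.trace(t)) / (k * k - k)
    return float(diag - off)
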