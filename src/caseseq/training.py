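"""Optimization regimes: encoder pretraining, modular two-step context
training, end-to-end training, and accuracy-based early stopping.

Two regimes are supported. *Modular*: the document encoder is trained alone
on individual reports with a temporary softmax head, then frozen; its saved
embeddings become the inputs on which the context module and its head are
trained. *End-to-end*: starting from the pretrained encoder, the full stack
(encoder, context, head) is fine-tuned jointly with whole cases per forward
pass.

All training uses Adam and stops when validation accuracy has not improved
for ``patience`` consecutive epochs, restoring the parameters of the best
epoch. Case batches are padded to the longest case in the batch; padded
positions are excluded from the loss and unreachable to attention.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .autodiff import Adam, Tensor, collect_parameters, stack
from .context import concat_case
from .corpus import CaseSequence, CaseSet
from .encoders import TextCnn, extract_embeddings
from .heads import CrfHead, SoftmaxHead
from .preprocess import TokenizedDoc


@dataclass
class TrainConfig:
    """Optimization settings shared by every training stage."""

    batch_size: int = 64
    learning_rate: float = 1e-4
    patience: int = 5
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be at least 1")
        if self.batch_size < 1:
            raise ValueError("batch size must be at least 1")


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_epoch: int = 0

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "val_accuracy"])
            for i, (loss, acc) in enumerate(zip(self.train_loss, self.val_accuracy), 1):
                writer.writerow([i, loss, acc])
            writer.writerow(["best_epoch", self.best_epoch, ""])


def fit_with_early_stopping(
    model,
    train_items: Sequence,
    val_accuracy_fn: Callable[[], float],
    config: TrainConfig,
) -> TrainLog:
    """Train ``model`` (exposing parameters() and loss_on_batch(items)).

    Shuffles ``train_items`` each epoch, saves parameters after the epoch
    with the highest validation accuracy, and stops once validation accuracy
    has failed to improve for ``patience`` consecutive epochs. The model is
    left holding the best epoch's parameters.
    """
    if len(train_items) == 0:
        raise ValueError("empty train set")
    params = collect_parameters(model)
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    log = TrainLog()
    best_acc = -np.inf
    best_state: list[np.ndarray] = [p.data.copy() for p in params]
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_items))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_items[i] for i in order[start : start + config.batch_size]]
            opt.zero_grad()
            loss = model.loss_on_batch(batch)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_acc = val_accuracy_fn()
        log.train_loss.append(float(np.mean(losses)))
        log.val_accuracy.append(float(val_acc))
        if val_acc > best_acc:
            best_acc = val_acc
            log.best_epoch = epoch
            best_state = [p.data.copy() for p in params]
        elif epoch - log.best_epoch >= config.patience:
            log.stop_epoch = epoch
            break
    else:
        log.stop_epoch = config.max_epochs
    for p, saved in zip(params, best_state):
        p.data = saved.copy()
    return log


def save_checkpoint(
    path: str | Path,
    model,
    config: TrainConfig | None = None,
    vocab_hash: str | None = None,
) -> None:
    """Write model parameters as an npz: arrays p0..pN in
    collect_parameters() order, plus a JSON metadata entry."""
    params = collect_parameters(model)
    meta = {
        "n_params": len(params),
        "shapes": [list(p.shape) for p in params],
        "config": asdict(config) if config else None,
        "vocab_hash": vocab_hash,
    }
    arrays = {f"p{i}": p.data for i, p in enumerate(params)}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str | Path, model) -> dict:
    """Load parameters saved by save_checkpoint into ``model`` (in order)."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        params = collect_parameters(model)
        if len(params) != meta["n_params"]:
            raise ValueError("checkpoint does not match this model's parameters")
        for i, p in enumerate(params):
            arr = data[f"p{i}"]
            if arr.shape != p.shape:
                raise ValueError(f"parameter {i} shape mismatch: {arr.shape} vs {p.shape}")
            p.data = arr.astype(np.float64)
    return meta


# ---------------------------------------------------------------------------
# trainable wrappers


class EncoderClassifier:
    """Document encoder + softmax head trained on individual reports."""

    def __init__(self, encoder, head: SoftmaxHead):
        self.encoder = encoder
        self.head = head

    def parameters(self) -> list[Tensor]:
        return self.encoder.parameters() + self.head.parameters()

    def _encode(self, docs) -> Tensor:
        if isinstance(self.encoder, TextCnn):
            docs = [
                d.token_ids if isinstance(d, TokenizedDoc) else np.asarray(d)
                for d in docs
            ]
        return self.encoder.encode_batch(docs)

    def loss_on_batch(self, items: Sequence[tuple]) -> Tensor:
        docs = [doc for doc, _ in items]
        labels = np.array([y for _, y in items], dtype=np.int64)
        emb = self._encode(docs)  # (B, d)
        out = emb.reshape(emb.shape[0], 1, emb.shape[1])
        return self.head.loss(out, labels[:, None], np.ones((len(items), 1)))

    def predict(self, docs, batch_size: int = 256) -> np.ndarray:
        preds = []
        for start in range(0, len(docs), batch_size):
            emb = self._encode(docs[start : start + batch_size])
            preds.append(np.argmax(self.head.logits(emb).data, axis=-1))
        return np.concatenate(preds)

    def accuracy(self, docs, labels) -> float:
        return float(np.mean(self.predict(docs) == np.asarray(labels)))


def _pad_sequences(
    seqs: Sequence[np.ndarray], labels: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = max(len(s) for s in seqs)
    dim = seqs[0].shape[1]
    e = np.zeros((len(seqs), n, dim))
    y = np.zeros((len(seqs), n), dtype=np.int64)
    mask = np.zeros((len(seqs), n))
    for i, (s, lab) in enumerate(zip(seqs, labels)):
        e[i, : len(s)] = s
        lab = np.asarray(lab)
        valid = lab >= 0
        y[i, : len(s)][valid] = lab[valid]
        mask[i, : len(s)] = valid.astype(float)
    return e, y, mask


class ContextClassifier:
    """Context mechanism + head trained on embedding sequences.

    Items are (sequence (n, d) array, labels (n,) int array) pairs; label -1
    marks a report excluded from the loss (missing label).
    """

    def __init__(self, context, head):
        self.context = context
        self.head = head

    def parameters(self) -> list[Tensor]:
        return self.context.parameters() + self.head.parameters()

    def _truncate(self, seq: np.ndarray, labels: np.ndarray | None = None):
        """Cap over-long cases oldest-first (positional tables are finite)."""
        cap = getattr(self.context, "max_seq_len", None)
        if cap is None or len(seq) <= cap:
            return seq, labels
        import warnings

        warnings.warn(
            f"case of {len(seq)} reports truncated oldest-first to {cap}"
        )
        return seq[-cap:], None if labels is None else labels[-cap:]

    def loss_on_batch(self, items: Sequence[tuple]) -> Tensor:
        pairs = [self._truncate(s, y) for s, y in items]
        e, y, mask = _pad_sequences([s for s, _ in pairs], [y for _, y in pairs])
        out = self.context.forward(Tensor(e), mask)
        return self.head.loss(out, y, mask)

    def predict_sequence(self, seq: np.ndarray) -> np.ndarray:
        full_len = len(seq)
        seq, _ = self._truncate(np.asarray(seq))
        out = self.context.forward(Tensor(np.asarray(seq)[None]))
        o = out.data[0]
        preds = self.head.decode(o) if isinstance(self.head, CrfHead) else self.head.predict(o)
        if full_len > len(preds):  # dropped oldest reports inherit the
            # earliest retained prediction (labels are shared within a case)
            pad = np.full(full_len - len(preds), preds[0], dtype=preds.dtype)
            preds = np.concatenate([pad, preds])
        return preds

    def accuracy(self, items: Sequence[tuple]) -> float:
        correct = total = 0
        for seq, labels in items:
            pred = self.predict_sequence(seq)
            labels = np.asarray(labels)
            valid = labels >= 0
            correct += int(np.sum(pred[valid] == labels[valid]))
            total += int(valid.sum())
        return correct / max(total, 1)


class EndToEndClassifier:
    """Encoder + context + head trained jointly, one case per sequence.

    Items are (docs, labels) where docs is the case's list of tokenized
    documents. All documents in the batch run through the encoder in one
    flattened pass, then regroup into padded case sequences.
    """

    def __init__(self, encoder, context, head):
        self.encoder = encoder
        self.context = context
        self.head = head

    def parameters(self) -> list[Tensor]:
        return (
            self.encoder.parameters()
            + self.context.parameters()
            + self.head.parameters()
        )

    def _case_outputs(self, cases_docs: Sequence[Sequence]) -> tuple[Tensor, np.ndarray]:
        flat = [doc for docs in cases_docs for doc in docs]
        if isinstance(self.encoder, TextCnn):
            flat = [
                d.token_ids if isinstance(d, TokenizedDoc) else np.asarray(d)
                for d in flat
            ]
        emb = self.encoder.encode_batch(flat)  # (total, d)
        lengths = [len(docs) for docs in cases_docs]
        n = max(lengths)
        dim = emb.shape[1]
        rows = []
        mask = np.zeros((len(cases_docs), n))
        offset = 0
        zero = Tensor(np.zeros((1, dim)))
        for i, length in enumerate(lengths):
            case_rows = [emb[offset + j].reshape(1, dim) for j in range(length)]
            case_rows += [zero] * (n - length)
            rows.append(stack(case_rows, axis=0).reshape(n, dim))
            mask[i, :length] = 1.0
            offset += length
        e = stack(rows, axis=0)  # (B, n, dim)
        return e, mask

    def loss_on_batch(self, items: Sequence[tuple]) -> Tensor:
        cases_docs = [docs for docs, _ in items]
        labels = [np.asarray(y) for _, y in items]
        e, mask = self._case_outputs(cases_docs)
        n = mask.shape[1]
        y = np.zeros((len(items), n), dtype=np.int64)
        for i, lab in enumerate(labels):
            valid = lab >= 0
            y[i, : len(lab)][valid] = lab[valid]
            mask[i, : len(lab)] *= valid.astype(float)
        out = self.context.forward(e, mask)
        return self.head.loss(out, y, mask)

    def predict_case(self, docs: Sequence) -> np.ndarray:
        e, _ = self._case_outputs([docs])
        out = self.context.forward(e)
        o = out.data[0]
        if isinstance(self.head, CrfHead):
            return self.head.decode(o)
        return self.head.predict(o)

    def accuracy(self, items: Sequence[tuple]) -> float:
        correct = total = 0
        for docs, labels in items:
            pred = self.predict_case(docs)
            labels = np.asarray(labels)
            valid = labels >= 0
            correct += int(np.sum(pred[valid] == labels[valid]))
            total += int(valid.sum())
        return correct / max(total, 1)


class ConcatClassifier:
    """Concatenation strategy: classify the merged case document.

    mode="all" (offline) classifies one merged document per case and assigns
    its label to every report; mode="previous" (online) merges documents
    0..i for each target report i.
    """

    def __init__(self, encoder, head: SoftmaxHead, separator_id: int, mode: str = "all"):
        if mode not in ("all", "previous"):
            raise ValueError(f"unknown concatenation mode {mode!r}")
        self.inner = EncoderClassifier(encoder, head)
        self.separator_id = separator_id
        self.mode = mode

    def parameters(self) -> list[Tensor]:
        return self.inner.parameters()

    def loss_on_batch(self, items: Sequence[tuple]) -> Tensor:
        return self.inner.loss_on_batch(items)

    def _merge(self, docs: Sequence, i: int, mode: str):
        if isinstance(self.inner.encoder, TextCnn):
            ids = [d.token_ids if isinstance(d, TokenizedDoc) else d for d in docs]
            return concat_case(ids, i, mode, self.separator_id)
        from .context import concat_case_docs

        return concat_case_docs(docs, i, mode, self.separator_id)

    def training_items(self, case_docs: Sequence[Sequence], case_labels):
        """Flatten cases into (merged doc, label) training examples."""
        items = []
        for docs, label in zip(case_docs, case_labels):
            if self.mode == "all":
                items.append((self._merge(docs, 0, "all"), label))
            else:
                for i in range(len(docs)):
                    items.append((self._merge(docs, i, "previous"), label))
        return items

    def predict_case(self, docs: Sequence) -> np.ndarray:
        if self.mode == "all":
            merged = self._merge(docs, 0, "all")
            label = int(self.inner.predict([merged])[0])
            return np.full(len(docs), label, dtype=np.int64)
        merged = [self._merge(docs, i, "previous") for i in range(len(docs))]
        return self.inner.predict(merged)


# ---------------------------------------------------------------------------
# case plumbing


def case_items(
    cases: CaseSet | Sequence[CaseSequence],
    docs: dict[str, TokenizedDoc],
    task: str,
) -> list[tuple]:
    """(documents, labels) per case; label -1 where a report lacks the task."""
    items = []
    for case in cases:
        ds = [docs[r.report_id] for r in case]
        ys = np.array(
            [r.label(task) if r.label(task) is not None else -1 for r in case],
            dtype=np.int64,
        )
        items.append((ds, ys))
    return items


def report_items(
    cases: CaseSet | Sequence[CaseSequence],
    docs: dict[str, TokenizedDoc],
    task: str,
) -> list[tuple]:
    """(document, label) per individual labelled report."""
    items = []
    for case in cases:
        for r in case:
            y = r.label(task)
            if y is not None:
                items.append((docs[r.report_id], y))
    return items


def embedding_sequence_items(
    cases: CaseSet | Sequence[CaseSequence],
    embeddings: dict[str, np.ndarray],
    task: str,
) -> list[tuple]:
    """(embedding sequence, labels) per case, from a saved embedding store."""
    items = []
    for case in cases:
        seq = np.stack([embeddings[r.report_id] for r in case]).astype(np.float64)
        ys = np.array(
            [r.label(task) if r.label(task) is not None else -1 for r in case],
            dtype=np.int64,
        )
        items.append((seq, ys))
    return items


# ---------------------------------------------------------------------------
# regimes


@dataclass
class ModularPipeline:
    encoder: object
    context: object
    head: object
    encoder_log: TrainLog
    context_log: TrainLog
    embeddings: dict[str, np.ndarray]

    def predict_case_from_embeddings(self, seq: np.ndarray) -> np.ndarray:
        clf = ContextClassifier(self.context, self.head)
        return clf.predict_sequence(seq)


def train_encoder(
    encoder,
    n_classes: int,
    train_cases,
    val_cases,
    docs: dict[str, TokenizedDoc],
    task: str,
    config: TrainConfig,
) -> tuple[EncoderClassifier, TrainLog]:
    """Step 1: pretrain the encoder on individual reports (no context)."""
    head = SoftmaxHead(encoder.output_dim, n_classes, seed=config.seed + 1)
    clf = EncoderClassifier(encoder, head)
    train = report_items(train_cases, docs, task)
    val = report_items(val_cases, docs, task)
    val_docs = [d for d, _ in val]
    val_y = [y for _, y in val]
    log = fit_with_early_stopping(
        clf, train, lambda: clf.accuracy(val_docs, val_y), config
    )
    return clf, log


def train_modular(
    encoder,
    context,
    head,
    n_classes: int,
    train_cases,
    val_cases,
    docs: dict[str, TokenizedDoc],
    task: str,
    config: TrainConfig,
    pretrained: EncoderClassifier | None = None,
) -> ModularPipeline:
    """Two-step modular regime.

    Step 1 trains the encoder on individual reports (skipped when a
    ``pretrained`` classifier is supplied); step 2 freezes the encoder,
    extracts embeddings for every report, and trains context + head on the
    embedding sequences. The encoder's parameters are untouched by step 2.
    """
    if pretrained is None:
        enc_clf, enc_log = train_encoder(
            encoder, n_classes, train_cases, val_cases, docs, task, config
        )
    else:
        enc_clf, enc_log = pretrained, TrainLog()
        encoder = pretrained.encoder
    ids, matrix = extract_embeddings(encoder, docs)
    store = {rid: matrix[i].astype(np.float64) for i, rid in enumerate(ids)}
    train = embedding_sequence_items(train_cases, store, task)
    val = embedding_sequence_items(val_cases, store, task)
    ctx_clf = ContextClassifier(context, head)
    ctx_log = fit_with_early_stopping(
        ctx_clf, train, lambda: ctx_clf.accuracy(val), config
    )
    return ModularPipeline(
        encoder=encoder,
        context=context,
        head=head,
        encoder_log=enc_log,
        context_log=ctx_log,
        embeddings=store,
    )


def train_end_to_end(
    pretrained: EncoderClassifier,
    context,
    head,
    train_cases,
    val_cases,
    docs: dict[str, TokenizedDoc],
    task: str,
    config: TrainConfig,
) -> tuple[EndToEndClassifier, TrainLog]:
    """Joint fine-tuning of encoder + context + head from a pretrained
    encoder, batching whole cases."""
    clf = EndToEndClassifier(pretrained.encoder, context, head)
    train = case_items(train_cases, docs, task)
    val = case_items(val_cases, docs, task)
    log = fit_with_early_stopping(clf, train, lambda: clf.accuracy(val), config)
    return clf, log
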