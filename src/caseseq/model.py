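"""Model/Results surface tying corpus, encoders, context, and evaluation
together.

``CaseContextModel`` is configured from a case corpus (or built-in synthetic
generator) with an encoder family, a context mechanism, a scenario
(bidirectional for offline use, unidirectional for online), and a training
regime (modular two-step or end-to-end). ``fit`` runs the full pipeline —
vocabulary, tokenization, date split, (pre)training, context training, test
evaluation — and returns a ``CaseContextResults`` carrying per-report
predictions, accuracy and macro F with bootstrap intervals, the training
logs, and a ``summary()`` table. Two results on the same test set can be
compared with McNemar's test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluation
from .context import GruContext, IdentityContext, SelfAttentionContext
from .corpus import CaseSet, DatasetSplit, split_by_date
from .encoders import HiSanLite, TextCnn
from .evaluation import EvalReport, McNemarResult, evaluate_predictions
from .heads import CrfHead, SoftmaxHead
from .preprocess import Vocab, build_vocab, clean_text, tokenize_document
from .training import (
    ConcatClassifier,
    ContextClassifier,
    EncoderClassifier,
    TrainConfig,
    TrainLog,
    case_items,
    fit_with_early_stopping,
    report_items,
    train_end_to_end,
    train_encoder,
    train_modular,
)

ENCODERS = ("cnn", "hisan")
CONTEXTS = ("none", "concat", "gru", "gru_crf", "attn", "attn_crf")
SCENARIOS = ("bidirectional", "unidirectional")
REGIMES = ("modular", "end_to_end")


class ConfigError(ValueError):
    pass


class CaseContextModel:
    """A case-level-context classifier specification bound to a corpus.

    Parameters
    ----------
    cases : CaseSet
        Date-ordered, singleton-filtered case sequences.
    task : str
        Which label task to train (one of the six registry tasks).
    encoder : {"cnn", "hisan"}
    context : {"none", "concat", "gru", "gru_crf", "attn", "attn_crf"}
    scenario : {"bidirectional", "unidirectional"}
        Unidirectional restricts every mechanism to information from
        previous reports only (online scenario).
    regime : {"modular", "end_to_end"}
    dim : int
        Document-embedding and context dimension (300 mirrors the reference
        configuration; smaller values keep experiments cheap).
    heads : int
        Attention heads; must divide ``dim``.
    """

    def __init__(
        self,
        cases: CaseSet,
        task: str = "site",
        encoder: str = "cnn",
        context: str = "attn",
        scenario: str = "bidirectional",
        regime: str = "modular",
        dim: int = 300,
        embed_dim: int | None = None,
        heads: int = 6,
        min_count: int = 5,
        max_seq_len: int = 64,
        attn_scale: str = "sqrt_d",
        max_concat_tokens: int = 20000,
        split: DatasetSplit | None = None,
        cutoff_year: int = 2016,
    ):
        if encoder not in ENCODERS:
            raise ConfigError(f"unknown encoder {encoder!r}")
        if context not in CONTEXTS:
            raise ConfigError(f"unknown context {context!r}")
        if scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {scenario!r}")
        if regime not in REGIMES:
            raise ConfigError(f"unknown regime {regime!r}")
        if context in ("attn", "attn_crf") and dim % heads != 0:
            raise ConfigError(f"dim {dim} not divisible by heads {heads}")
        if regime == "end_to_end" and context in ("none", "concat"):
            raise ConfigError(f"end_to_end regime does not apply to {context!r}")
        self.cases = cases
        self.task = task
        self.encoder_name = encoder
        self.context_name = context
        self.scenario = scenario
        self.regime = regime
        self.dim = dim
        self.embed_dim = embed_dim if embed_dim is not None else dim
        self.heads = heads
        self.min_count = min_count
        self.max_seq_len = max_seq_len
        self.attn_scale = attn_scale
        self.max_concat_tokens = max_concat_tokens
        self.split = split
        self.cutoff_year = cutoff_year
        if encoder == "hisan" and context == "concat":
            est = self._estimated_concat_tokens()
            if est > max_concat_tokens:
                raise ConfigError(
                    "concatenation with the hierarchical encoder rejected: "
                    f"estimated concatenated length {est} tokens exceeds the "
                    f"cap of {max_concat_tokens}"
                )

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_jsonl(cls, path, **kwargs) -> "CaseContextModel":
        from .corpus import build_cases, read_reports_jsonl

        return cls(build_cases(read_reports_jsonl(path)), **kwargs)

    @classmethod
    def from_synthetic(cls, config=None, **kwargs) -> "CaseContextModel":
        from .synthetic import SynthConfig, generate_token_corpus

        cfg = config or SynthConfig()
        cases, _ = generate_token_corpus(cfg)
        kwargs.setdefault("task", cfg.task)
        return cls(cases, **kwargs)

    # -- internals --------------------------------------------------------

    def _estimated_concat_tokens(self) -> int:
        lengths = [len(r.text.split()) for c in self.cases for r in c]
        max_case = max(len(c) for c in self.cases)
        return int(np.mean(lengths) * max_case) if lengths else 0

    def _n_classes(self) -> int:
        labels = {
            r.label(self.task)
            for c in self.cases
            for r in c
            if r.label(self.task) is not None
        }
        if not labels:
            raise ConfigError(f"no labels for task {self.task!r}")
        return max(labels) + 1

    def _build_encoder(self, vocab_size: int, pad_id: int, seed: int):
        if self.encoder_name == "cnn":
            return TextCnn(
                vocab_size,
                embed_dim=self.embed_dim,
                output_dim=self.dim,
                pad_id=pad_id,
                seed=seed,
            )
        return HiSanLite(
            vocab_size, output_dim=self.dim, heads=self.heads, pad_id=pad_id, seed=seed
        )

    def _build_context(self, seed: int):
        causal = self.scenario == "unidirectional"
        if self.context_name in ("gru", "gru_crf"):
            return GruContext(
                self.dim, self.dim, bidirectional=not causal, seed=seed
            )
        if self.context_name in ("attn", "attn_crf"):
            return SelfAttentionContext(
                dim=self.dim,
                heads=self.heads,
                causal=causal,
                max_seq_len=self.max_seq_len,
                attn_scale=self.attn_scale,
                seed=seed,
            )
        return IdentityContext(self.dim)

    def _build_head(self, input_dim: int, n_classes: int, seed: int):
        if self.context_name.endswith("_crf"):
            return CrfHead(input_dim, n_classes, seed=seed)
        return SoftmaxHead(input_dim, n_classes, seed=seed)

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        config: TrainConfig | None = None,
        eval_reps: int = 1000,
        pretrained: EncoderClassifier | None = None,
    ) -> "CaseContextResults":
        config = config or TrainConfig()
        seed = config.seed
        split = self.split or split_by_date(
            self.cases, cutoff_year=self.cutoff_year, seed=seed
        )
        train_cases = self.cases.subset(split.train)
        val_cases = self.cases.subset(split.val)
        test_cases = self.cases.subset(split.test)
        vocab = build_vocab(
            (clean_text(r.text) for c in self.cases for r in c),
            min_count=self.min_count,
        )
        docs = {
            r.report_id: tokenize_document(r.text, vocab)
            for c in self.cases
            for r in c
        }
        n_classes = self._n_classes()
        encoder = (
            pretrained.encoder
            if pretrained is not None
            else self._build_encoder(len(vocab), vocab.pad_id, seed)
        )
        context = self._build_context(seed + 2)
        head = self._build_head(context.output_dim, n_classes, seed + 3)

        encoder_log = context_log = TrainLog()
        pipeline = None
        if self.context_name == "none":
            clf = pretrained
            if clf is None:
                clf, encoder_log = train_encoder(
                    encoder, n_classes, train_cases, val_cases, docs, self.task, config
                )
            predict = lambda case_docs: clf.predict(case_docs)
            pipeline = clf
        elif self.context_name == "concat":
            mode = "all" if self.scenario == "bidirectional" else "previous"
            enc_head = SoftmaxHead(encoder.output_dim, n_classes, seed=seed + 3)
            concat_clf = ConcatClassifier(encoder, enc_head, vocab.separator_id, mode)
            train_items = concat_clf.training_items(
                *_case_docs_labels(train_cases, docs, self.task)
            )
            val_case_items = case_items(val_cases, docs, self.task)

            def val_acc():
                correct = total = 0
                for ds, ys in val_case_items:
                    pred = concat_clf.predict_case(ds)
                    valid = ys >= 0
                    correct += int(np.sum(pred[valid] == ys[valid]))
                    total += int(valid.sum())
                return correct / max(total, 1)

            context_log = fit_with_early_stopping(
                concat_clf, train_items, val_acc, config
            )
            predict = concat_clf.predict_case
            pipeline = concat_clf
        elif self.regime == "modular":
            pipeline = train_modular(
                encoder,
                context,
                head,
                n_classes,
                train_cases,
                val_cases,
                docs,
                self.task,
                config,
                pretrained=pretrained,
            )
            encoder_log = pipeline.encoder_log
            context_log = pipeline.context_log
            ctx_clf = ContextClassifier(pipeline.context, pipeline.head)
        else:  # end_to_end
            if pretrained is None:
                pre_clf, encoder_log = train_encoder(
                    encoder, n_classes, train_cases, val_cases, docs, self.task, config
                )
            else:
                import copy

                pre_clf = copy.deepcopy(pretrained)  # joint phase mutates it
            clf, context_log = train_end_to_end(
                pre_clf, context, head, train_cases, val_cases, docs, self.task, config
            )
            predict = clf.predict_case
            pipeline = clf

        # -- test-set predictions, one row per report ----------------------
        rows = []
        for case in test_cases:
            ys = np.array(
                [
                    r.label(self.task) if r.label(self.task) is not None else -1
                    for r in case
                ]
            )
            if self.context_name == "none":
                case_docs = [docs[r.report_id] for r in case]
                preds = predict(case_docs)
            elif self.context_name == "concat":
                preds = predict([docs[r.report_id] for r in case])
            elif self.regime == "modular":
                seq = np.stack(
                    [pipeline.embeddings[r.report_id] for r in case]
                ).astype(np.float64)
                preds = ctx_clf.predict_sequence(seq)
            else:
                preds = predict([docs[r.report_id] for r in case])
            for r, y, p in zip(case.reports, ys, preds):
                rows.append(
                    {
                        "report_id": r.report_id,
                        "tumor_id": case.tumor_id,
                        "task": self.task,
                        "true_label": int(y),
                        "pred_label": int(p),
                    }
                )
        predictions = pd.DataFrame(rows)
        labelled = predictions[predictions["true_label"] >= 0]
        report = evaluate_predictions(
            labelled["true_label"].to_numpy(),
            labelled["pred_label"].to_numpy(),
            reps=eval_reps,
            seed=seed,
        )
        return CaseContextResults(
            model=self,
            predictions=predictions,
            report=report,
            encoder_log=encoder_log,
            context_log=context_log,
            pipeline=pipeline,
            vocab=vocab,
            split=split,
            config=config,
        )


def _case_docs_labels(cases, docs, task):
    all_docs, labels = [], []
    for case in cases:
        ds = [docs[r.report_id] for r in case]
        y = case.shared_label(task)
        if y is None:
            continue
        all_docs.append(ds)
        labels.append(y)
    return all_docs, labels


@dataclass
class CaseContextResults:
    """Fitted pipeline with test-set predictions and evaluation."""

    model: CaseContextModel
    predictions: pd.DataFrame
    report: EvalReport
    encoder_log: TrainLog
    context_log: TrainLog
    pipeline: object
    vocab: Vocab
    split: DatasetSplit
    config: TrainConfig

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    @property
    def macro_f1(self) -> float:
        return self.report.macro_f1

    @property
    def transition_matrix(self) -> np.ndarray | None:
        """The learned CRF transition matrix, if the head is a CRF."""
        head = getattr(self.pipeline, "head", None)
        if isinstance(head, CrfHead):
            return head.transitions.data.copy()
        return None

    def compare(self, other: "CaseContextResults") -> McNemarResult:
        """McNemar's test against another fit on the same test reports."""
        a = self.predictions.set_index("report_id")
        b = other.predictions.set_index("report_id")
        joined = a.join(b["pred_label"], rsuffix="_b", how="inner")
        labelled = joined[joined["true_label"] >= 0]
        return evaluation.mcnemar(
            labelled["pred_label"].to_numpy(),
            labelled["pred_label_b"].to_numpy(),
            labelled["true_label"].to_numpy(),
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "Case-Level Context Classification Results",
            "=" * 45,
            f"task:            {m.task}",
            f"encoder:         {m.encoder_name}",
            f"context:         {m.context_name}",
            f"scenario:        {m.scenario}",
            f"regime:          {m.regime}",
            f"dim / heads:     {m.dim} / {m.heads}",
            f"test reports:    {self.report.n}",
            "-" * 45,
            f"accuracy:        {100 * self.report.accuracy:.2f}%"
            f"  (95% CI {100 * self.report.accuracy_ci[0]:.2f},"
            f" {100 * self.report.accuracy_ci[1]:.2f})",
            f"macro F-score:   {100 * self.report.macro_f1:.2f}%"
            f"  (95% CI {100 * self.report.macro_f1_ci[0]:.2f},"
            f" {100 * self.report.macro_f1_ci[1]:.2f})",
            f"bootstrap reps:  {self.report.reps} (seed {self.report.seed})",
            "-" * 45,
            f"best epoch (context stage): {self.context_log.best_epoch}"
            if self.context_log.train_loss
            else f"best epoch (encoder stage): {self.encoder_log.best_epoch}",
        ]
        return "\n".join(lines)
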