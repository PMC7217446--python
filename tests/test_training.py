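"""Early stopping, the modular freeze contract, and end-to-end fine-tuning.

Training-regime behaviour is exercised on a deliberately tiny synthetic
corpus (60 cases, dimension 8) so each test trains in seconds; the
full-scale behaviour is covered by the acceptance suite.
"""

import numpy as np
import pytest

from caseseq.autodiff import parameter
from caseseq.context import SelfAttentionContext
from caseseq.corpus import split_by_date
from caseseq.encoders import TextCnn
from caseseq.heads import SoftmaxHead
from caseseq.preprocess import build_vocab, clean_text, tokenize_document
from caseseq.synthetic import SynthConfig, generate_token_corpus
from caseseq.training import (
    ContextClassifier,
    TrainConfig,
    fit_with_early_stopping,
    load_checkpoint,
    save_checkpoint,
    train_encoder,
    train_modular,
)


class ScriptedModel:
    """Minimal trainable whose parameter drifts one Adam step per batch."""

    def __init__(self):
        self.p = parameter(np.array([0.0]))

    def parameters(self):
        return [self.p]

    def loss_on_batch(self, batch):
        return (self.p * 1.0).sum()  # constant gradient of 1


class TestEarlyStopping:
    def test_patience_five_restores_best_epoch(self):
        """Scripted validation accuracies [.5,.6,.6,.6,.6,.6,.6]: training
        stops after epoch 7 and restores the epoch-2 parameters."""
        model = ScriptedModel()
        accs = iter([0.5, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6])
        snapshots = {}
        epoch_counter = {"i": 0}

        def val_fn():
            epoch_counter["i"] += 1
            snapshots[epoch_counter["i"]] = model.p.data.copy()
            return next(accs)

        config = TrainConfig(patience=5, max_epochs=50, batch_size=1, seed=0)
        log = fit_with_early_stopping(model, [1, 2, 3], val_fn, config)
        assert log.best_epoch == 2
        assert log.stop_epoch == 7
        assert log.stop_epoch - log.best_epoch == config.patience
        assert np.array_equal(model.p.data, snapshots[2])

    def test_monotone_improvement_runs_to_cap(self):
        model = ScriptedModel()
        accs = iter(np.linspace(0.1, 0.9, 100))
        config = TrainConfig(patience=5, max_epochs=6, batch_size=1, seed=0)
        log = fit_with_early_stopping(model, [1], lambda: next(accs), config)
        assert log.stop_epoch == 6 and log.best_epoch == 6

    def test_empty_train_set_rejected(self):
        with pytest.raises(ValueError, match="empty train"):
            fit_with_early_stopping(ScriptedModel(), [], lambda: 0.0, TrainConfig())

    def test_fixed_seed_reproduces_log(self, tiny_setup):
        cases, sp, docs, vocab = tiny_setup
        logs = []
        for _ in range(2):
            enc = TextCnn(vocab_size=len(vocab), embed_dim=8, output_dim=8, seed=3)
            _, log = train_encoder(
                enc, 3, cases.subset(sp.train), cases.subset(sp.val), docs,
                "site", TrainConfig(max_epochs=3, seed=5, learning_rate=1e-3),
            )
            logs.append((log.train_loss, log.val_accuracy))
        assert logs[0] == logs[1]


@pytest.fixture(scope="module")
def tiny_setup():
    cfg = SynthConfig(num_cases=60, num_classes=3, tokens_per_report=15, seed=13)
    cases, _ = generate_token_corpus(cfg)
    sp = split_by_date(cases, seed=0)
    vocab = build_vocab((clean_text(r.text) for c in cases for r in c), min_count=2)
    docs = {r.report_id: tokenize_document(r.text, vocab) for c in cases for r in c}
    return cases, sp, docs, vocab


class TestModularRegime:
    def test_encoder_frozen_during_context_step(self, tiny_setup):
        cases, sp, docs, vocab = tiny_setup
        enc = TextCnn(vocab_size=len(vocab), embed_dim=8, output_dim=8, seed=1)
        ctx = SelfAttentionContext(dim=8, heads=2, seed=2)
        head = SoftmaxHead(8, 3, seed=3)
        config = TrainConfig(max_epochs=2, seed=0, learning_rate=1e-3)
        train_c, val_c = cases.subset(sp.train), cases.subset(sp.val)
        pipeline = train_modular(
            enc, ctx, head, 3, train_c, val_c, docs, "site", config
        )
        before = [p.data.copy() for p in enc.parameters()]
        # re-run only step 2 from the saved embeddings
        from caseseq.training import embedding_sequence_items

        items = embedding_sequence_items(train_c, pipeline.embeddings, "site")
        clf = ContextClassifier(ctx, head)
        fit_with_early_stopping(
            clf, items, lambda: clf.accuracy(items), config
        )
        after = [p.data for p in enc.parameters()]
        for a, b in zip(before, after):
            assert np.array_equal(a, b)  # bit-identical

    def test_step_two_reproducible_from_saved_embeddings(self, tiny_setup):
        cases, sp, docs, vocab = tiny_setup
        config = TrainConfig(max_epochs=2, seed=0, learning_rate=1e-3)
        from caseseq.training import embedding_sequence_items

        accs = []
        store = None
        for _ in range(2):
            enc = TextCnn(vocab_size=len(vocab), embed_dim=8, output_dim=8, seed=1)
            ctx = SelfAttentionContext(dim=8, heads=2, seed=2)
            head = SoftmaxHead(8, 3, seed=3)
            pipeline = train_modular(
                enc, ctx, head, 3, cases.subset(sp.train), cases.subset(sp.val),
                docs, "site", config,
            )
            store = pipeline.embeddings
            val = embedding_sequence_items(cases.subset(sp.val), store, "site")
            accs.append(ContextClassifier(ctx, head).accuracy(val))
        assert accs[0] == accs[1]

    def test_loss_decreases_over_first_epochs(self, tiny_setup):
        cases, sp, docs, vocab = tiny_setup
        enc = TextCnn(vocab_size=len(vocab), embed_dim=8, output_dim=8, seed=4)
        _, log = train_encoder(
            enc, 3, cases.subset(sp.train), cases.subset(sp.val), docs, "site",
            TrainConfig(max_epochs=5, seed=1, learning_rate=1e-3, patience=5),
        )
        assert log.train_loss[-1] < log.train_loss[0]


class TestEndToEnd:
    def test_encoder_parameters_move_and_gradient_reaches_embeddings(self, tiny_setup):
        cases, sp, docs, vocab = tiny_setup
        from caseseq.training import train_end_to_end, EncoderClassifier

        enc = TextCnn(vocab_size=len(vocab), embed_dim=8, output_dim=8, seed=6)
        pre = EncoderClassifier(enc, SoftmaxHead(8, 3, seed=7))
        ctx = SelfAttentionContext(dim=8, heads=2, seed=8)
        head = SoftmaxHead(8, 3, seed=9)
        before = enc.embeddings.data.copy()
        clf, _ = train_end_to_end(
            pre, ctx, head, cases.subset(sp.train), cases.subset(sp.val), docs,
            "site", TrainConfig(max_epochs=2, seed=2, learning_rate=1e-3),
        )
        assert not np.array_equal(before, enc.embeddings.data)

    def test_unidirectional_training_preserves_causality(self, tiny_setup):
        cases, sp, docs, vocab = tiny_setup
        from caseseq.training import embedding_sequence_items
        from caseseq.context import run_self_attention

        enc = TextCnn(vocab_size=len(vocab), embed_dim=8, output_dim=8, seed=10)
        ctx = SelfAttentionContext(dim=8, heads=2, causal=True, seed=11)
        head = SoftmaxHead(8, 3, seed=12)
        pipeline = train_modular(
            enc, ctx, head, 3, cases.subset(sp.train), cases.subset(sp.val),
            docs, "site", TrainConfig(max_epochs=2, seed=3, learning_rate=1e-3),
        )
        rng = np.random.default_rng(0)
        e = rng.normal(size=(5, 8))
        base = run_self_attention(e, ctx)
        e2 = e.copy()
        e2[3:] = rng.normal(size=(2, 8))
        assert np.array_equal(base[:3], run_self_attention(e2, ctx)[:3])


class TestLongCaseTruncation:
    def test_overlong_case_truncated_oldest_first_with_warning(self):
        from caseseq.context import SelfAttentionContext as Attn
        from caseseq.heads import SoftmaxHead as Head
        from caseseq.training import ContextClassifier

        ctx = Attn(dim=4, heads=2, max_seq_len=3, seed=0)
        clf = ContextClassifier(ctx, Head(4, 2, seed=1))
        seq = np.random.default_rng(0).normal(size=(5, 4))
        with pytest.warns(UserWarning, match="truncated oldest-first"):
            preds = clf.predict_sequence(seq)
        assert len(preds) == 5
        # dropped oldest positions inherit the earliest retained prediction
        assert preds[0] == preds[1] == preds[2]


class TestCheckpoint:
    def test_round_trip_restores_parameters(self, tmp_path):
        enc = TextCnn(vocab_size=50, embed_dim=4, output_dim=6, seed=0)
        clf_head = SoftmaxHead(6, 3, seed=1)
        from caseseq.training import EncoderClassifier

        clf = EncoderClassifier(enc, clf_head)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, clf, TrainConfig())
        originals = [p.data.copy() for p in clf.parameters()]
        for p in clf.parameters():
            p.data = p.data + 1.0
        meta = load_checkpoint(path, clf)
        assert meta["n_params"] == len(originals)
        for p, orig in zip(clf.parameters(), originals):
            assert np.array_equal(p.data, orig)

    def test_mismatched_model_rejected(self, tmp_path):
        from caseseq.training import EncoderClassifier

        a = EncoderClassifier(
            TextCnn(vocab_size=50, embed_dim=4, output_dim=6, seed=0),
            SoftmaxHead(6, 3, seed=1),
        )
        b = SoftmaxHead(6, 3, seed=1)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, a)
        with pytest.raises(ValueError):
            load_checkpoint(path, b)
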