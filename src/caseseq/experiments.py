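"""Canned synthetic experiments: context uplift and regime comparison.

These bundle the full pipeline — generate a synthetic case corpus, pretrain
the CNN encoder on individual reports, then train context mechanisms on its
frozen embeddings — under one fixed set of scaled-down study conditions:
2,000 cases of 4 classes at model dimension 32. The optimizer settings
differ from the full-scale reference configuration only in learning rate
(1e-3) and epoch cap (40), matched to a corpus roughly two orders of
magnitude smaller than a registry corpus (see docs/methods.md).

Expected structure of the results: the per-report baseline lands near its
signal ceiling (1 - addendum_rate) + addendum_rate/K; bidirectional
self-attention context recovers addendum reports from their neighbours and
approaches 1; unidirectional (causal) context falls strictly between,
because early addenda have no visible signal yet.
"""

from __future__ import annotations

from dataclasses import dataclass

from .heads import transition_diagnostic
from .model import CaseContextModel
from .synthetic import SynthConfig, generate_token_corpus
from .training import TrainConfig

#: Scaled-down study conditions shared by tests and the acceptance script.
UPLIFT_NUM_CASES = 2000
UPLIFT_NUM_CLASSES = 4
UPLIFT_DIM = 32
UPLIFT_HEADS = 4
UPLIFT_LR = 1e-3
UPLIFT_MAX_EPOCHS = 40


@dataclass
class UpliftResult:
    """Accuracies of baseline vs context mechanisms on one synthetic corpus."""

    seed: int
    baseline_accuracy: float
    unidirectional_accuracy: float
    bidirectional_accuracy: float
    crf_accuracy: float
    signal_ceiling: float
    transition_diag_minus_offdiag: float
    mcnemar_p_bi_vs_baseline: float
    n_test_reports: int

    @property
    def ordering_holds(self) -> bool:
        return (
            self.bidirectional_accuracy
            > self.unidirectional_accuracy
            > self.baseline_accuracy
        )


def _train_config(seed: int) -> TrainConfig:
    return TrainConfig(
        learning_rate=UPLIFT_LR, max_epochs=UPLIFT_MAX_EPOCHS, seed=seed
    )


def _corpus(seed: int, num_cases: int):
    cfg = SynthConfig(
        num_cases=num_cases, num_classes=UPLIFT_NUM_CLASSES, seed=seed
    )
    return cfg, generate_token_corpus(cfg)[0]


def run_context_uplift(
    seed: int, num_cases: int = UPLIFT_NUM_CASES, eval_reps: int = 200
) -> UpliftResult:
    """Baseline CNN vs masked/unmasked self-attention context (+ CRF)."""
    cfg, cases = _corpus(seed, num_cases)
    tc = _train_config(seed)
    kw = dict(
        task=cfg.task, encoder="cnn", dim=UPLIFT_DIM, heads=UPLIFT_HEADS
    )
    base = CaseContextModel(cases, context="none", **kw).fit(tc, eval_reps=eval_reps)
    pre = base.pipeline
    bi = CaseContextModel(cases, context="attn", scenario="bidirectional", **kw).fit(
        tc, eval_reps=eval_reps, pretrained=pre
    )
    uni = CaseContextModel(cases, context="attn", scenario="unidirectional", **kw).fit(
        tc, eval_reps=eval_reps, pretrained=pre
    )
    crf = CaseContextModel(
        cases, context="attn_crf", scenario="bidirectional", **kw
    ).fit(tc, eval_reps=eval_reps, pretrained=pre)
    return UpliftResult(
        seed=seed,
        baseline_accuracy=base.accuracy,
        unidirectional_accuracy=uni.accuracy,
        bidirectional_accuracy=bi.accuracy,
        crf_accuracy=crf.accuracy,
        signal_ceiling=cfg.signal_ceiling,
        transition_diag_minus_offdiag=transition_diagnostic(crf.transition_matrix),
        mcnemar_p_bi_vs_baseline=bi.compare(base).p_value,
        n_test_reports=base.report.n,
    )


@dataclass
class RegimeResult:
    """Modular two-step vs end-to-end training, identical architecture."""

    seed: int
    modular_accuracy: float
    end_to_end_accuracy: float
    n_test_reports: int

    @property
    def gap(self) -> float:
        return abs(self.modular_accuracy - self.end_to_end_accuracy)


def run_regime_comparison(
    seed: int, num_cases: int = UPLIFT_NUM_CASES, eval_reps: int = 200
) -> RegimeResult:
    """Modular vs end-to-end training of CNN + bidirectional attention."""
    cfg, cases = _corpus(seed, num_cases)
    tc = _train_config(seed)
    kw = dict(task=cfg.task, encoder="cnn", dim=UPLIFT_DIM, heads=UPLIFT_HEADS)
    base = CaseContextModel(cases, context="none", **kw).fit(tc, eval_reps=eval_reps)
    pre = base.pipeline
    mod = CaseContextModel(
        cases, context="attn", scenario="bidirectional", regime="modular", **kw
    ).fit(tc, eval_reps=eval_reps, pretrained=pre)
    e2e = CaseContextModel(
        cases, context="attn", scenario="bidirectional", regime="end_to_end", **kw
    ).fit(tc, eval_reps=eval_reps, pretrained=pre)
    return RegimeResult(
        seed=seed,
        modular_accuracy=mod.accuracy,
        end_to_end_accuracy=e2e.accuracy,
        n_test_reports=mod.report.n,
    )
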