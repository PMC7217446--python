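"""Accuracy, macro F-score, bootstrap confidence intervals, McNemar's test.

Accuracy doubles as micro F-score in this single-label setting. Macro
F-score is the unweighted mean of per-class F1 over the classes present in
the ground truth of the evaluated split (a convention that keeps the average
meaningful for tasks with hundreds of schema classes, most absent from any
given split); zero-division components count as 0. Confidence intervals
come from a percentile bootstrap over individual report predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import f1_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar


def _validate(truth, predictions) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth)
    p = np.asarray(predictions)
    if t.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if t.shape != p.shape:
        raise ValueError("truth and predictions are not aligned")
    return t, p


def accuracy(truth: Sequence, predictions: Sequence) -> float:
    """Fraction exactly correct (equals micro F-score for single labels)."""
    t, p = _validate(truth, predictions)
    return float(np.mean(t == p))


def macro_f1(truth: Sequence, predictions: Sequence) -> float:
    """Unweighted mean per-class F1 over classes present in the truth."""
    t, p = _validate(truth, predictions)
    classes = np.unique(t)
    return float(f1_score(t, p, labels=classes, average="macro", zero_division=0))


def micro_f1(truth: Sequence, predictions: Sequence) -> float:
    t, p = _validate(truth, predictions)
    return float(f1_score(t, p, average="micro", zero_division=0))


def bootstrap_ci(
    truth: Sequence,
    predictions: Sequence,
    metric: Callable[[np.ndarray, np.ndarray], float] = accuracy,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% percentile bootstrap interval for a metric.

    Prediction-truth pairs are resampled with replacement to the original
    size ``reps`` times; the interval is the 2.5 and 97.5 percentile of the
    resampled metric values (F-score is not normally distributed, so
    percentiles rather than a normal approximation).
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    t, p = _validate(truth, predictions)
    rng = np.random.default_rng(seed)
    n = t.shape[0]
    values = np.empty(reps)
    for i in range(reps):
        idx = rng.integers(0, n, size=n)
        values[i] = metric(t[idx], p[idx])
    return float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5))


@dataclass
class McNemarResult:
    """Paired comparison of two classifiers' errors on the same test set."""

    b: int  # A right, B wrong
    c: int  # A wrong, B right
    p_value: float
    method: str

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def mcnemar(
    predictions_a: Sequence,
    predictions_b: Sequence,
    truth: Sequence,
    exact_threshold: int = 25,
) -> McNemarResult:
    """McNemar's test on discordant pairs.

    Exact two-sided binomial when b + c < ``exact_threshold``, otherwise the
    continuity-corrected chi-square statistic (|b-c|-1)^2 / (b+c).
    """
    t, pa = _validate(truth, predictions_a)
    _, pb = _validate(truth, predictions_b)
    right_a = pa == t
    right_b = pb == t
    b = int(np.sum(right_a & ~right_b))
    c = int(np.sum(~right_a & right_b))
    if b + c == 0:
        return McNemarResult(b=b, c=c, p_value=1.0, method="degenerate")
    table = [[int(np.sum(right_a & right_b)), b], [c, int(np.sum(~right_a & ~right_b))]]
    exact = (b + c) < exact_threshold
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return McNemarResult(
        b=b, c=c, p_value=float(res.pvalue), method="exact" if exact else "chi2"
    )


@dataclass
class EvalReport:
    """Point metrics with bootstrap intervals for one model on one task."""

    accuracy: float
    macro_f1: float
    accuracy_ci: tuple[float, float]
    macro_f1_ci: tuple[float, float]
    n: int
    reps: int
    seed: int
    point_outside_ci: bool = False

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "accuracy_ci": list(self.accuracy_ci),
            "macro_f1_ci": list(self.macro_f1_ci),
            "n": self.n,
            "reps": self.reps,
            "seed": self.seed,
            "point_outside_ci": self.point_outside_ci,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_predictions(
    truth: Sequence, predictions: Sequence, reps: int = 1000, seed: int = 0
) -> EvalReport:
    """Full evaluation: both metrics with 95% bootstrap intervals."""
    t, p = _validate(truth, predictions)
    acc = accuracy(t, p)
    mf1 = macro_f1(t, p)
    acc_ci = bootstrap_ci(t, p, accuracy, reps=reps, seed=seed)
    f1_ci = bootstrap_ci(t, p, macro_f1, reps=reps, seed=seed)
    outside = not (
        acc_ci[0] <= acc <= acc_ci[1] and f1_ci[0] <= mf1 <= f1_ci[1]
    )
    return EvalReport(
        accuracy=acc,
        macro_f1=mf1,
        accuracy_ci=acc_ci,
        macro_f1_ci=f1_ci,
        n=int(t.shape[0]),
        reps=reps,
        seed=seed,
        point_outside_ci=outside,
    )
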