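"""Synthetic case corpora with the structure that makes case-level context pay.

The generator emulates the statistical shape of a tumor-registry corpus
without mimicking clinical language: cases average 3.2 reports (shifted
geometric length, minimum 2, mirroring singleton filtering); every report in
a case shares the case's aggregate label; a configurable fraction of reports
are *addenda* carrying no label evidence at all; and with probability
``cue_split_rate`` the label's two cue tokens are distributed across
different reports of the case, so the evidence for the label is spread over
the sequence.

Each class owns two unique cue tokens, so any single cue token identifies
the class. The per-report signal ceiling is therefore

    (1 - addendum_rate) + addendum_rate / K

— a per-report classifier can do no better, because addendum reports are
pure background noise. Context models recover addenda from their neighbours,
which is exactly the gap the context mechanisms are meant to close.
Background text is Zipf-distributed over a fixed vocabulary so that
rare-token collapsing is exercised.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .corpus import CaseSet, Report, build_cases

DEFAULT_TASK = "site"


@dataclass
class SynthConfig:
    """Study conditions for the synthetic corpus."""

    num_cases: int = 2000
    num_classes: int = 4
    mean_case_length: float = 3.2
    min_case_length: int = 2
    addendum_rate: float = 0.3
    cue_split_rate: float = 0.5
    background_vocab: int = 2000
    tokens_per_report: int = 30
    label_noise: float = 0.0
    lines_per_report: int = 3
    task: str = DEFAULT_TASK
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_case_length < self.min_case_length:
            raise ValueError("mean case length below the minimum length")
        for name in ("addendum_rate", "cue_split_rate", "label_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def signal_ceiling(self) -> float:
        """Best possible per-report accuracy without case-level context."""
        return (1.0 - self.addendum_rate) + self.addendum_rate / self.num_classes


@dataclass
class GroundTruth:
    """Per-case aggregate labels and per-report signal flags."""

    case_labels: dict[str, int]
    signal_flags: dict[str, bool]  # report_id -> carries label evidence

    def is_addendum(self, report_id: str) -> bool:
        return not self.signal_flags[report_id]


def cue_tokens(task: str, label: int) -> tuple[str, str]:
    """The two unique cue tokens owned by a class."""
    return (f"cue{task}{label}x", f"cue{task}{label}y")


def _case_length(rng: np.random.Generator, cfg: SynthConfig) -> int:
    # length = min + (Geometric(p) - 1); mean = min - 1 + 1/p
    p = 1.0 / (cfg.mean_case_length - cfg.min_case_length + 1.0)
    return cfg.min_case_length + int(rng.geometric(p)) - 1


def _background(rng: np.random.Generator, cfg: SynthConfig, n: int) -> list[str]:
    ranks = np.arange(1, cfg.background_vocab + 1, dtype=np.float64)
    probs = ranks**-1.1
    probs /= probs.sum()
    draws = rng.choice(cfg.background_vocab, size=n, p=probs)
    return [f"w{int(i):04d}" for i in draws]


def _render_text(rng: np.random.Generator, tokens: list[str], lines: int) -> str:
    """Join tokens into a few natural lines (line structure for the HiSAN)."""
    if lines <= 1 or len(tokens) <= lines:
        return " ".join(tokens)
    cuts = sorted(rng.choice(np.arange(1, len(tokens)), size=lines - 1, replace=False))
    pieces, prev = [], 0
    for c in list(cuts) + [len(tokens)]:
        pieces.append(" ".join(tokens[prev:c]))
        prev = c
    return "\n".join(pieces)


def generate_token_corpus(cfg: SynthConfig) -> tuple[CaseSet, GroundTruth]:
    """Generate a labelled report corpus as date-ordered cases.

    Every case has at least one signal report; each signal report carries
    both of its class's cue tokens, unless the case's cue pair is split, in
    which case each signal report carries exactly one of the two.
    """
    if cfg.num_classes < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(cfg.seed)
    reports: list[Report] = []
    case_labels: dict[str, int] = {}
    signal_flags: dict[str, bool] = {}
    for ci in range(cfg.num_cases):
        tumor_id = f"T{ci:06d}"
        label = int(rng.integers(cfg.num_classes))
        case_labels[tumor_id] = label
        length = _case_length(rng, cfg)
        addendum = rng.random(length) < cfg.addendum_rate
        if addendum.all():
            addendum[int(rng.integers(length))] = False
        split = rng.random() < cfg.cue_split_rate and (~addendum).sum() >= 2
        cue_a, cue_b = cue_tokens(cfg.task, label)
        start = _dt.date(2004, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 4748)))
        date = start
        for ri in range(length):
            rid = f"R{ci:06d}n{ri:02d}"
            tokens = _background(rng, cfg, cfg.tokens_per_report)
            if not addendum[ri]:
                if split:
                    cues = [cue_a if rng.random() < 0.5 else cue_b]
                else:
                    cues = [cue_a, cue_b]
                for cue in cues:
                    pos = int(rng.integers(0, len(tokens) + 1))
                    tokens.insert(pos, cue)
            signal_flags[rid] = not bool(addendum[ri])
            y = label
            if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
                y = int(rng.integers(cfg.num_classes))
            reports.append(
                Report(
                    report_id=rid,
                    tumor_id=tumor_id,
                    date=date,
                    text=_render_text(rng, tokens, cfg.lines_per_report),
                    labels={cfg.task: y},
                )
            )
            date = date + _dt.timedelta(days=int(rng.integers(30, 120)))
    cases = build_cases(reports, min_length=cfg.min_case_length)
    return cases, GroundTruth(case_labels=case_labels, signal_flags=signal_flags)


@dataclass
class EmbeddingSequences:
    """Pre-encoded embedding sequences: one (n_i, dim) array per case."""

    sequences: list[np.ndarray]
    labels: list[int]
    signal_flags: list[np.ndarray]
    centroids: np.ndarray
    addendum_centroid: np.ndarray
    noise_sd: float

    def __len__(self) -> int:
        return len(self.sequences)


def generate_embedding_sequences(
    cfg: SynthConfig,
    dim: int = 32,
    centroid_distance: float = 4.0,
    noise_sd: float = 1.0,
) -> EmbeddingSequences:
    """Generate embedding-sequence data directly (no encoder needed).

    Signal reports are drawn around their class centroid, addenda around a
    shared background centroid at the origin; centroids sit at pairwise
    distance ``centroid_distance``. With well-separated centroids the
    per-report Bayes accuracy approaches the signal ceiling
    (1 - addendum_rate) + addendum_rate / K.
    """
    if dim < cfg.num_classes:
        raise ValueError("dim must be at least the number of classes")
    rng = np.random.default_rng(cfg.seed)
    centroids = np.zeros((cfg.num_classes, dim))
    for y in range(cfg.num_classes):
        centroids[y, y] = centroid_distance / np.sqrt(2.0)
    mu0 = np.zeros(dim)
    sequences, labels, flags = [], [], []
    for _ in range(cfg.num_cases):
        label = int(rng.integers(cfg.num_classes))
        length = _case_length(rng, cfg)
        addendum = rng.random(length) < cfg.addendum_rate
        if addendum.all():
            addendum[int(rng.integers(length))] = False
        means = np.where(addendum[:, None], mu0[None, :], centroids[label][None, :])
        seq = means + rng.normal(0.0, noise_sd, size=(length, dim))
        sequences.append(seq)
        labels.append(label)
        flags.append(~addendum)
    return EmbeddingSequences(
        sequences=sequences,
        labels=labels,
        signal_flags=flags,
        centroids=centroids,
        addendum_centroid=mu0,
        noise_sd=noise_sd,
    )
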