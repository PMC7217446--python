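"""Data model and I/O for pathology reports, case sequences, and dataset splits.

A *case* is the ordered sequence of all reports sharing one tumor ID. Cancer
registries assign aggregate labels (site, subsite, laterality, histology,
behavior, grade) to the tumor ID, so every report in a case carries the same
per-task labels. Cases with a single report need no case-level context and are
filtered out before modelling.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

#: The six SEER classification tasks.
TASKS = ("site", "subsite", "laterality", "histology", "behavior", "grade")


class CorpusError(ValueError):
    """Record-level corpus problem; carries the offending report_id."""

    def __init__(self, message: str, report_id: str | None = None):
        super().__init__(message)
        self.report_id = report_id


@dataclass(frozen=True)
class Report:
    """One clinical report with its registry labels.

    ``labels`` maps task name to an integer class id, or ``None`` when the
    label is explicitly missing; missing labels exclude the report from that
    task's loss and metrics.
    """

    report_id: str
    tumor_id: str
    date: _dt.date
    text: str
    labels: Mapping[str, int | None] = field(default_factory=dict)

    def label(self, task: str) -> int | None:
        return self.labels.get(task)


@dataclass
class CaseSequence:
    """All reports of one tumor ID, ascending by date."""

    tumor_id: str
    reports: list[Report]

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self.reports)

    def labels(self, task: str) -> list[int | None]:
        return [r.label(task) for r in self.reports]

    def shared_label(self, task: str) -> int | None:
        """The case's aggregate label, or raise if reports disagree."""
        seen = {y for y in self.labels(task) if y is not None}
        if len(seen) > 1:
            raise CorpusError(
                f"labels differ within case {self.tumor_id} for task {task!r}: {sorted(seen)}"
            )
        return next(iter(seen)) if seen else None


@dataclass
class CaseSet:
    """A collection of case sequences."""

    cases: list[CaseSequence]

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self) -> Iterator[CaseSequence]:
        return iter(self.cases)

    @property
    def n_reports(self) -> int:
        return sum(len(c) for c in self.cases)

    @property
    def tumor_ids(self) -> list[str]:
        return [c.tumor_id for c in self.cases]

    def subset(self, tumor_ids: Iterable[str]) -> "CaseSet":
        wanted = set(tumor_ids)
        return CaseSet([c for c in self.cases if c.tumor_id in wanted])


@dataclass
class CaseStats:
    n_reports: int
    n_cases: int
    mean_reports_per_case: float
    length_histogram: dict[int, int]

    @property
    def mean_rounded(self) -> float:
        """Mean reports per case at presentation precision (one decimal)."""
        return round(self.mean_reports_per_case, 1)


@dataclass
class DatasetSplit:
    """Disjoint train/val/test partitions of tumor IDs."""

    train: set[str]
    val: set[str]
    test: set[str]
    cutoff_year: int = 2016

    def __post_init__(self) -> None:
        if (self.train & self.val) or (self.train & self.test) or (self.val & self.test):
            raise ValueError("split sets must be disjoint")

    def assignment(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for name in ("train", "val", "test"):
            for tid in getattr(self, name):
                out[tid] = name
        return out

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["tumor_id", "split"])
            for tid, name in sorted(self.assignment().items()):
                writer.writerow([tid, name])

    @classmethod
    def load(cls, path: str | Path, cutoff_year: int = 2016) -> "DatasetSplit":
        sets: dict[str, set[str]] = {"train": set(), "val": set(), "test": set()}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                sets[row["split"]].add(row["tumor_id"])
        return cls(cutoff_year=cutoff_year, **sets)


def _parse_date(value: str, report_id: str) -> _dt.date:
    """ISO-8601 date; bare years are accepted at year granularity."""
    value = str(value).strip()
    try:
        if len(value) == 4 and value.isdigit():
            return _dt.date(int(value), 1, 1)
        return _dt.date.fromisoformat(value[:10])
    except ValueError as exc:
        raise CorpusError(f"unparseable date {value!r}", report_id=report_id) from exc


def read_reports_jsonl(path: str | Path) -> list[Report]:
    """Read a JSON-Lines corpus: one object per report with keys
    report_id, tumor_id, date, text, labels.{site,...,grade}."""
    reports: list[Report] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            rid = str(obj["report_id"])
            if rid in seen:
                raise CorpusError(f"duplicate report_id at line {lineno}", report_id=rid)
            seen.add(rid)
            labels = {t: obj.get("labels", {}).get(t) for t in TASKS}
            labels = {t: (None if v is None else int(v)) for t, v in labels.items()}
            reports.append(
                Report(
                    report_id=rid,
                    tumor_id=str(obj["tumor_id"]),
                    date=_parse_date(obj["date"], rid),
                    text=str(obj.get("text", "")),
                    labels=labels,
                )
            )
    return reports


def write_reports_jsonl(reports: Iterable[Report], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reports:
            obj = {
                "report_id": r.report_id,
                "tumor_id": r.tumor_id,
                "date": r.date.isoformat(),
                "text": r.text,
                "labels": {t: r.labels.get(t) for t in TASKS},
            }
            fh.write(json.dumps(obj) + "\n")


def build_cases(reports: Sequence[Report], min_length: int = 2) -> CaseSet:
    """Group reports by tumor ID into date-ordered cases, dropping cases
    shorter than ``min_length`` (single-report cases carry no context).

    Date ties break on report_id (stable, lexicographic).
    """
    by_tumor: dict[str, list[Report]] = {}
    for r in reports:
        if not r.tumor_id:
            raise CorpusError("report without tumor_id", report_id=r.report_id)
        by_tumor.setdefault(r.tumor_id, []).append(r)
    cases = []
    for tid in sorted(by_tumor):
        group = sorted(by_tumor[tid], key=lambda r: (r.date, r.report_id))
        if len(group) >= min_length:
            cases.append(CaseSequence(tumor_id=tid, reports=group))
    return CaseSet(cases)


def split_by_date(
    cases: CaseSet,
    cutoff_year: int = 2016,
    train_frac: float = 0.8,
    seed: int = 0,
) -> DatasetSplit:
    """Date-based production split.

    Any case with at least one report dated in or after ``cutoff_year`` goes
    entirely to test; the rest are randomly assigned ``train_frac`` : rest to
    train/val at the case level, so no case straddles two sets.
    """
    if len(cases) == 0:
        raise ValueError("cannot split an empty case set")
    test, remaining = set(), []
    for case in cases:
        if any(r.date.year >= cutoff_year for r in case):
            test.add(case.tumor_id)
        else:
            remaining.append(case.tumor_id)
    rng = np.random.default_rng(seed)
    order = list(np.array(sorted(remaining))[rng.permutation(len(remaining))]) if remaining else []
    n_train = int(round(train_frac * len(order)))
    train, val = set(order[:n_train]), set(order[n_train:])
    if not train:
        warnings.warn("empty train set: all cases fall at or after the cutoff year")
    return DatasetSplit(train=train, val=val, test=test, cutoff_year=cutoff_year)


def case_stats(cases: CaseSet) -> CaseStats:
    """Summary counts: reports, cases, mean reports/case, length histogram."""
    if len(cases) == 0:
        raise ValueError("empty case set")
    hist = Counter(len(c) for c in cases)
    n_reports = cases.n_reports
    return CaseStats(
        n_reports=n_reports,
        n_cases=len(cases),
        mean_reports_per_case=n_reports / len(cases),
        length_histogram=dict(sorted(hist.items())),
    )
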