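import datetime as dt

import numpy as np
import pytest

from caseseq.corpus import CaseSet, Report, build_cases
from caseseq.synthetic import SynthConfig, generate_token_corpus


def make_report(rid, tid, date, text="tumor tissue sample", label=0, task="site"):
    return Report(
        report_id=rid,
        tumor_id=tid,
        date=dt.date.fromisoformat(date),
        text=text,
        labels={task: label},
    )


@pytest.fixture
def toy_cases() -> CaseSet:
    """Three tumor IDs: lengths 3, 2, and a singleton (filtered out)."""
    reports = [
        make_report("r1", "t1", "2010-03-01"),
        make_report("r2", "t1", "2009-01-15"),
        make_report("r3", "t1", "2009-06-20"),
        make_report("r4", "t2", "2015-05-01", label=1),
        make_report("r5", "t2", "2016-02-01", label=1),
        make_report("r6", "t3", "2012-01-01", label=2),
    ]
    return build_cases(reports)


@pytest.fixture(scope="session")
def small_synth():
    """A small synthetic corpus shared by read-only tests."""
    cfg = SynthConfig(num_cases=120, seed=7)
    cases, truth = generate_token_corpus(cfg)
    return cfg, cases, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
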