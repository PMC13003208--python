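"""Shared fixtures: tiny hand-written corpora and small synthetic worlds."""

from __future__ import annotations

from datetime import date

import pytest

from qadiscourse.corpus import Answer, QARecord
from qadiscourse.synthetic import GeneratorConfig, generate_corpus


def make_record(rid, question, answers=(), platform="quora", day=1, url=None):
    return QARecord(
        record_id=rid,
        platform=platform,
        question_text=question,
        question_timestamp=date(2020, 7, day),
        answers=[
            a if isinstance(a, Answer) else Answer(answer_text=a[0], upvotes=a[1])
            for a in answers
        ],
        url=url,
    )


@pytest.fixture
def ten_records():
    """10 records, 4 unanswered, 7 containing the keyword 'vaccine'."""
    recs = []
    for i in range(10):
        kw = "vaccine" if i < 7 else "mask"
        answers = [(f"answer about {kw} {i}", i)] if i % 10 not in (2, 5, 7, 9) else []
        recs.append(make_record(f"r{i}", f"Is the {kw} safe? #{i}", answers, day=i + 1))
    return recs


@pytest.fixture(scope="session")
def small_world():
    """Small 2-topic synthetic corpus with disjoint cores and rho=1."""
    cfg = GeneratorConfig(
        n_records=200,
        n_topics=2,
        shared_vocab_size=0,
        doc_length_range=(30, 80),
        rho=1.0,
        seed=42,
    )
    records, truth = generate_corpus(cfg)
    return cfg, records, truth
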