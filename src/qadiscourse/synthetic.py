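"""Synthetic Q&A corpus generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes:
topic structure (per-topic private vocabularies plus shared noise
vocabulary), per-topic question sentiment mixtures, question->answer
sentiment coupling, month-resolved timestamps with drifting answer
positivity rates (to plant temporal crossovers), and multi-answer
records where one designated "gold" answer carries strictly maximal
upvotes.  Tokens are abstract symbols; no natural-language realism is
attempted.  Sentiment is expressed purely lexically -- polarity tokens
injected at a configured rate -- so the deterministic lexicon scorer
can recover it without trained weights.

Everything is reproducible byte-for-byte from the config (including
its seed).
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .corpus import Answer, QARecord

POSITIVE = "positive"
NEGATIVE = "negative"

_DEFAULT_DATE_RANGE = (date(2020, 6, 27), date(2021, 6, 27))


def _default_pos_lexicon() -> list[str]:
    return [f"upbeatpos{i:02d}" for i in range(15)]


def _default_neg_lexicon() -> list[str]:
    return [f"gloomneg{i:02d}" for i in range(15)]


@dataclass
class GeneratorConfig:
    """Stated world for one synthetic platform-like corpus.

    Defaults mirror the analysed corpora: 3952 records per platform
    collected over 2020-06-27..2021-06-27, 5 topics with the observed
    topic proportions available through :func:`quora_like_config`,
    document lengths 30-400 tokens so that 128-token chunking is
    exercised, and lexical sentiment injection at rate 0.15 with 0.03
    opposite-polarity noise.
    """

    n_records: int = 3952
    n_topics: int = 5
    vocab_size_per_topic: int = 40
    shared_vocab_size: int = 30
    topic_weights: list[float] | None = None  # None -> uniform
    doc_length_range: tuple[int, int] = (30, 400)
    pos_lexicon: list[str] = field(default_factory=_default_pos_lexicon)
    neg_lexicon: list[str] = field(default_factory=_default_neg_lexicon)
    pi_t: list[float] | float = 0.5  # per-topic question-positive probability
    rho: float = 0.7  # question->answer sentiment agreement probability
    month_pos_rate: dict[str, float] | None = None  # month "YYYY-MM" -> P(answer positive)
    injection_rate: float = 0.15
    opposite_injection_rate: float = 0.03
    core_rate: float = 0.8  # topic-core share of non-lexicon tokens
    date_range: tuple[date, date] = _DEFAULT_DATE_RANGE
    answers_per_record_range: tuple[int, int] = (1, 5)
    platform: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1 or self.n_topics < 1:
            raise ValueError("n_records and n_topics must be positive")
        if self.topic_weights is not None:
            w = np.asarray(self.topic_weights, dtype=float)
            if len(w) != self.n_topics:
                raise ValueError("topic_weights length must equal n_topics")
            if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
                raise ValueError("topic_weights must be a probability vector summing to 1")
        if set(self.pos_lexicon) & set(self.neg_lexicon):
            raise ValueError("pos_lexicon and neg_lexicon must be disjoint")
        probs = [self.rho, self.injection_rate, self.opposite_injection_rate, self.core_rate]
        probs += list(self.pi_t) if isinstance(self.pi_t, (list, tuple)) else [self.pi_t]
        if self.month_pos_rate:
            probs += list(self.month_pos_rate.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.injection_rate + self.opposite_injection_rate > 0 and not (
            self.pos_lexicon and self.neg_lexicon
        ):
            raise ValueError("nonzero injection rate requires non-empty lexicons")
        lo, hi = self.doc_length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid doc_length_range {self.doc_length_range}")
        if isinstance(self.date_range[0], str):
            self.date_range = (
                date.fromisoformat(self.date_range[0]),
                date.fromisoformat(self.date_range[1]),
            )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_records": self.n_records,
            "n_topics": self.n_topics,
            "vocab_size_per_topic": self.vocab_size_per_topic,
            "shared_vocab_size": self.shared_vocab_size,
            "topic_weights": self.topic_weights,
            "doc_length_range": list(self.doc_length_range),
            "pos_lexicon": list(self.pos_lexicon),
            "neg_lexicon": list(self.neg_lexicon),
            "pi_t": self.pi_t,
            "rho": self.rho,
            "month_pos_rate": self.month_pos_rate,
            "injection_rate": self.injection_rate,
            "opposite_injection_rate": self.opposite_injection_rate,
            "core_rate": self.core_rate,
            "date_range": [self.date_range[0].isoformat(), self.date_range[1].isoformat()],
            "answers_per_record_range": list(self.answers_per_record_range),
            "platform": self.platform,
            "seed": self.seed,
        }
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "doc_length_range" in d:
            d["doc_length_range"] = tuple(d["doc_length_range"])
        if "answers_per_record_range" in d:
            d["answers_per_record_range"] = tuple(d["answers_per_record_range"])
        if "date_range" in d:
            d["date_range"] = tuple(d["date_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def quora_like_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Platform analogue with 5 topics at the observed Quora proportions.

    Questions lean negative and answers lean negative in four of five
    topics, matching the published sentiment pattern.
    """
    params = dict(
        n_records=3952,
        n_topics=5,
        topic_weights=[978 / 3952, 821 / 3952, 782 / 3952, 743 / 3952, 628 / 3952],
        pi_t=[0.21, 0.24, 0.27, 0.20, 0.24],
        rho=0.7,
        month_pos_rate={
            "2020-07": 0.55, "2020-08": 0.42, "2020-09": 0.56, "2020-10": 0.41,
            "2020-11": 0.44, "2020-12": 0.58, "2021-01": 0.40, "2021-02": 0.45,
            "2021-03": 0.43, "2021-04": 0.47, "2021-05": 0.56, "2021-06": 0.58,
        },
        platform="quora_like",
        seed=seed,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


def naver_like_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Platform analogue with 7 topics at the observed Naver KiN proportions.

    Questions are mixed but answers lean positive, stabilising above
    0.5 after early 2021, matching the published pattern.
    """
    params = dict(
        n_records=3952,
        n_topics=7,
        topic_weights=[
            790 / 3952, 711 / 3952, 592 / 3952, 553 / 3952,
            513 / 3952, 474 / 3952, 319 / 3952,
        ],
        pi_t=[0.59, 0.68, 0.47, 0.48, 0.57, 0.72, 0.55],
        rho=0.7,
        month_pos_rate={
            "2020-07": 0.55, "2020-08": 0.45, "2020-09": 0.58, "2020-10": 0.44,
            "2020-11": 0.57, "2020-12": 0.42, "2021-01": 0.46, "2021-02": 0.62,
            "2021-03": 0.68, "2021-04": 0.70, "2021-05": 0.72, "2021-06": 0.74,
        },
        platform="naver_like",
        seed=seed,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


# -- month helpers -------------------------------------------------------


def _months_in_range(start: date, end: date) -> list[str]:
    months = []
    y, m = start.year, start.month
    while (y, m) <= (end.year, end.month):
        months.append(f"{y:04d}-{m:02d}")
        y, m = (y + 1, 1) if m == 12 else (y, m + 1)
    return months


def _month_days(month: str, window: tuple[date, date]) -> list[date]:
    y, m = int(month[:4]), int(month[5:7])
    first = date(y, m, 1)
    last = date(y, m, calendar.monthrange(y, m)[1])
    lo = max(first, window[0])
    hi = min(last, window[1])
    return [lo + timedelta(days=i) for i in range((hi - lo).days + 1)]


def planted_crossover_count(config_or_rates: GeneratorConfig | dict[str, float]) -> int:
    """Number of consecutive-month pairs where the planted positivity
    rate crosses 0.5 (strict sign flip of rate - 0.5; an exact 0.5
    carries the previous month's sign, a leading 0.5 counts positive).
    """
    if isinstance(config_or_rates, GeneratorConfig):
        rates = config_or_rates.month_pos_rate
        if not rates:
            raise ValueError("config has no month_pos_rate")
    else:
        rates = config_or_rates
    if len(rates) < 2:
        raise ValueError("need month_pos_rate on >= 2 months")
    values = [rates[m] for m in sorted(rates)]
    count = 0
    prev_sign = 1
    for i, v in enumerate(values):
        sign = 1 if v > 0.5 else (-1 if v < 0.5 else prev_sign)
        if i > 0 and sign != prev_sign:
            count += 1
        prev_sign = sign
    return count


# -- generation ----------------------------------------------------------


def _draw_tokens(
    rng: np.random.Generator,
    length: int,
    topic_vocab: list[str],
    shared_vocab: list[str],
    sentiment: str,
    cfg: GeneratorConfig,
) -> list[str]:
    own = cfg.pos_lexicon if sentiment == POSITIVE else cfg.neg_lexicon
    opp = cfg.neg_lexicon if sentiment == POSITIVE else cfg.pos_lexicon
    u = rng.random(length)
    shared_draw = rng.random(length) >= cfg.core_rate if shared_vocab else np.zeros(length, bool)
    own_idx = rng.integers(len(own), size=length) if own else np.zeros(length, int)
    opp_idx = rng.integers(len(opp), size=length) if opp else np.zeros(length, int)
    shared_idx = (
        rng.integers(len(shared_vocab), size=length) if shared_vocab else np.zeros(length, int)
    )
    core_idx = rng.integers(len(topic_vocab), size=length)
    tokens = []
    for i in range(length):
        if u[i] < cfg.injection_rate:
            tokens.append(own[own_idx[i]])
        elif u[i] < cfg.injection_rate + cfg.opposite_injection_rate:
            tokens.append(opp[opp_idx[i]])
        elif shared_draw[i]:
            tokens.append(shared_vocab[shared_idx[i]])
        else:
            tokens.append(topic_vocab[core_idx[i]])
    return tokens


def generate_corpus(config: GeneratorConfig) -> tuple[list[QARecord], pd.DataFrame]:
    """Generate a corpus and its ground truth.

    Returns the records and a DataFrame indexed by record_id with
    columns true_topic, true_question_sentiment, true_answer_sentiment,
    true_month.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    topic_vocabs = [
        [f"t{k:02d}w{j:03d}" for j in range(cfg.vocab_size_per_topic)]
        for k in range(cfg.n_topics)
    ]
    shared_vocab = [f"shared{j:03d}" for j in range(cfg.shared_vocab_size)]
    weights = (
        np.asarray(cfg.topic_weights, dtype=float)
        if cfg.topic_weights is not None
        else np.full(cfg.n_topics, 1.0 / cfg.n_topics)
    )
    pi = (
        list(cfg.pi_t)
        if isinstance(cfg.pi_t, (list, tuple))
        else [cfg.pi_t] * cfg.n_topics
    )
    if len(pi) != cfg.n_topics:
        raise ValueError("pi_t must be scalar or one value per topic")
    months = (
        sorted(cfg.month_pos_rate)
        if cfg.month_pos_rate
        else _months_in_range(*cfg.date_range)
    )
    month_days = {m: _month_days(m, cfg.date_range) for m in months}
    months = [m for m in months if month_days[m]]
    if not months:
        raise ValueError("no usable months inside date_range")

    lo, hi = cfg.doc_length_range
    a_lo, a_hi = cfg.answers_per_record_range
    records: list[QARecord] = []
    truth_rows = []
    width = len(str(cfg.n_records - 1))
    for i in range(cfg.n_records):
        topic = int(rng.choice(cfg.n_topics, p=weights))
        month = months[rng.integers(len(months))]
        days = month_days[month]
        q_date = days[rng.integers(len(days))]
        q_sent = POSITIVE if rng.random() < pi[topic] else NEGATIVE
        if cfg.month_pos_rate:
            a_sent = POSITIVE if rng.random() < cfg.month_pos_rate[month] else NEGATIVE
        else:
            a_sent = q_sent if rng.random() < cfg.rho else (
                NEGATIVE if q_sent == POSITIVE else POSITIVE
            )

        q_tokens = _draw_tokens(
            rng, int(rng.integers(lo, hi + 1)), topic_vocabs[topic], shared_vocab, q_sent, cfg
        )
        gold_tokens = _draw_tokens(
            rng, int(rng.integers(lo, hi + 1)), topic_vocabs[topic], shared_vocab, a_sent, cfg
        )
        n_answers = int(rng.integers(a_lo, a_hi + 1))
        other_upvotes = rng.integers(0, 20, size=n_answers - 1) if n_answers > 1 else []
        gold_upvotes = (int(max(other_upvotes)) if n_answers > 1 else 0) + 1 + int(rng.integers(0, 10))
        answers = [
            Answer(
                answer_text=" ".join(gold_tokens),
                upvotes=gold_upvotes,
                answer_timestamp=min(q_date + timedelta(days=int(rng.integers(0, 7))), cfg.date_range[1]),
            )
        ]
        for up in other_upvotes:
            filler = _draw_tokens(
                rng, int(rng.integers(5, 15)), topic_vocabs[topic], shared_vocab,
                POSITIVE if rng.random() < 0.5 else NEGATIVE, cfg,
            )
            answers.append(Answer(answer_text=" ".join(filler), upvotes=int(up)))
        perm = rng.permutation(len(answers))
        answers = [answers[j] for j in perm]

        rid = f"{cfg.platform}-{i:0{width}d}"
        records.append(
            QARecord(
                record_id=rid,
                platform=cfg.platform,
                question_text=" ".join(q_tokens),
                question_timestamp=q_date,
                answers=answers,
            )
        )
        truth_rows.append(
            {
                "record_id": rid,
                "true_topic": topic,
                "true_question_sentiment": q_sent,
                "true_answer_sentiment": a_sent,
                "true_month": month,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("record_id")
    return records, truth


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Write ground truth as CSV (record_id, true_topic, ...)."""
    truth.to_csv(path, lineterminator="\n")


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("record_id")
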