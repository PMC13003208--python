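"""Document-level binary sentiment via chunking and model bagging.

Long documents bias single-pass transformer classifiers toward their
opening tokens (e.g. a friendly greeting), so each document is split
into consecutive 128-token chunks, every chunk is scored for
positive/negative probabilities, and the chunk scores are averaged
(unweighted by default) into a document score.  Multiple scorers are
then bagged: their document-level probabilities are averaged and the
label with the higher averaged probability wins (exact tie ->
positive).

Scorers are pluggable through the :class:`SentimentScorer` protocol.
The reference backend is a deterministic lexicon scorer: with n+
positive-lexicon and n- negative-lexicon tokens in a chunk,

    s = (n+ - n-) / (n+ + n- + 1),   p_pos = (1 + s) / 2.

Transformer-based backends (e.g. BERT/ELECTRA sentiment heads) can be
adapted to the same protocol; nothing in this package depends on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import pandas as pd

from .corpus import QARecord, select_top_answer
from .errors import DataError
from .tokenize import tokenize

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
CHUNK_SIZE = 128


@runtime_checkable
class SentimentScorer(Protocol):
    """A chunk scorer: returns (p_pos, p_neg) summing to 1."""

    name: str

    def score(self, chunk_tokens: list[str]) -> tuple[float, float]: ...


def chunk(tokens: list[str], chunk_size: int = CHUNK_SIZE) -> list[list[str]]:
    """Consecutive non-overlapping chunks; all full except possibly the
    last; concatenation reproduces the input."""
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if not tokens:
        raise DataError("cannot chunk an empty token list")
    return [tokens[i : i + chunk_size] for i in range(0, len(tokens), chunk_size)]


def lexicon_score(
    chunk_tokens: list[str], pos_lexicon: set[str], neg_lexicon: set[str]
) -> tuple[float, float]:
    """Deterministic reference chunk score from lexicon counts."""
    pos, neg = set(pos_lexicon), set(neg_lexicon)
    if pos & neg:
        raise ValueError("lexicons must be disjoint")
    n_pos = sum(1 for t in chunk_tokens if t in pos)
    n_neg = sum(1 for t in chunk_tokens if t in neg)
    s = (n_pos - n_neg) / (n_pos + n_neg + 1)
    p_pos = (1.0 + s) / 2.0
    return p_pos, 1.0 - p_pos


class LexiconScorer:
    """Reference :class:`SentimentScorer` backed by polarity lexicons."""

    def __init__(self, pos_lexicon, neg_lexicon, name: str = "lexicon"):
        self.pos_lexicon = frozenset(pos_lexicon)
        self.neg_lexicon = frozenset(neg_lexicon)
        if self.pos_lexicon & self.neg_lexicon:
            raise ValueError("lexicons must be disjoint")
        self.name = name

    @classmethod
    def from_files(cls, pos_path, neg_path, name: str = "lexicon") -> "LexiconScorer":
        """Load one-token-per-line lexicon files."""
        read = lambda p: {
            line.strip().lower()
            for line in open(p, encoding="utf-8")
            if line.strip()
        }
        return cls(read(pos_path), read(neg_path), name=name)

    def score(self, chunk_tokens: list[str]) -> tuple[float, float]:
        return lexicon_score(chunk_tokens, self.pos_lexicon, self.neg_lexicon)


def score_document(
    scorer: SentimentScorer,
    text: str | list[str],
    *,
    chunk_size: int = CHUNK_SIZE,
    length_weighted: bool = False,
) -> tuple[float, float, int]:
    """Chunk the document, score each chunk, and average.

    The average is unweighted across chunks by default (each chunk
    counts equally regardless of length); ``length_weighted=True``
    weights chunks by token count instead.  Returns
    ``(p_pos, p_neg, n_chunks)``.
    """
    tokens = tokenize(text) if isinstance(text, str) else list(text)
    chunks = chunk(tokens, chunk_size)
    p_pos_sum = 0.0
    weight_sum = 0.0
    for idx, ch in enumerate(chunks):
        try:
            p_pos, p_neg = scorer.score(ch)
        except Exception as exc:
            raise DataError(f"scorer {scorer.name!r} failed on chunk {idx}: {exc}") from exc
        if not (0.0 <= p_pos <= 1.0) or abs(p_pos + p_neg - 1.0) > 1e-9:
            raise DataError(
                f"scorer {scorer.name!r} chunk {idx}: probabilities ({p_pos}, {p_neg}) invalid"
            )
        w = len(ch) if length_weighted else 1.0
        p_pos_sum += w * p_pos
        weight_sum += w
    doc_p_pos = p_pos_sum / weight_sum
    return doc_p_pos, 1.0 - doc_p_pos, len(chunks)


def ensemble(doc_scores: dict[str, tuple[float, float]]) -> tuple[float, float, str]:
    """Bag scorers: average their document probabilities; the label with
    the higher average wins (exact tie -> positive)."""
    if not doc_scores:
        raise DataError("ensemble requires at least one scorer output")
    p_pos = sum(p for p, _ in doc_scores.values()) / len(doc_scores)
    p_neg = sum(n for _, n in doc_scores.values()) / len(doc_scores)
    label = POSITIVE if p_pos >= p_neg else NEGATIVE
    return p_pos, p_neg, label


@dataclass
class SentimentResult:
    """Per-document sentiment: per-scorer and ensemble probabilities."""

    record_id: str
    target: str  # "question" or "answer"
    scorer_p_pos: dict[str, float]
    p_pos: float
    p_neg: float
    label: str
    n_chunks: int


def classify_corpus(
    records: list[QARecord],
    scorers: list[SentimentScorer],
    target: str = "answers",
    *,
    chunk_size: int = CHUNK_SIZE,
    length_weighted: bool = False,
) -> pd.DataFrame:
    """Classify question and/or top-answer sentiment for every record.

    ``target`` is one of "questions", "answers", "both".  Returns a
    DataFrame with one row per (record, target): record_id, target,
    per-scorer p_pos columns, ensemble p_pos/p_neg, label, n_chunks.
    Documents empty after tokenization are excluded and counted in the
    log.
    """
    if target not in ("questions", "answers", "both"):
        raise ValueError(f"target must be questions/answers/both, got {target!r}")
    if not scorers:
        raise DataError("at least one scorer is required")
    jobs = []
    for r in records:
        if target in ("questions", "both"):
            jobs.append((r.record_id, "question", r.question_text))
        if target in ("answers", "both"):
            jobs.append((r.record_id, "answer", select_top_answer(r).answer_text))
    rows = []
    n_excluded = 0
    for rid, tgt, text in jobs:
        tokens = tokenize(text)
        if not tokens:
            n_excluded += 1
            continue
        scores = {}
        n_chunks = 1
        for scorer in scorers:
            p_pos, p_neg, n_chunks = score_document(
                scorer, tokens, chunk_size=chunk_size, length_weighted=length_weighted
            )
            scores[scorer.name] = (p_pos, p_neg)
        e_pos, e_neg, label = ensemble(scores)
        row = {"record_id": rid, "target": tgt}
        for name, (p, _) in scores.items():
            row[f"p_pos_{name}"] = p
        row.update({"p_pos": e_pos, "p_neg": e_neg, "label": label, "n_chunks": n_chunks})
        rows.append(row)
    if n_excluded:
        logger.warning("classify_corpus: excluded %d empty documents", n_excluded)
    return pd.DataFrame(rows)


def evaluate_accuracy(
    predicted: pd.Series | dict[str, str], gold: pd.Series | dict[str, str]
) -> tuple[float, int, int]:
    """Accuracy of predicted labels against gold labels aligned on
    record_id.  Returns (accuracy, n_match, n_total)."""
    pred = pd.Series(predicted)
    gold = pd.Series(gold)
    common = pred.index.intersection(gold.index)
    if len(common) == 0:
        raise DataError("predicted and gold label sets share no record_ids")
    n_match = int((pred.loc[common] == gold.loc[common]).sum())
    n_total = int(len(common))
    return n_match / n_total, n_match, n_total
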