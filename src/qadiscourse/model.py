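"""End-to-end discourse model: corpus in, result tables out.

:class:`DiscourseModel` is built from preprocessed Q&A records plus
analysis settings; :meth:`DiscourseModel.fit` runs question
categorization, question and answer sentiment classification, and all
discourse statistics, returning a :class:`DiscourseResults` that
carries every table together with a ``summary()`` view.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

from .corpus import QARecord
from .errors import ConfigError
from .sentiment import LexiconScorer, SentimentScorer, classify_corpus
from .stats import (
    MarginalCheck,
    marginal_check,
    monthly_series,
    pair_crosstab,
    sentiment_proportions,
    temporal_stats,
    topic_table,
)
from .topics import MergeMap, TopicAssignment, categorize_questions


class DiscourseModel:
    """Cross-platform Q&A discourse analysis over one corpus.

    Parameters
    ----------
    records : list of QARecord
        Preprocessed corpus (keyword-filtered, answered-only, sampled).
    scorers : list of SentimentScorer
        Chunk scorers to bag; at least one (two in the analysed
        design).
    K, candidate_Ks, merge_map, ... :
        Topic settings forwarded to
        :func:`~qadiscourse.topics.categorize_questions`.
    window : (date, date), optional
        Temporal analysis window; defaults to the corpus' timestamp
        span.
    """

    def __init__(
        self,
        records: list[QARecord],
        scorers: list[SentimentScorer],
        *,
        K: int | None = None,
        candidate_Ks: list[int] | None = None,
        merge_map: MergeMap | None = None,
        n_sweeps: int = 1000,
        alpha: float | None = None,
        beta: float = 0.01,
        n_keywords: int = 10,
        embedding_dimension: int = 50,
        refine_with_centroids: bool = False,
        chunk_size: int = 128,
        length_weighted: bool = False,
        window: tuple[date, date] | None = None,
        merge_threshold_days: int = 7,
        stop_words: tuple[str, ...] = (),
    ):
        if not records:
            raise ConfigError("no records to analyse")
        if K is None and not candidate_Ks:
            raise ConfigError("either K or candidate_Ks is required")
        self.records = records
        self.scorers = scorers
        self.K = K
        self.candidate_Ks = candidate_Ks
        self.merge_map = merge_map
        self.n_sweeps = n_sweeps
        self.alpha = alpha
        self.beta = beta
        self.n_keywords = n_keywords
        self.embedding_dimension = embedding_dimension
        self.refine_with_centroids = refine_with_centroids
        self.chunk_size = chunk_size
        self.length_weighted = length_weighted
        self.window = window or (
            min(r.question_timestamp for r in records),
            max(r.question_timestamp for r in records),
        )
        self.merge_threshold_days = merge_threshold_days
        self.stop_words = stop_words

    @classmethod
    def with_lexicons(cls, records, pos_lexicon, neg_lexicon, **kwargs) -> "DiscourseModel":
        """Convenience constructor: a two-member bag of the reference
        lexicon scorer (the deterministic stand-in for a two-model
        transformer ensemble)."""
        scorers = [
            LexiconScorer(pos_lexicon, neg_lexicon, name="lexicon_a"),
            LexiconScorer(pos_lexicon, neg_lexicon, name="lexicon_b"),
        ]
        return cls(records, scorers, **kwargs)

    def fit(self, seed: int = 0) -> "DiscourseResults":
        """Run the full analysis deterministically for ``seed``."""
        assignment = categorize_questions(
            self.records,
            K=self.K,
            candidate_Ks=self.candidate_Ks,
            merge_map=self.merge_map,
            alpha=self.alpha,
            beta=self.beta,
            n_sweeps=self.n_sweeps,
            seed=seed,
            n_keywords=self.n_keywords,
            embedding_dimension=self.embedding_dimension,
            refine_with_centroids=self.refine_with_centroids,
            stop_words=self.stop_words,
        )
        label_order = assignment.merge_map.label_order
        topic_labels = assignment.labels["merged_label"]

        sent = classify_corpus(
            self.records, self.scorers, target="both",
            chunk_size=self.chunk_size, length_weighted=self.length_weighted,
        )
        q_labels = sent[sent["target"] == "question"].set_index("record_id")["label"]
        a_labels = sent[sent["target"] == "answer"].set_index("record_id")["label"]

        common = topic_labels.index.intersection(q_labels.index).intersection(a_labels.index)
        topic_labels = topic_labels.loc[common]
        q_labels, a_labels = q_labels.loc[common], a_labels.loc[common]
        timestamps = pd.Series(
            {r.record_id: r.question_timestamp for r in self.records}
        ).loc[common]

        topics = topic_table(topic_labels, label_order)
        proportions = sentiment_proportions(a_labels, topic_labels, label_order)
        q_proportions = sentiment_proportions(q_labels, topic_labels, label_order)
        pairs = pair_crosstab(q_labels, a_labels, topic_labels, label_order)
        check = marginal_check(pairs, proportions, q_proportions)
        series = monthly_series(
            a_labels, topic_labels, timestamps,
            self.window[0], self.window[1], self.merge_threshold_days, label_order,
        )
        stats = temporal_stats(series)
        return DiscourseResults(
            model=self,
            seed=seed,
            assignment=assignment,
            sentiment=sent,
            topic_labels=topic_labels,
            question_labels=q_labels,
            answer_labels=a_labels,
            topic_table=topics,
            sentiment_proportions=proportions,
            question_proportions=q_proportions,
            pair_table=pairs,
            marginal_check=check,
            monthly_series=series,
            temporal_stats=stats,
        )


@dataclass
class DiscourseResults:
    """All result surfaces of one fitted discourse analysis."""

    model: DiscourseModel
    seed: int
    assignment: TopicAssignment
    sentiment: pd.DataFrame
    topic_labels: pd.Series
    question_labels: pd.Series
    answer_labels: pd.Series
    topic_table: pd.DataFrame
    sentiment_proportions: pd.DataFrame
    question_proportions: pd.DataFrame
    pair_table: pd.DataFrame
    marginal_check: MarginalCheck
    monthly_series: pd.DataFrame
    temporal_stats: dict

    def summary(self) -> str:
        """Human-readable account of the fitted analysis."""
        n = len(self.topic_labels)
        lines = [
            "Q&A discourse analysis",
            "=" * 60,
            f"records: {n}   topics: {len(self.topic_table)}   seed: {self.seed}",
            "",
            "Topic proportions (count, % of N):",
        ]
        for lab, row in self.topic_table.iterrows():
            lines.append(f"  {lab:<24s} {int(row['count']):>5d}  ({row['percent']:.0f}%)")
        lines.append("")
        lines.append("Answer sentiment per topic (pos / neg, % positive):")
        for lab, row in self.sentiment_proportions.iterrows():
            lines.append(
                f"  {lab:<24s} {int(row['n_pos']):>5d} / {int(row['n_neg']):>5d}  ({row['pos_pct']:.2f}%)"
            )
        lines.append("")
        lines.append("Question-answer sentiment pairs (PP, PN, NP, NN):")
        for lab, row in self.pair_table.iterrows():
            lines.append(
                f"  {lab:<24s} {int(row['pos_pos']):>5d} {int(row['pos_neg']):>5d} "
                f"{int(row['neg_pos']):>5d} {int(row['neg_neg']):>5d}   (N={int(row['n'])})"
            )
        lines.append("")
        lines.append(f"marginal consistency: {'OK' if self.marginal_check.ok else 'FAILED'}")
        lines.append("Temporal statistics per topic:")
        for lab, entry in self.temporal_stats.items():
            streak = entry["positive_streak"]
            if streak is None or streak["start"] is None:
                streak_txt = "no positive-dominant month"
            else:
                streak_txt = f"longest positive streak={streak['length']} from {streak['start']}"
            lines.append(f"  {lab:<24s} crossovers={entry['crossovers']}, {streak_txt}")
        return "\n".join(lines)
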