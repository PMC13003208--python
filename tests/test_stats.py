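"""Tables, cross-tabs, marginal consistency, and temporal statistics."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qadiscourse.errors import DataError
from qadiscourse.stats import (
    count_crossovers,
    dominance_streak,
    marginal_check,
    month_bin,
    monthly_series,
    pair_crosstab,
    percent,
    sentiment_proportions,
    temporal_stats,
    topic_table,
)


class TestTopicTable:
    def test_counts_and_integer_percent(self):
        labels = pd.Series(["A"] * 3 + ["B"] * 1)
        table = topic_table(labels, ["A", "B"])
        assert list(table["count"]) == [3, 1]
        assert list(table["percent"]) == [75, 25]
        assert table["count"].sum() == len(labels)

    def test_single_label_is_100(self):
        table = topic_table(pd.Series(["A"] * 7))
        assert list(table["percent"]) == [100]

    def test_unlabeled_record_is_error(self):
        with pytest.raises(DataError):
            topic_table(pd.Series(["A", None]))

    def test_half_up_rounding(self):
        # 1/8 = 12.5% rounds half-up to 13
        labels = pd.Series(["A"] * 1 + ["B"] * 7)
        assert list(topic_table(labels, ["A", "B"])["percent"]) == [13, 88]


class TestProportionsAndPairs:
    def build(self):
        # topic A: q/a pairs PP x2, PN x1, NP x1, NN x1 ; topic B: NN x2
        q = pd.Series(
            ["positive", "positive", "positive", "negative", "negative",
             "negative", "negative"],
            index=[f"r{i}" for i in range(7)],
        )
        a = pd.Series(
            ["positive", "positive", "negative", "positive", "negative",
             "negative", "negative"],
            index=[f"r{i}" for i in range(7)],
        )
        topics = pd.Series(["A"] * 5 + ["B"] * 2, index=[f"r{i}" for i in range(7)])
        return q, a, topics

    def test_sentiment_proportions_counts_and_pct(self):
        q, a, topics = self.build()
        props = sentiment_proportions(a, topics, ["A", "B"])
        assert list(props["n_pos"]) == [3, 0]
        assert list(props["n_neg"]) == [2, 2]
        assert props.loc["A", "pos_pct"] == 60.0
        assert props.loc["B", "neg_pct"] == 100.0

    def test_pair_crosstab_counts_and_pct(self):
        q, a, topics = self.build()
        pairs = pair_crosstab(q, a, topics, ["A", "B"])
        assert list(pairs.loc["A", ["pos_pos", "pos_neg", "neg_pos", "neg_neg"]]) == [2, 1, 1, 1]
        assert pairs.loc["A", "pos_pos_pct"] == 40.0
        assert pairs.loc["B", "neg_neg_pct"] == 100.0
        assert pairs.loc["A", ["pos_pos", "pos_neg", "neg_pos", "neg_neg"]].sum() == pairs.loc["A", "n"]

    def test_all_positive_pairs_degenerate(self):
        idx = ["x", "y"]
        q = a = pd.Series(["positive", "positive"], index=idx)
        topics = pd.Series(["T", "T"], index=idx)
        pairs = pair_crosstab(q, a, topics)
        assert pairs.loc["T", "pos_pos"] == 2
        assert pairs.loc["T", "pos_pos_pct"] == 100.0
        assert pairs.loc["T", ["pos_neg", "neg_pos", "neg_neg"]].sum() == 0

    def test_missing_label_names_record(self):
        q, a, topics = self.build()
        with pytest.raises(DataError, match="r6"):
            pair_crosstab(q.drop("r6"), a, topics)

    def test_marginal_check_passes_by_construction(self):
        q, a, topics = self.build()
        pairs = pair_crosstab(q, a, topics, ["A", "B"])
        props = sentiment_proportions(a, topics, ["A", "B"])
        q_props = sentiment_proportions(q, topics, ["A", "B"])
        check = marginal_check(pairs, props, q_props)
        assert check.ok
        assert check.discrepancies == []

    def test_marginal_check_reports_failures_as_data(self):
        q, a, topics = self.build()
        pairs = pair_crosstab(q, a, topics, ["A", "B"])
        props = sentiment_proportions(a, topics, ["A", "B"]).copy()
        props.loc["A", "n_pos"] += 1
        check = marginal_check(pairs, props)
        assert not check.ok
        assert any("A" in d for d in check.discrepancies)


class TestMonthBin:
    WINDOW = (date(2020, 6, 27), date(2021, 6, 27))

    def test_leading_partial_month_merged_forward(self):
        assert month_bin(date(2020, 6, 28), *self.WINDOW) == "2020-07"

    def test_regular_month_unchanged(self):
        assert month_bin(date(2020, 8, 15), *self.WINDOW) == "2020-08"

    def test_window_starting_first_of_month_never_merges(self):
        assert month_bin(date(2020, 7, 1), date(2020, 7, 1), date(2021, 6, 30)) == "2020-07"

    def test_threshold_respected(self):
        # 4-day leading June is merged for any threshold >= 4, kept below
        assert month_bin(date(2020, 6, 28), *self.WINDOW, merge_threshold_days=4) == "2020-07"
        assert month_bin(date(2020, 6, 28), *self.WINDOW, merge_threshold_days=3) == "2020-06"

    def test_outside_window_is_error(self):
        with pytest.raises(DataError):
            month_bin(date(2019, 1, 1), *self.WINDOW)


class TestMonthlySeries:
    def test_single_month_share(self):
        idx = ["a", "b", "c", "d"]
        ans = pd.Series(["positive"] * 3 + ["negative"], index=idx)
        topics = pd.Series(["T"] * 4, index=idx)
        ts = pd.Series([date(2020, 8, i + 1) for i in range(4)], index=idx)
        series = monthly_series(ans, topics, ts, date(2020, 8, 1), date(2020, 8, 31))
        assert len(series) == 1
        assert series.iloc[0]["share"] == pytest.approx(0.75)

    def test_zero_record_months_are_null_not_imputed(self):
        idx = ["a", "b"]
        ans = pd.Series(["positive", "negative"], index=idx)
        topics = pd.Series(["T", "T"], index=idx)
        ts = pd.Series([date(2020, 7, 1), date(2020, 9, 1)], index=idx)
        series = monthly_series(ans, topics, ts, date(2020, 7, 1), date(2020, 9, 30))
        assert list(series["month"]) == ["2020-07", "2020-08", "2020-09"]
        assert np.isnan(series.set_index("month").loc["2020-08", "share"])

    def test_empty_topic_gives_all_null_series(self):
        idx = ["a"]
        ans = pd.Series(["positive"], index=idx)
        topics = pd.Series(["T"], index=idx)
        ts = pd.Series([date(2020, 7, 5)], index=idx)
        series = monthly_series(ans, topics, ts, date(2020, 7, 1), date(2020, 8, 31),
                                label_order=["T", "EMPTY"])
        empty = series[series["label"] == "EMPTY"]
        assert empty["share"].isna().all()


class TestCrossovers:
    @pytest.mark.parametrize(
        "shares, expected",
        [
            ([0.6, 0.4, 0.6, 0.4], 3),
            ([0.7, 0.7, 0.7], 0),
            ([0.6, 0.5, 0.4], 1),  # 0.5 carries positive, then flips
            ([0.5, 0.4, 0.6], 2),  # leading 0.5 treated positive
            ([0.6, np.nan, 0.4], 1),  # null months skipped
        ],
    )
    def test_counting_rule(self, shares, expected):
        assert count_crossovers(shares) == expected

    def test_too_few_months_error(self):
        with pytest.raises(DataError):
            count_crossovers([0.6, np.nan])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=24))
    def test_bounded_by_months_minus_one(self, shares):
        assert 0 <= count_crossovers(shares) <= len(shares) - 1

    def test_monotone_series_at_most_one(self):
        assert count_crossovers([0.2, 0.3, 0.45, 0.55, 0.7]) <= 1


class TestDominanceStreak:
    def test_longest_run_and_start(self):
        length, start = dominance_streak([0.6, 0.7, 0.4, 0.8])
        assert (length, start) == (2, 0)

    def test_all_dominant_full_length(self):
        length, _ = dominance_streak([0.6, 0.7, 0.9])
        assert length == 3

    def test_negative_polarity(self):
        length, start = dominance_streak([0.6, 0.3, 0.2, 0.1, 0.8], polarity="negative")
        assert (length, start) == (3, 1)

    def test_earliest_run_wins_ties(self):
        length, start = dominance_streak([0.6, 0.6, 0.4, 0.7, 0.7])
        assert (length, start) == (2, 0)

    def test_null_months_break_runs(self):
        length, _ = dominance_streak([0.6, np.nan, 0.6, 0.6])
        assert length == 2

    def test_exactly_half_never_dominates(self):
        length, start = dominance_streak([0.5, 0.5])
        assert (length, start) == (0, None)

    def test_planted_four_month_block_recovered(self):
        series = pd.DataFrame(
            {
                "label": ["T"] * 6,
                "month": [f"2021-{m:02d}" for m in range(1, 7)],
                "n_pos": [1] * 6,
                "n_neg": [1] * 6,
                "share": [0.4, 0.6, 0.7, 0.8, 0.9, 0.3],
            }
        )
        length, start = dominance_streak(series)
        assert (length, start) == (4, "2021-02")
        stats = temporal_stats(series)
        assert stats["T"]["positive_streak"] == {"length": 4, "start": "2021-02"}


class TestPercent:
    @pytest.mark.parametrize(
        "count, total, places, expected",
        [(1, 8, 0, 13.0), (504, 978, 2, 51.53), (374, 711, 2, 52.6), (0, 7, 2, 0.0)],
    )
    def test_exact_half_up(self, count, total, places, expected):
        assert percent(count, total, places) == expected
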