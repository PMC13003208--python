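"""Result surfaces: topic tables, sentiment proportions, question-answer
sentiment pair cross-tabulations, and monthly temporal series with
crossover and dominance-streak statistics.

Display conventions follow the source tables: topic proportions are
rounded to integer percent, sentiment and pair percentages to two
decimals, both with half-up rounding computed by exact decimal
arithmetic on the integer counts (no float round-off).  Internally the
exact counts are always retained.

A month is the calendar month of the timestamp, except that a leading
partial month covering at most ``merge_threshold_days`` days of the
analysis window is merged into the following month (the analysed
window started on June 27, so its four June days fold into July).
Months with zero records carry a null share and are skipped -- not
imputed -- by the crossover and streak statistics.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from datetime import date
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import DataError

POSITIVE = "positive"
NEGATIVE = "negative"
PAIR_COLUMNS = ("pos_pos", "pos_neg", "neg_pos", "neg_neg")


def percent(count: int, total: int, places: int = 2) -> float:
    """Exact half-up percentage of ``count/total`` at ``places`` decimals."""
    if total <= 0:
        raise DataError("percentage of an empty total")
    q = Decimal(count) * 100 / Decimal(total)
    return float(q.quantize(Decimal(1).scaleb(-places), rounding=ROUND_HALF_UP))


def topic_table(labels: pd.Series | dict, label_order: list[str] | None = None) -> pd.DataFrame:
    """Per-topic counts and integer percentages of the corpus N.

    ``labels`` maps record_id -> merged label; any null label is an
    error.  The exact share is kept in the ``share`` column.
    """
    labels = pd.Series(labels)
    if labels.isna().any():
        bad = list(labels.index[labels.isna()])[:5]
        raise DataError(f"unlabeled records: {bad}")
    n = len(labels)
    counts = labels.value_counts()
    order = label_order or list(counts.index)
    rows = []
    for lab in order:
        c = int(counts.get(lab, 0))
        rows.append({"label": lab, "count": c, "percent": percent(c, n, 0), "share": c / n})
    return pd.DataFrame(rows).set_index("label")


def sentiment_proportions(
    answer_labels: pd.Series | dict,
    topic_labels: pd.Series | dict,
    label_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-topic positive/negative answer counts and 2-dp percentages."""
    ans = pd.Series(answer_labels)
    top = pd.Series(topic_labels)
    missing = top.index.difference(ans.index)
    if len(missing):
        raise DataError(f"records without an answer sentiment label: {list(missing)[:5]}")
    order = label_order or list(pd.Series(top).value_counts().index)
    rows = []
    for lab in order:
        ids = top.index[top == lab]
        n_pos = int((ans.loc[ids] == POSITIVE).sum())
        n_neg = int((ans.loc[ids] == NEGATIVE).sum())
        total = n_pos + n_neg
        rows.append(
            {
                "label": lab,
                "n": total,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "pos_pct": percent(n_pos, total) if total else np.nan,
                "neg_pct": percent(n_neg, total) if total else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("label")


def pair_crosstab(
    question_labels: pd.Series | dict,
    answer_labels: pd.Series | dict,
    topic_labels: pd.Series | dict,
    label_order: list[str] | None = None,
) -> pd.DataFrame:
    """Ordered (question sentiment, answer sentiment) pair counts per
    topic with percentages of the row N at two decimals."""
    q = pd.Series(question_labels)
    a = pd.Series(answer_labels)
    top = pd.Series(topic_labels)
    for name, series in (("question", q), ("answer", a)):
        missing = top.index.difference(series.index)
        if len(missing):
            raise DataError(
                f"record {list(missing)[0]!r} lacks a {name} sentiment label"
            )
    order = label_order or list(top.value_counts().index)
    rows = []
    for lab in order:
        ids = top.index[top == lab]
        qs, as_ = q.loc[ids], a.loc[ids]
        n = len(ids)
        row = {"label": lab, "n": n}
        for col, (qv, av) in zip(
            PAIR_COLUMNS,
            [(POSITIVE, POSITIVE), (POSITIVE, NEGATIVE), (NEGATIVE, POSITIVE), (NEGATIVE, NEGATIVE)],
        ):
            c = int(((qs == qv) & (as_ == av)).sum())
            row[col] = c
            row[f"{col}_pct"] = percent(c, n) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("label")


@dataclass
class MarginalCheck:
    """Outcome of the pair-table vs proportions consistency check."""

    ok: bool
    discrepancies: list[str] = field(default_factory=list)


def marginal_check(
    pair_table: pd.DataFrame,
    proportions: pd.DataFrame,
    question_proportions: pd.DataFrame | None = None,
) -> MarginalCheck:
    """Assert the pair table's column sums reproduce the answer
    sentiment counts (PP+NP = n_pos, PN+NN = n_neg) per topic, and,
    when question proportions are supplied, the question marginals
    (PP+PN, NP+NN) likewise.  Failures are returned as data."""
    problems: list[str] = []
    for lab, row in pair_table.iterrows():
        if lab not in proportions.index:
            problems.append(f"{lab}: missing from sentiment proportions")
            continue
        prow = proportions.loc[lab]
        if row["pos_pos"] + row["neg_pos"] != prow["n_pos"]:
            problems.append(
                f"{lab}: PP+NP = {row['pos_pos'] + row['neg_pos']} != n_pos = {prow['n_pos']}"
            )
        if row["pos_neg"] + row["neg_neg"] != prow["n_neg"]:
            problems.append(
                f"{lab}: PN+NN = {row['pos_neg'] + row['neg_neg']} != n_neg = {prow['n_neg']}"
            )
        if question_proportions is not None and lab in question_proportions.index:
            qrow = question_proportions.loc[lab]
            if row["pos_pos"] + row["pos_neg"] != qrow["n_pos"]:
                problems.append(
                    f"{lab}: PP+PN = {row['pos_pos'] + row['pos_neg']} != question n_pos = {qrow['n_pos']}"
                )
            if row["neg_pos"] + row["neg_neg"] != qrow["n_neg"]:
                problems.append(
                    f"{lab}: NP+NN = {row['neg_pos'] + row['neg_neg']} != question n_neg = {qrow['n_neg']}"
                )
    return MarginalCheck(ok=not problems, discrepancies=problems)


# -- temporal ------------------------------------------------------------


def _month_key(d: date) -> str:
    return f"{d.year:04d}-{d.month:02d}"


def _next_month(month: str) -> str:
    y, m = int(month[:4]), int(month[5:7])
    y, m = (y + 1, 1) if m == 12 else (y, m + 1)
    return f"{y:04d}-{m:02d}"


def _leading_merge_month(window_start: date, window_end: date, merge_threshold_days: int) -> str | None:
    """The first month's key if its in-window day span is short enough
    to be folded into the following month."""
    first = _month_key(window_start)
    if first == _month_key(window_end):
        return None
    days_in_month = calendar.monthrange(window_start.year, window_start.month)[1]
    days_in_window = days_in_month - window_start.day + 1
    if window_start.day > 1 and days_in_window <= merge_threshold_days:
        return first
    return None


def month_bin(
    timestamp: date,
    window_start: date,
    window_end: date,
    merge_threshold_days: int = 7,
) -> str:
    """Calendar month key "YYYY-MM" of ``timestamp``, with a leading
    partial month of at most ``merge_threshold_days`` days merged into
    the following month."""
    if not window_start <= timestamp <= window_end:
        raise DataError(f"timestamp {timestamp} outside window {window_start}..{window_end}")
    key = _month_key(timestamp)
    merged = _leading_merge_month(window_start, window_end, merge_threshold_days)
    if merged is not None and key == merged:
        return _next_month(key)
    return key


def analysis_months(window_start: date, window_end: date, merge_threshold_days: int = 7) -> list[str]:
    """Contiguous month keys of the window after the leading-merge rule."""
    months = []
    key = _month_key(window_start)
    end_key = _month_key(window_end)
    while key <= end_key:
        months.append(key)
        key = _next_month(key)
    merged = _leading_merge_month(window_start, window_end, merge_threshold_days)
    if merged is not None:
        months = months[1:]
    return months


def monthly_series(
    answer_labels: pd.Series | dict,
    topic_labels: pd.Series | dict,
    timestamps: pd.Series | dict,
    window_start: date,
    window_end: date,
    merge_threshold_days: int = 7,
    label_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-topic month-indexed positive/negative answer counts and the
    positive share; months with zero records carry a null share."""
    ans = pd.Series(answer_labels)
    top = pd.Series(topic_labels)
    ts = pd.Series(timestamps)
    months = analysis_months(window_start, window_end, merge_threshold_days)
    order = label_order or list(top.value_counts().index)
    bins = {
        rid: month_bin(ts.loc[rid], window_start, window_end, merge_threshold_days)
        for rid in top.index
    }
    rows = []
    for lab in order:
        ids = top.index[top == lab]
        for month in months:
            mids = [rid for rid in ids if bins[rid] == month]
            n_pos = int((ans.loc[mids] == POSITIVE).sum()) if mids else 0
            n_neg = int((ans.loc[mids] == NEGATIVE).sum()) if mids else 0
            total = n_pos + n_neg
            rows.append(
                {
                    "label": lab,
                    "month": month,
                    "n_pos": n_pos,
                    "n_neg": n_neg,
                    "share": n_pos / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _signs(shares: list[float]) -> list[int]:
    """Sign of share-0.5 per non-null month; exact 0.5 carries the
    previous sign (a leading 0.5 counts positive)."""
    signs = []
    prev = 1
    for s in shares:
        sign = 1 if s > 0.5 else (-1 if s < 0.5 else prev)
        signs.append(sign)
        prev = sign
    return signs


def count_crossovers(series: pd.DataFrame | list[float]) -> int:
    """Number of consecutive non-null month pairs whose majority
    polarity strictly flips."""
    shares = _series_shares(series)
    shares = [s for s in shares if not pd.isna(s)]
    if len(shares) < 2:
        raise DataError("need >= 2 non-null months to count crossovers")
    signs = _signs(shares)
    return sum(1 for a, b in zip(signs, signs[1:]) if a != b)


def dominance_streak(
    series: pd.DataFrame | list[float], polarity: str = POSITIVE
) -> tuple[int, str | int | None]:
    """Longest run of consecutive months in which ``polarity``'s share
    strictly exceeds one half (ties -> earliest run).

    Null months break runs.  Returns (length, start month); the start
    is a month key when the input carries months, else a positional
    index, or None for a zero-length run.
    """
    if polarity not in (POSITIVE, NEGATIVE):
        raise ValueError(f"polarity must be positive/negative, got {polarity!r}")
    shares = _series_shares(series)
    months = (
        list(series["month"]) if isinstance(series, pd.DataFrame) else list(range(len(shares)))
    )
    if not [s for s in shares if not pd.isna(s)]:
        raise DataError("need >= 1 non-null month")
    best_len, best_start = 0, None
    run_len, run_start = 0, None
    for month, s in zip(months, shares):
        dominant = (not pd.isna(s)) and (
            s > 0.5 if polarity == POSITIVE else (1.0 - s) > 0.5
        )
        if dominant:
            if run_len == 0:
                run_start = month
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len, run_start = 0, None
    return best_len, best_start


def _series_shares(series: pd.DataFrame | list[float]) -> list[float]:
    if isinstance(series, pd.DataFrame):
        return list(series["share"])
    return list(series)


def temporal_stats(series: pd.DataFrame) -> dict:
    """Crossovers and dominance streaks per topic from a monthly series."""
    out = {}
    for lab, sub in series.groupby("label", sort=False):
        sub = sub.sort_values("month")
        non_null = sub["share"].notna().sum()
        entry: dict = {"n_months": int(non_null)}
        entry["crossovers"] = count_crossovers(sub) if non_null >= 2 else None
        for pol in (POSITIVE, NEGATIVE):
            if non_null >= 1:
                length, start = dominance_streak(sub, pol)
                entry[f"{pol}_streak"] = {"length": int(length), "start": start}
            else:
                entry[f"{pol}_streak"] = None
        out[lab] = entry
    return out
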