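"""Static figure helpers mirroring the published result layouts:
stacked per-topic sentiment proportions and per-topic monthly
positive-share curves with the 0.5 majority line."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_sentiment_proportions(proportions: pd.DataFrame, path: str | Path) -> None:
    """Horizontal stacked bars of positive/negative share per topic."""
    fig, ax = plt.subplots(figsize=(8, 0.6 * len(proportions) + 1.5))
    labels = list(proportions.index)
    pos = proportions["pos_pct"].to_numpy()
    neg = proportions["neg_pct"].to_numpy()
    ax.barh(labels, pos, color="#2b8cbe", label="positive")
    ax.barh(labels, neg, left=pos, color="#e34a33", label="negative")
    ax.set_xlabel("share of answers (%)")
    ax.set_xlim(0, 100)
    ax.legend(loc="lower right")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_monthly_series(series: pd.DataFrame, path: str | Path) -> None:
    """Positive-sentiment share per month, one line per topic."""
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for lab, sub in series.groupby("label", sort=False):
        sub = sub.sort_values("month")
        ax.plot(sub["month"], sub["share"], marker="o", markersize=3, label=lab)
    ax.axhline(0.5, color="grey", linestyle="--", linewidth=1)
    ax.set_ylabel("positive share of answers")
    ax.set_ylim(0, 1)
    ax.tick_params(axis="x", rotation=45)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
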