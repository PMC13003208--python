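"""Configuration and end-to-end orchestration.

A run is a sequence of file-backed stages over one output directory:

    generate -> ingest -> topics -> sentiment -> pairs -> temporal -> report

:func:`run_pipeline` executes them in order; the CLI subcommands run
exactly one stage each, so chained subcommands are byte-identical to a
single run on the same config.  Every stage reads its inputs from the
previous stage's files and uses the same library functions the
:class:`~qadiscourse.model.DiscourseModel` facade uses in memory.  The
resolved config is frozen alongside the outputs, and a manifest
(config hash, versions, filter report, per-stage counts and wall
times) is written on every run, success or failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .corpus import preprocess_corpus, read_corpus, write_corpus
from .errors import ConfigError, DataError
from .sentiment import LexiconScorer, classify_corpus
from .stats import (
    marginal_check,
    monthly_series,
    pair_crosstab,
    sentiment_proportions,
    temporal_stats,
    topic_table,
)
from .synthetic import GeneratorConfig, generate_corpus, write_ground_truth
from .topics import MergeMap, categorize_questions

logger = logging.getLogger(__name__)

STAGES = ("generate", "ingest", "topics", "sentiment", "pairs", "temporal", "report")


@dataclass
class RunConfig:
    """Fully resolved settings for one pipeline run.

    Either ``input`` (a JSONL/CSV corpus file) or ``generator`` (a
    synthetic corpus config) must be set.  Every field has a recorded
    default and the resolved config is serialized next to the outputs.
    """

    outdir: str = "qadiscourse_out"
    input: str | None = None
    input_format: str | None = None
    generator: GeneratorConfig | None = None
    keyword_forms: list[str] = field(default_factory=lambda: ["vaccine"])
    search_answers: bool = True
    sample_n: int | None = None
    seed: int = 0
    K: int | None = None
    candidate_Ks: list[int] | None = None
    merge_map: str | dict | None = None  # path, or inline {mapping, label_order}
    alpha: float | None = None
    beta: float = 0.01
    n_sweeps: int = 1000
    n_keywords: int = 10
    embedding_dimension: int = 50
    refine_with_centroids: bool = False
    chunk_size: int = 128
    length_weighted: bool = False
    pos_lexicon_file: str | None = None
    neg_lexicon_file: str | None = None
    n_scorers: int = 2
    window: tuple[date, date] | None = None
    merge_threshold_days: int = 7
    stop_words: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.input is None and self.generator is None:
            raise ConfigError("config needs either 'input' or 'generator'")
        if self.K is None and not self.candidate_Ks:
            raise ConfigError("config needs K or candidate_Ks")
        if self.candidate_Ks and self.merge_map is None:
            raise ConfigError(
                "a merge_map is required when candidate_Ks is given "
                "(the raw-to-merged topic mapping cannot be inferred)"
            )
        if self.generator is None and not (self.pos_lexicon_file and self.neg_lexicon_file):
            raise ConfigError("lexicon files are required when no generator supplies lexicons")

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["generator"] = self.generator.to_dict() if self.generator else None
        if self.window:
            d["window"] = [self.window[0].isoformat(), self.window[1].isoformat()]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("generator"):
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if d.get("window"):
            d["window"] = (date.fromisoformat(d["window"][0]), date.fromisoformat(d["window"][1]))
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        obj = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(obj)

    def freeze(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    # -- shared lookups --------------------------------------------------

    def resolve_merge_map(self, K: int) -> MergeMap:
        if self.merge_map is None:
            return MergeMap.identity(K)
        if isinstance(self.merge_map, dict):
            return MergeMap(
                mapping={int(k): str(v) for k, v in self.merge_map["mapping"].items()},
                label_order=list(self.merge_map.get("label_order") or []),
            )
        return MergeMap.from_yaml(self.merge_map)

    def resolve_scorers(self) -> list[LexiconScorer]:
        if self.pos_lexicon_file and self.neg_lexicon_file:
            base = LexiconScorer.from_files(self.pos_lexicon_file, self.neg_lexicon_file)
            pos, neg = base.pos_lexicon, base.neg_lexicon
        elif self.generator is not None:
            pos, neg = set(self.generator.pos_lexicon), set(self.generator.neg_lexicon)
        else:
            raise ConfigError("no lexicons available for the sentiment scorers")
        if self.n_scorers < 1:
            raise ConfigError("n_scorers must be >= 1")
        return [
            LexiconScorer(pos, neg, name=f"lexicon_{chr(ord('a') + i)}")
            for i in range(self.n_scorers)
        ]


def _to_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, lineterminator="\n", float_format="%.10g", **kwargs)


def _require(outdir: Path, name: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise DataError(f"missing upstream artifact: expected file {path}")
    return path


# -- stages --------------------------------------------------------------


def stage_generate(cfg: RunConfig, outdir: Path) -> dict:
    if cfg.generator is None:
        raise ConfigError("stage 'generate' requires a generator config")
    records, truth = generate_corpus(cfg.generator)
    write_corpus(records, outdir / "corpus.jsonl")
    write_ground_truth(truth, outdir / "ground_truth.csv")
    return {"n_generated": len(records)}


def stage_ingest(cfg: RunConfig, outdir: Path) -> dict:
    src = Path(cfg.input) if cfg.input else _require(outdir, "corpus.jsonl")
    records = read_corpus(src, cfg.input_format)
    kept, report = preprocess_corpus(
        records, cfg.keyword_forms, sample_n=cfg.sample_n, seed=cfg.seed,
        search_answers=cfg.search_answers,
    )
    write_corpus(kept, outdir / "filtered.jsonl")
    (outdir / "filter_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report.to_dict()


def stage_topics(cfg: RunConfig, outdir: Path) -> dict:
    records = read_corpus(_require(outdir, "filtered.jsonl"))
    # None -> categorize_questions falls back to the identity merge
    merge_map = None if cfg.merge_map is None else cfg.resolve_merge_map(cfg.K or 0)
    assignment = categorize_questions(
        records,
        K=cfg.K,
        candidate_Ks=cfg.candidate_Ks,
        merge_map=merge_map,
        alpha=cfg.alpha,
        beta=cfg.beta,
        n_sweeps=cfg.n_sweeps,
        seed=cfg.seed,
        n_keywords=cfg.n_keywords,
        embedding_dimension=cfg.embedding_dimension,
        refine_with_centroids=cfg.refine_with_centroids,
        stop_words=tuple(cfg.stop_words),
    )
    _to_csv(assignment.labels, outdir / "doc_topics.csv")
    kw_rows = []
    for lab in assignment.merge_map.label_order:
        for rank, w in enumerate(assignment.space.topic_keywords.get(lab, []), start=1):
            kw_rows.append({"label": lab, "rank": rank, "keyword": w})
    _to_csv(pd.DataFrame(kw_rows), outdir / "topic_keywords.csv", index=False)
    if assignment.coherence_table is not None:
        _to_csv(assignment.coherence_table, outdir / "coherence.csv", index=False)
    return {"n_labeled": len(assignment.labels), "K": assignment.lda.K}


def stage_sentiment(cfg: RunConfig, outdir: Path) -> dict:
    records = read_corpus(_require(outdir, "filtered.jsonl"))
    sent = classify_corpus(
        records, cfg.resolve_scorers(), target="both",
        chunk_size=cfg.chunk_size, length_weighted=cfg.length_weighted,
    )
    _to_csv(sent, outdir / "sentiment.csv", index=False)
    return {"n_scored": int(len(sent))}


def _load_labels(outdir: Path) -> tuple[pd.Series, pd.Series, pd.Series, list[str]]:
    topics = pd.read_csv(_require(outdir, "doc_topics.csv")).set_index("record_id")
    sent_path = _require(outdir, "sentiment.csv")
    sent = pd.read_csv(sent_path)
    q = sent[sent["target"] == "question"].set_index("record_id")["label"]
    a = sent[sent["target"] == "answer"].set_index("record_id")["label"]
    common = topics.index.intersection(q.index).intersection(a.index)
    label_order = list(dict.fromkeys(topics["merged_label"]))
    return topics.loc[common, "merged_label"], q.loc[common], a.loc[common], label_order


def stage_pairs(cfg: RunConfig, outdir: Path) -> dict:
    topic_labels, q_labels, a_labels, label_order = _load_labels(outdir)
    topics = topic_table(topic_labels, label_order)
    props = sentiment_proportions(a_labels, topic_labels, label_order)
    q_props = sentiment_proportions(q_labels, topic_labels, label_order)
    pairs = pair_crosstab(q_labels, a_labels, topic_labels, label_order)
    check = marginal_check(pairs, props, q_props)
    _to_csv(topics, outdir / "topic_table.csv")
    _to_csv(props, outdir / "sentiment_proportions.csv")
    _to_csv(q_props, outdir / "question_proportions.csv")
    _to_csv(pairs, outdir / "pair_table.csv")
    (outdir / "marginal_check.json").write_text(
        json.dumps({"ok": check.ok, "discrepancies": check.discrepancies}, indent=2) + "\n",
        encoding="utf-8",
    )
    return {"marginals_ok": check.ok}


def stage_temporal(cfg: RunConfig, outdir: Path) -> dict:
    topic_labels, _, a_labels, label_order = _load_labels(outdir)
    records = read_corpus(_require(outdir, "filtered.jsonl"))
    timestamps = pd.Series({r.record_id: r.question_timestamp for r in records})
    timestamps = timestamps.loc[topic_labels.index]
    window = cfg.window or (timestamps.min(), timestamps.max())
    series = monthly_series(
        a_labels, topic_labels, timestamps, window[0], window[1],
        cfg.merge_threshold_days, label_order,
    )
    _to_csv(series, outdir / "monthly_series.csv", index=False)
    stats = temporal_stats(series)
    (outdir / "stats.json").write_text(
        json.dumps(stats, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {"n_months": int(series["month"].nunique())}


def stage_report(cfg: RunConfig, outdir: Path) -> dict:
    lines = ["qadiscourse run summary", "=" * 40]
    for name in ("topic_table", "sentiment_proportions", "pair_table"):
        path = outdir / f"{name}.csv"
        if path.exists():
            lines.append(f"\n## {name}")
            lines.append(path.read_text(encoding="utf-8").rstrip())
    stats_path = outdir / "stats.json"
    if stats_path.exists():
        lines.append("\n## temporal stats")
        lines.append(stats_path.read_text(encoding="utf-8").rstrip())
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return {"report": "summary.txt"}


_STAGE_FUNCS = {
    "generate": stage_generate,
    "ingest": stage_ingest,
    "topics": stage_topics,
    "sentiment": stage_sentiment,
    "pairs": stage_pairs,
    "temporal": stage_temporal,
    "report": stage_report,
}


def run_stage(name: str, cfg: RunConfig, outdir: str | Path) -> dict:
    """Run exactly one stage against an existing output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return _STAGE_FUNCS[name](cfg, outdir)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    The manifest records per-stage counts and wall times and is
    written last -- also on failure, with the failing stage named.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.freeze(outdir)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "stages": {},
        "status": "running",
    }
    stages = [s for s in STAGES if not (s == "generate" and cfg.generator is None)]
    try:
        for name in stages:
            t0 = time.perf_counter()
            info = _STAGE_FUNCS[name](cfg, outdir)
            manifest["stages"][name] = {
                **info,
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
            logger.info("stage %s done: %s", name, info)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = next(
            (s for s in stages if s not in manifest["stages"]), "unknown"
        )
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return outdir


def run_platform_comparison(configs: dict[str, RunConfig], outdir: str | Path) -> pd.DataFrame:
    """Run the pipeline per platform config and emit a side-by-side
    topic-proportion comparison table."""
    outdir = Path(outdir)
    tables = {}
    for name, cfg in configs.items():
        cfg.outdir = str(outdir / name)
        run_pipeline(cfg)
        tables[name] = pd.read_csv(outdir / name / "topic_table.csv").set_index("label")
    comparison = pd.concat(tables, axis=1)
    _to_csv(comparison, outdir / "comparison_topic_table.csv")
    return comparison
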