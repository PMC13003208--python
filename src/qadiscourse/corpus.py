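"""Corpus ingestion, validation, filtering, and sample-size matching.

Reproduces the preprocessing funnel applied to the scraped Q&A data:
keyword filter (case-insensitive substring on any morphological form of
the target keyword), removal of unanswered questions, selection of the
most-upvoted answer per question, and seeded random subsampling to a
fixed corpus size so two platforms can be compared at equal N.

Records travel as :class:`QARecord` objects; files are JSONL (one
record per line) or CSV (one row per answer, record fields repeated).
The writer is bit-stable (sorted keys, fixed formatting) so that
serialization round-trips can be compared byte for byte.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np

from .errors import DataError, SchemaError

logger = logging.getLogger(__name__)

_REQUIRED_FIELDS = ("record_id", "platform", "question_text", "question_timestamp")


@dataclass
class Answer:
    """One answer to a question: text, upvote count, optional date."""

    answer_text: str
    upvotes: int = 0
    answer_timestamp: date | None = None

    def __post_init__(self) -> None:
        if self.upvotes < 0:
            raise SchemaError(f"upvotes must be >= 0, got {self.upvotes}")


@dataclass
class QARecord:
    """One question with its answers; the atomic corpus unit."""

    record_id: str
    platform: str
    question_text: str
    question_timestamp: date
    answers: list[Answer] = field(default_factory=list)
    url: str | None = None


@dataclass
class CorpusFilterReport:
    """Record counts through the preprocessing funnel, plus the sampling seed.

    Counts must be weakly decreasing: input >= after keyword filter >=
    after answered-only filter >= after sampling.
    """

    n_input: int
    n_after_keyword: int
    n_after_answered: int
    n_after_sampling: int
    seed: int

    def __post_init__(self) -> None:
        counts = (
            self.n_input,
            self.n_after_keyword,
            self.n_after_answered,
            self.n_after_sampling,
        )
        if any(c < 0 for c in counts):
            raise DataError(f"filter counts must be non-negative: {counts}")
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise DataError(f"filter counts must be weakly decreasing: {counts}")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_keyword": self.n_after_keyword,
            "n_after_answered": self.n_after_answered,
            "n_after_sampling": self.n_after_sampling,
            "seed": self.seed,
        }


def _parse_date(value, *, where: str) -> date:
    if isinstance(value, date):
        return value
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise SchemaError(f"unparseable date {value!r} at {where}") from exc


def _record_from_obj(obj: dict, *, where: str) -> QARecord:
    for key in _REQUIRED_FIELDS:
        if key not in obj or obj[key] in (None, ""):
            raise SchemaError(f"missing required field {key!r} at {where}")
    answers = []
    for j, a in enumerate(obj.get("answers") or []):
        if "answer_text" not in a:
            raise SchemaError(f"missing required field 'answer_text' at {where}, answer {j}")
        ts = a.get("answer_timestamp")
        answers.append(
            Answer(
                answer_text=str(a["answer_text"]),
                upvotes=int(a.get("upvotes", 0)),
                answer_timestamp=_parse_date(ts, where=where) if ts else None,
            )
        )
    return QARecord(
        record_id=str(obj["record_id"]),
        platform=str(obj["platform"]),
        question_text=str(obj["question_text"]),
        question_timestamp=_parse_date(obj["question_timestamp"], where=where),
        answers=answers,
        url=obj.get("url") or None,
    )


def _check_unique_ids(records: list[QARecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.record_id in seen:
            raise SchemaError(f"duplicate record_id {r.record_id!r}")
        seen.add(r.record_id)


def read_corpus(path: str | Path, format: str | None = None, *, strict: bool = True) -> list[QARecord]:
    """Read a Q&A corpus from a JSONL or CSV file.

    The format is inferred from the file suffix when not given.  With
    ``strict=True`` (default) any malformed row raises
    :class:`SchemaError` naming the field and line; with
    ``strict=False`` malformed rows are skipped and counted in the log.
    Input order is preserved.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")

    records: list[QARecord] = []
    n_bad = 0
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                where = f"{path.name}:{lineno}"
                try:
                    obj = json.loads(line)
                    records.append(_record_from_obj(obj, where=where))
                except (json.JSONDecodeError, SchemaError, TypeError, ValueError):
                    if strict:
                        raise
                    n_bad += 1
    else:
        records = _read_csv(path, strict=strict)
        n_bad = getattr(_read_csv, "_last_bad", 0)
    if n_bad:
        logger.warning("read_corpus: rejected %d malformed rows from %s", n_bad, path)
    _check_unique_ids(records)
    return records


def _read_csv(path: Path, *, strict: bool) -> list[QARecord]:
    # One row per answer; record-level fields repeated.  Rows for the
    # same record_id must be contiguous; a row with empty answer_text
    # encodes an unanswered question.
    by_id: dict[str, QARecord] = {}
    order: list[str] = []
    n_bad = 0
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path.name}: empty CSV (header row mandatory)")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path.name}:{lineno}"
            try:
                for key in _REQUIRED_FIELDS:
                    if not row.get(key):
                        raise SchemaError(f"missing required field {key!r} at {where}")
                rid = row["record_id"]
                if rid not in by_id:
                    by_id[rid] = QARecord(
                        record_id=rid,
                        platform=row["platform"],
                        question_text=row["question_text"],
                        question_timestamp=_parse_date(row["question_timestamp"], where=where),
                        url=row.get("url") or None,
                    )
                    order.append(rid)
                if row.get("answer_text"):
                    ts = row.get("answer_timestamp") or None
                    by_id[rid].answers.append(
                        Answer(
                            answer_text=row["answer_text"],
                            upvotes=int(row.get("upvotes") or 0),
                            answer_timestamp=_parse_date(ts, where=where) if ts else None,
                        )
                    )
            except (SchemaError, ValueError):
                if strict:
                    raise
                n_bad += 1
    _read_csv._last_bad = n_bad  # type: ignore[attr-defined]
    return [by_id[rid] for rid in order]


def _record_to_obj(record: QARecord) -> dict:
    obj = {
        "record_id": record.record_id,
        "platform": record.platform,
        "question_text": record.question_text,
        "question_timestamp": record.question_timestamp.isoformat(),
        "answers": [
            {
                "answer_text": a.answer_text,
                "upvotes": a.upvotes,
                **(
                    {"answer_timestamp": a.answer_timestamp.isoformat()}
                    if a.answer_timestamp
                    else {}
                ),
            }
            for a in record.answers
        ],
    }
    if record.url:
        obj["url"] = record.url
    return obj


def write_corpus(records: list[QARecord], path: str | Path, format: str | None = None) -> None:
    """Write records bit-stably (sorted keys, LF newlines) as JSONL or CSV."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for r in records:
                fh.write(json.dumps(_record_to_obj(r), sort_keys=True, ensure_ascii=False))
                fh.write("\n")
    elif format == "csv":
        buf = io.StringIO()
        fields = [
            "record_id",
            "platform",
            "question_text",
            "question_timestamp",
            "url",
            "answer_text",
            "upvotes",
            "answer_timestamp",
        ]
        writer = csv.DictWriter(buf, fieldnames=fields, lineterminator="\n")
        writer.writeheader()
        for r in records:
            base = {
                "record_id": r.record_id,
                "platform": r.platform,
                "question_text": r.question_text,
                "question_timestamp": r.question_timestamp.isoformat(),
                "url": r.url or "",
            }
            rows = r.answers or [None]
            for a in rows:
                writer.writerow(
                    {
                        **base,
                        "answer_text": a.answer_text if a else "",
                        "upvotes": a.upvotes if a else "",
                        "answer_timestamp": (
                            a.answer_timestamp.isoformat() if a and a.answer_timestamp else ""
                        ),
                    }
                )
        Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def filter_by_keyword(
    records: list[QARecord],
    keyword_forms: set[str] | list[str],
    *,
    search_answers: bool = True,
) -> list[QARecord]:
    """Keep records whose question (or any answer) contains a keyword form.

    Matching is case-insensitive substring matching on the raw text, so
    a form like "vaccine" also matches "vaccines" and "vaccinated" --
    any string containing the form.  ``search_answers=False`` restricts
    the search to question text only.
    """
    forms = [f.lower() for f in keyword_forms if f]
    if not forms:
        raise ValueError("keyword_forms must be non-empty")

    def hit(r: QARecord) -> bool:
        texts = [r.question_text]
        if search_answers:
            texts.extend(a.answer_text for a in r.answers)
        return any(any(f in t.lower() for f in forms) for t in texts)

    return [r for r in records if hit(r)]


def drop_unanswered(records: list[QARecord]) -> list[QARecord]:
    """Remove records with no answers; others pass through unchanged."""
    return [r for r in records if r.answers]


def select_top_answer(record: QARecord) -> Answer:
    """Return the most-upvoted answer of ``record``.

    Ties are broken by earliest answer_timestamp (answers without a
    timestamp sort last), then by position in the answer list.
    """
    if not record.answers:
        raise DataError(f"record {record.record_id!r} has no answers")
    _, best = min(
        enumerate(record.answers),
        key=lambda ia: (-ia[1].upvotes, ia[1].answer_timestamp or date.max, ia[0]),
    )
    return best


def sample_match(records: list[QARecord], n: int, seed: int) -> list[QARecord]:
    """Uniform sample of exactly ``n`` records without replacement.

    Reproducible given ``seed``; output sorted by question_timestamp
    (record_id as a deterministic secondary key).
    """
    if n > len(records):
        raise ValueError(f"cannot sample {n} from {len(records)} records")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n, replace=False)
    sampled = [records[i] for i in sorted(idx)]
    return sorted(sampled, key=lambda r: (r.question_timestamp, r.record_id))


def preprocess_corpus(
    records: list[QARecord],
    keyword_forms: set[str] | list[str],
    *,
    sample_n: int | None = None,
    seed: int = 0,
    search_answers: bool = True,
) -> tuple[list[QARecord], CorpusFilterReport]:
    """Run the full preprocessing funnel and report counts at each stage.

    keyword filter -> answered-only filter -> random subsample of
    ``sample_n`` records (skipped when ``sample_n`` is None or exceeds
    the surviving count, in which case all survivors are kept).
    """
    n_input = len(records)
    kept = filter_by_keyword(records, keyword_forms, search_answers=search_answers)
    n_kw = len(kept)
    kept = drop_unanswered(kept)
    n_ans = len(kept)
    if sample_n is not None and sample_n < len(kept):
        kept = sample_match(kept, sample_n, seed)
    report = CorpusFilterReport(
        n_input=n_input,
        n_after_keyword=n_kw,
        n_after_answered=n_ans,
        n_after_sampling=len(kept),
        seed=seed,
    )
    return kept, report
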