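"""Ingestion, preprocessing funnel, and serialization round-trips."""

from __future__ import annotations

import json
from datetime import date

import pytest

from qadiscourse.corpus import (
    Answer,
    CorpusFilterReport,
    drop_unanswered,
    filter_by_keyword,
    preprocess_corpus,
    read_corpus,
    sample_match,
    select_top_answer,
    write_corpus,
)
from qadiscourse.errors import DataError, SchemaError

from .conftest import make_record


class TestReadCorpus:
    def test_jsonl_identity_ingestion(self, tmp_path):
        lines = [
            {"record_id": f"q{i}", "platform": "quora", "question_text": f"t{i}",
             "question_timestamp": "2020-07-01",
             "answers": [{"answer_text": "a", "upvotes": i}]}
            for i in range(3)
        ]
        path = tmp_path / "c.jsonl"
        path.write_text("\n".join(json.dumps(x) for x in lines) + "\n")
        records = read_corpus(path)
        assert [r.record_id for r in records] == ["q0", "q1", "q2"]
        assert records[2].answers[0].upvotes == 2

    def test_missing_field_names_field_and_line(self, tmp_path):
        path = tmp_path / "c.jsonl"
        good = {"record_id": "a", "platform": "p", "question_text": "x",
                "question_timestamp": "2020-07-01", "answers": []}
        bad = {"record_id": "b", "platform": "p",
               "question_timestamp": "2020-07-01", "answers": []}
        path.write_text(json.dumps(good) + "\n" + json.dumps(bad) + "\n")
        with pytest.raises(SchemaError, match=r"question_text.*:2"):
            read_corpus(path)

    def test_unparseable_date_is_schema_error(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text(json.dumps({
            "record_id": "a", "platform": "p", "question_text": "x",
            "question_timestamp": "July 1st", "answers": []}) + "\n")
        with pytest.raises(SchemaError, match="date"):
            read_corpus(path)

    def test_duplicate_record_id_rejected(self, tmp_path):
        rec = {"record_id": "a", "platform": "p", "question_text": "x",
               "question_timestamp": "2020-07-01", "answers": []}
        path = tmp_path / "c.jsonl"
        path.write_text(json.dumps(rec) + "\n" + json.dumps(rec) + "\n")
        with pytest.raises(SchemaError, match="duplicate"):
            read_corpus(path)

    def test_csv_jsonl_round_trip_identical(self, tmp_path, ten_records):
        write_corpus(ten_records, tmp_path / "c.jsonl")
        write_corpus(ten_records, tmp_path / "c.csv")
        assert read_corpus(tmp_path / "c.jsonl") == read_corpus(tmp_path / "c.csv")

    def test_writer_is_bit_stable(self, tmp_path, ten_records):
        write_corpus(ten_records, tmp_path / "a.jsonl")
        write_corpus(ten_records, tmp_path / "b.jsonl")
        assert (tmp_path / "a.jsonl").read_bytes() == (tmp_path / "b.jsonl").read_bytes()


class TestFilters:
    def test_keyword_substring_matches_morphological_forms(self):
        kept = filter_by_keyword([make_record("a", "Are vaccines safe?")], {"vaccine"})
        assert len(kept) == 1

    def test_keyword_miss_drops_record(self):
        rec = make_record("a", "Is masking enough?", [("Yes.", 1)])
        assert filter_by_keyword([rec], {"vaccine"}) == []

    def test_keyword_found_in_answer_keeps_record(self):
        rec = make_record("a", "Is masking enough?", [("No, get the vaccine.", 1)])
        assert len(filter_by_keyword([rec], {"vaccine"})) == 1
        assert filter_by_keyword([rec], {"vaccine"}, search_answers=False) == []

    def test_planted_keyword_carriers_exactly_recovered(self, ten_records):
        kept = filter_by_keyword(ten_records, {"vaccine"})
        assert [r.record_id for r in kept] == [f"r{i}" for i in range(7)]

    def test_empty_keyword_forms_is_error(self, ten_records):
        with pytest.raises(ValueError):
            filter_by_keyword(ten_records, set())

    def test_drop_unanswered_counts(self, ten_records):
        kept = drop_unanswered(ten_records)
        assert len(kept) == 6
        assert all(r.answers for r in kept)

    @pytest.mark.parametrize("op", [lambda r: filter_by_keyword(r, {"vaccine"}), drop_unanswered])
    def test_filters_idempotent(self, ten_records, op):
        once = op(ten_records)
        assert op(once) == once


class TestTopAnswer:
    def test_unique_max_upvotes_wins(self):
        rec = make_record("a", "q", [("x", 3), ("y", 9), ("z", 1)])
        assert select_top_answer(rec).answer_text == "y"

    def test_tie_broken_by_earliest_timestamp(self):
        rec = make_record("a", "q")
        rec.answers = [
            Answer("late", 7, date(2020, 7, 2)),
            Answer("early", 7, date(2020, 7, 1)),
        ]
        assert select_top_answer(rec).answer_text == "early"

    def test_tie_without_timestamps_takes_first_position(self):
        rec = make_record("a", "q", [("first", 7), ("second", 7)])
        assert select_top_answer(rec).answer_text == "first"

    def test_no_answers_is_precondition_error(self):
        with pytest.raises(DataError):
            select_top_answer(make_record("a", "q"))


class TestSampling:
    def test_exact_size_and_repeatability(self, small_world):
        _, records, _ = small_world
        s1 = sample_match(records, 150, seed=9)
        s2 = sample_match(records, 150, seed=9)
        assert len(s1) == 150
        assert s1 == s2
        times = [r.question_timestamp for r in s1]
        assert times == sorted(times)

    def test_full_corpus_degenerate_sample(self, ten_records):
        s = sample_match(ten_records, 10, seed=0)
        assert sorted(r.record_id for r in s) == sorted(r.record_id for r in ten_records)

    def test_different_seeds_differ(self, small_world):
        _, records, _ = small_world
        s1 = sample_match(records, 100, seed=1)
        s2 = sample_match(records, 100, seed=2)
        assert {r.record_id for r in s1} != {r.record_id for r in s2}

    def test_oversample_is_error(self, ten_records):
        with pytest.raises(ValueError):
            sample_match(ten_records, 11, seed=0)


class TestFunnel:
    def test_report_counts_weakly_decreasing(self, ten_records):
        kept, report = preprocess_corpus(ten_records, {"vaccine"}, sample_n=3, seed=5)
        assert (report.n_input, report.n_after_keyword, report.n_after_answered,
                report.n_after_sampling) == (10, 7, 5, 3)
        assert len(kept) == 3

    def test_increasing_counts_rejected(self):
        with pytest.raises(DataError):
            CorpusFilterReport(5, 6, 4, 3, seed=0)

    def test_funnel_deterministic_serialization(self, tmp_path, small_world):
        _, records, _ = small_world
        outs = []
        for name in ("a", "b"):
            kept, _ = preprocess_corpus(records, {"t0"}, sample_n=50, seed=3)
            write_corpus(kept, tmp_path / f"{name}.jsonl")
            outs.append((tmp_path / f"{name}.jsonl").read_bytes())
        assert outs[0] == outs[1]
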