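import random

import numpy as np
import pytest

from forumhealth.corpus_io import RatingRecord
from forumhealth.errors import IncompleteDesignError
from forumhealth.hiq_eval import (
    QuestionItem,
    Questionnaire,
    RatingSet,
    default_questionnaire,
    post_total,
    round_half_up,
    score_range,
    section_stats_from_question_means,
    summarize,
    validate,
)


def complete_design(value=3, n_experts=4, n_posts=25, questionnaire=None):
    q = questionnaire or default_questionnaire()
    records = []
    for e in range(n_experts):
        for p in range(n_posts):
            for item in q.items:
                v = value if isinstance(value, int) else value(e, p, item.id)
                records.append(RatingRecord(f"e{e+1}", f"p{p+1:02d}", item.id, v))
    return RatingSet(records)


class TestQuestionnaire:
    def test_default_shape(self):
        q = default_questionnaire()
        assert q.n_items == 13
        assert q.sections == {
            "S1": [1, 2, 3, 4],
            "S2": [5, 6, 7, 8, 9],
            "S3": [10, 11, 12],
            "SUMMARY": [13],
        }

    def test_nonconsecutive_ids_rejected(self):
        with pytest.raises(ValueError):
            Questionnaire(items=[QuestionItem(2, "x", "S1")])

    def test_config_roundtrip(self, tmp_path):
        cfg = tmp_path / "q.yaml"
        cfg.write_text(
            "items:\n"
            "  - {id: 1, text: one, section: S1}\n"
            "  - {id: 2, text: two, section: S2}\n"
            "scale: {min: 1, max: 5}\n"
        )
        q = Questionnaire.from_config(cfg)
        assert q.n_items == 2 and q.section_of(2) == "S2"


class TestScoreRange:
    def test_thirteen_item_instrument(self):
        assert score_range(default_questionnaire()) == (13, 65)

    def test_three_item_instrument(self):
        q = Questionnaire(items=[QuestionItem(i, "", "S1") for i in (1, 2, 3)])
        assert score_range(q) == (3, 15)

    def test_degenerate_scale(self):
        q = Questionnaire(
            items=[QuestionItem(i, "", "S1") for i in range(1, 14)],
            scale_min=1,
            scale_max=1,
        )
        assert score_range(q) == (13, 13)


class TestPostTotal:
    def test_all_ones_gives_minimum_13(self):
        ratings = complete_design(1, n_posts=2)
        assert post_total(ratings, "p01", "e1") == 13

    def test_all_fives_gives_maximum_65(self):
        ratings = complete_design(5, n_posts=2)
        assert post_total(ratings, "p01", "e1") == 65

    def test_mixed_arithmetic(self):
        # five 3s and eight 2s
        ratings = complete_design(lambda e, p, q: 3 if q <= 5 else 2, n_posts=1)
        assert post_total(ratings, "p01", "e1") == 5 * 3 + 8 * 2

    def test_incomplete_lists_missing_questions(self):
        records = [RatingRecord("e1", "p1", q, 3) for q in range(1, 12)]
        with pytest.raises(IncompleteDesignError) as exc:
            post_total(RatingSet(records), "p1", "e1")
        assert exc.value.missing == [12, 13]


class TestValidate:
    def test_complete_design_reports_complete(self):
        report = validate(complete_design(), default_questionnaire())
        assert report.complete and report.n_records == 1300

    def test_missing_cell_named(self):
        ratings = complete_design(3, n_experts=2, n_posts=2)
        ratings = RatingSet(
            [r for r in ratings.records if not (r.expert_id == "e2" and r.post_id == "p02" and r.question_id == 7)]
        )
        report = validate(ratings, default_questionnaire())
        assert not report.complete
        assert report.missing_cells == [("e2", "p02", 7)]

    def test_duplicate_reported(self):
        ratings = complete_design(3, n_experts=1, n_posts=1)
        dup = RatingSet(ratings.records + [RatingRecord("e1", "p01", 1, 5)])
        report = validate(dup, default_questionnaire())
        assert report.duplicates == [("e1", "p01", 1)]


class TestSummarize:
    def test_constant_ratings(self):
        q = default_questionnaire()
        summary = summarize(complete_design(3), q)
        assert all(m == 3.0 and sd == 0.0 for m, sd in summary.question_stats.values())
        assert all(m == 3.0 for m, _ in summary.section_stats.values())
        assert summary.overall_post_mean == 39.0
        assert summary.overall_post_sd == 0.0
        assert all(m == 39.0 for m, _ in summary.post_stats.values())

    def test_incomplete_design_refused(self):
        q = default_questionnaire()
        ratings = complete_design(3, n_experts=2, n_posts=2)
        broken = RatingSet(ratings.records[:-1])
        with pytest.raises(IncompleteDesignError):
            summarize(broken, q)

    def test_linear_identities_on_random_design(self):
        rng = random.Random(7)
        q = default_questionnaire()
        ratings = complete_design(
            lambda e, p, qid: rng.randint(1, 5), n_experts=4, n_posts=10
        )
        summary = summarize(ratings, q)
        question_means = {qid: m for qid, (m, _) in summary.question_stats.items()}
        # overall post mean = sum of the 13 question means
        assert summary.overall_post_mean == pytest.approx(
            sum(question_means.values()), abs=1e-9
        )
        # section mean = equal-weight mean of its questions' means
        for section, qids in q.sections.items():
            m, _ = summary.section_stats[section]
            assert m == pytest.approx(np.mean([question_means[i] for i in qids]), abs=1e-9)
        # overall question mean = overall post mean / 13
        assert summary.overall_question_mean == pytest.approx(
            summary.overall_post_mean / 13, abs=1e-9
        )

    def test_invariant_to_record_order(self):
        rng = random.Random(3)
        q = default_questionnaire()
        ratings = complete_design(
            lambda e, p, qid: rng.randint(1, 5), n_experts=2, n_posts=5
        )
        shuffled = list(ratings.records)
        random.Random(11).shuffle(shuffled)
        s1 = summarize(ratings, q)
        s2 = summarize(RatingSet(shuffled), q)
        for qid in s1.question_stats:
            assert s1.question_stats[qid] == pytest.approx(
                s2.question_stats[qid], abs=1e-12
            )
        assert s1.overall_post_mean == pytest.approx(s2.overall_post_mean, abs=1e-12)

    def test_tables_render(self):
        q = default_questionnaire()
        summary = summarize(complete_design(3), q)
        t1 = summary.question_table(q)
        assert len(t1) == 13 + 4  # one row per question plus one per section
        t2 = summary.expert_table()
        assert list(t2["expert_id"]) == ["e1", "e2", "e3", "e4"]


def test_section_stats_from_question_means():
    q = default_questionnaire()
    means = {i: 3.0 for i in range(1, 14)}
    out = section_stats_from_question_means(means, q)
    assert out["S1"] == 3.0 and out["overall_post_mean"] == 39.0
    assert out["overall_question_mean"] == 3.0


def test_round_half_up():
    # 0.125 is exactly representable, so the half-way case is genuine
    assert round_half_up(0.125) == 0.13
    assert round_half_up(2.784) == 2.78
    assert round_half_up(-0.125) == -0.13
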