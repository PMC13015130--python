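"""The 13-item health-information-quality (HIQ) expert instrument and its
aggregation statistics.

The instrument has three thematic sections plus a stand-alone summary item:

* Section 1, items 1–4 — reliability of knowledge and evidence-based medicine;
* Section 2, items 5–9 — safety;
* Section 3, items 10–12 — authenticity and personal experiences;
* Summary, item 13 — overall quality judgment.

Each item is rated on a 1–5 scale (1 = no, 5 = yes, 2/4 = partially; for the
summary item, moderately). A post's total score is the sum of its 13 ratings,
so totals range from 13 to 65. Under a complete expert x post x question
design the aggregate statistics obey exact identities: the overall post mean
equals the sum of the 13 question means, a section mean equals the
equal-weight mean of its questions' means, and the overall question mean is
the overall post mean divided by 13.

Standard deviations are sample (n - 1) SDs, pooled over all ratings entering
a cell. Display rounding is half-up to two decimals; internal computation
keeps full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .corpus_io import RatingRecord
from .errors import IncompleteDesignError

__all__ = [
    "QuestionItem",
    "Questionnaire",
    "RatingSet",
    "QualitySummary",
    "ValidationReport",
    "default_questionnaire",
    "validate",
    "post_total",
    "score_range",
    "summarize",
    "section_stats_from_question_means",
    "round_half_up",
]

SECTION_NAMES = {
    "S1": "Reliability of knowledge and evidence-based medicine",
    "S2": "Safety",
    "S3": "Authenticity and personal experiences",
    "SUMMARY": "Summary",
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention for the quality tables)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class QuestionItem:
    id: int
    text: str
    section: str  # S1 | S2 | S3 | SUMMARY


@dataclass
class Questionnaire:
    """An ordered list of rating items grouped into sections, on an integer
    scale (1–5 by default)."""

    items: Sequence[QuestionItem]
    scale_min: int = 1
    scale_max: int = 5

    def __post_init__(self) -> None:
        ids = [item.id for item in self.items]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("item ids must be consecutive starting at 1")
        if self.scale_min > self.scale_max:
            raise ValueError("scale_min must be <= scale_max")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def sections(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for item in self.items:
            out.setdefault(item.section, []).append(item.id)
        return out

    def section_of(self, question_id: int) -> str:
        return self.items[question_id - 1].section

    @classmethod
    def from_config(cls, path: str | Path) -> "Questionnaire":
        cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        items = [
            QuestionItem(int(i["id"]), str(i.get("text", "")), str(i["section"]))
            for i in cfg["items"]
        ]
        scale = cfg.get("scale", {})
        return cls(
            items=items,
            scale_min=int(scale.get("min", 1)),
            scale_max=int(scale.get("max", 5)),
        )


# Paraphrase labels of the instrument's thirteen items.
_DEFAULT_ITEMS = [
    (1, "Consistency with current medical guidelines / evidence-based medicine", "S1"),
    (2, "Accounts for individual differences in reactions to substances", "S1"),
    (3, "Covers tolerance and/or synergy between substances", "S1"),
    (4, "Considers long-term effects of using the substance", "S1"),
    (5, "Information can be considered safe for readers", "S2"),
    (6, "Acknowledges the limitations of the information provided", "S2"),
    (7, "Considers potential risks of substance use", "S2"),
    (8, "Includes information about dosage differences", "S2"),
    (9, "Presents safety guidelines for using the substance", "S2"),
    (10, "Focuses on facts", "S3"),
    (11, "Not overtly anecdotal or subjective", "S3"),
    (12, "Encourages consultation with specialists", "S3"),
    (13, "Overall quality as an information source on substances", "SUMMARY"),
]


def default_questionnaire() -> Questionnaire:
    """The 13-item, three-section HIQ instrument on the 1–5 scale."""
    return Questionnaire(items=[QuestionItem(i, t, s) for i, t, s in _DEFAULT_ITEMS])


class RatingSet:
    """A collection of rating records with at most one record per
    (expert, post, question) cell."""

    def __init__(self, records: Iterable[RatingRecord]):
        self.records: list[RatingRecord] = list(records)
        self.experts = sorted({r.expert_id for r in self.records})
        self.posts = sorted({r.post_id for r in self.records})
        self._cells: dict[tuple[str, str, int], int] = {}
        self.duplicates: list[tuple[str, str, int]] = []
        for r in self.records:
            key = (r.expert_id, r.post_id, r.question_id)
            if key in self._cells:
                self.duplicates.append(key)
            else:
                self._cells[key] = r.rating

    def __len__(self) -> int:
        return len(self.records)

    def rating(self, expert_id: str, post_id: str, question_id: int) -> int:
        return self._cells[(expert_id, post_id, question_id)]

    def missing_cells(self, questionnaire: Questionnaire) -> list[tuple[str, str, int]]:
        return [
            (e, p, item.id)
            for e in self.experts
            for p in self.posts
            for item in questionnaire.items
            if (e, p, item.id) not in self._cells
        ]

    def is_complete(self, questionnaire: Questionnaire) -> bool:
        return not self.duplicates and not self.missing_cells(questionnaire)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.expert_id, r.post_id, r.question_id, r.rating) for r in self.records],
            columns=["expert_id", "post_id", "question_id", "rating"],
        )


@dataclass
class ValidationReport:
    n_records: int
    duplicates: list[tuple[str, str, int]]
    missing_cells: list[tuple[str, str, int]]
    out_of_range: list[tuple[str, str, int, int]]

    @property
    def complete(self) -> bool:
        return not (self.duplicates or self.missing_cells or self.out_of_range)


def validate(ratings: RatingSet, questionnaire: Questionnaire) -> ValidationReport:
    """Report duplicates, out-of-range values and design incompleteness."""
    out_of_range = [
        (r.expert_id, r.post_id, r.question_id, r.rating)
        for r in ratings.records
        if not questionnaire.scale_min <= r.rating <= questionnaire.scale_max
        or not 1 <= r.question_id <= questionnaire.n_items
    ]
    return ValidationReport(
        n_records=len(ratings),
        duplicates=list(ratings.duplicates),
        missing_cells=ratings.missing_cells(questionnaire),
        out_of_range=out_of_range,
    )


def score_range(questionnaire: Questionnaire) -> tuple[int, int]:
    """(minimum, maximum) total score: n_items x scale bounds."""
    return (
        questionnaire.n_items * questionnaire.scale_min,
        questionnaire.n_items * questionnaire.scale_max,
    )


def post_total(
    ratings: RatingSet,
    post_id: str,
    expert_id: str,
    questionnaire: Questionnaire | None = None,
) -> int:
    """Sum of one expert's ratings for one post over all questionnaire items."""
    questionnaire = questionnaire or default_questionnaire()
    values = []
    missing = []
    for item in questionnaire.items:
        key = (expert_id, post_id, item.id)
        if key in ratings._cells:
            values.append(ratings._cells[key])
        else:
            missing.append(item.id)
    if missing:
        raise IncompleteDesignError(
            f"expert {expert_id!r}, post {post_id!r}: missing questions {missing}",
            missing=missing,
        )
    return int(sum(values))


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return mean, sd


@dataclass
class QualitySummary:
    """All aggregates of a complete rating design.

    ``question_stats`` and ``section_stats`` pool ratings over experts and
    posts; ``post_stats`` aggregate per-expert post totals;
    ``expert_section_stats`` pool one expert's ratings in a section across
    posts.
    """

    question_stats: dict[int, tuple[float, float]]
    section_stats: dict[str, tuple[float, float]]
    post_stats: dict[str, tuple[float, float]]
    expert_section_stats: dict[tuple[str, str], tuple[float, float]]
    overall_post_mean: float
    overall_post_sd: float
    overall_question_mean: float
    overall_question_sd: float

    def question_table(self, questionnaire: Questionnaire) -> pd.DataFrame:
        """Section-and-question means/SDs, rounded for display (2 d.p.)."""
        rows = []
        for section, qids in questionnaire.sections.items():
            if section in self.section_stats:
                m, sd = self.section_stats[section]
                rows.append(
                    ("section", section, SECTION_NAMES.get(section, section),
                     round_half_up(m), round_half_up(sd))
                )
            for qid in qids:
                m, sd = self.question_stats[qid]
                rows.append(
                    ("question", f"Q{qid}", questionnaire.items[qid - 1].text,
                     round_half_up(m), round_half_up(sd))
                )
        return pd.DataFrame(rows, columns=["level", "id", "label", "mean", "sd"])

    def expert_table(self) -> pd.DataFrame:
        """Per-expert section means/SDs (2 d.p.), experts as rows."""
        experts = sorted({e for e, _ in self.expert_section_stats})
        sections = sorted({s for _, s in self.expert_section_stats})
        rows = []
        for e in experts:
            row: dict[str, object] = {"expert_id": e}
            for s in sections:
                m, sd = self.expert_section_stats[(e, s)]
                row[f"{s}_mean"] = round_half_up(m)
                row[f"{s}_sd"] = round_half_up(sd)
            rows.append(row)
        return pd.DataFrame(rows)


def summarize(ratings: RatingSet, questionnaire: Questionnaire) -> QualitySummary:
    """Compute every aggregate of a complete design; refuses incomplete data."""
    if ratings.duplicates:
        raise IncompleteDesignError(
            f"duplicate records present: {ratings.duplicates[:5]}"
        )
    missing = ratings.missing_cells(questionnaire)
    if missing:
        raise IncompleteDesignError(
            f"incomplete design: {len(missing)} missing cells, first {missing[:5]}",
            missing=missing,
        )
    if not ratings.records:
        raise IncompleteDesignError("empty rating set")

    by_question: dict[int, list[int]] = {item.id: [] for item in questionnaire.items}
    by_section: dict[str, list[int]] = {s: [] for s in questionnaire.sections}
    by_expert_section: dict[tuple[str, str], list[int]] = {}
    for r in ratings.records:
        section = questionnaire.section_of(r.question_id)
        by_question[r.question_id].append(r.rating)
        by_section[section].append(r.rating)
        by_expert_section.setdefault((r.expert_id, section), []).append(r.rating)

    totals_by_post: dict[str, list[int]] = {
        p: [post_total(ratings, p, e, questionnaire) for e in ratings.experts]
        for p in ratings.posts
    }
    all_totals = [t for ts in totals_by_post.values() for t in ts]
    all_ratings = [r.rating for r in ratings.records]

    overall_post_mean, overall_post_sd = _mean_sd(all_totals)
    overall_question_mean, overall_question_sd = _mean_sd(all_ratings)
    return QualitySummary(
        question_stats={q: _mean_sd(v) for q, v in by_question.items()},
        section_stats={s: _mean_sd(v) for s, v in by_section.items()},
        post_stats={p: _mean_sd(v) for p, v in totals_by_post.items()},
        expert_section_stats={k: _mean_sd(v) for k, v in by_expert_section.items()},
        overall_post_mean=overall_post_mean,
        overall_post_sd=overall_post_sd,
        overall_question_mean=overall_question_mean,
        overall_question_sd=overall_question_sd,
    )


def section_stats_from_question_means(
    question_means: Mapping[int, float], questionnaire: Questionnaire
) -> dict[str, float]:
    """Section means implied by question-level means under a complete design
    (equal-weight mean of each section's question means), plus the implied
    overall post mean (sum of all question means) and overall question mean
    (that sum divided by the item count).

    Useful for checking published question-level tables for internal
    consistency without access to the raw ratings.
    """
    if set(question_means) != {item.id for item in questionnaire.items}:
        raise ValueError("question_means must cover exactly the questionnaire items")
    out: dict[str, float] = {}
    for section, qids in questionnaire.sections.items():
        out[section] = float(np.mean([question_means[q] for q in qids]))
    total = float(sum(question_means.values()))
    out["overall_post_mean"] = total
    out["overall_question_mean"] = total / questionnaire.n_items
    return out
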