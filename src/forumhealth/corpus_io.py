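"""Readers and writers for forum corpora, category lexicons and expert ratings.

Interchange formats are deliberately plain text:

* posts — JSON-lines (one post per line) or CSV with the same header
  ``post_id,raw_text,thread_id,board,published_at``;
* tokenized posts — JSON-lines with keys ``post_id`` and ``tokens``;
* lexicon — tab-separated ``term / category / canonical`` (canonical empty
  when the term is its own canonical form);
* expert ratings — long-format CSV ``expert_id,post_id,question_id,rating``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import (
    CorpusFormatError,
    DuplicatePostIdError,
    LexiconError,
    RatingFormatError,
)

#: The closed set of lexicon categories: psychoactive substances plus the
#: seven health-related word classes used for seed selection.
CATEGORIES = frozenset(
    {
        "substance",
        "medicines_supplements",
        "medical_conditions",
        "medical_specializations",
        "medical_procedures",
        "body_parts_tissues",
        "organism_processes",
        "knowledge_sources",
    }
)

#: Categories that count as "medical treatment" in the narrow sense.
MEDICAL_TREATMENT_CATEGORIES = frozenset(
    {
        "medicines_supplements",
        "medical_conditions",
        "medical_specializations",
        "medical_procedures",
    }
)

POST_FIELDS = ("post_id", "raw_text", "thread_id", "board", "published_at")


@dataclass(frozen=True)
class Post:
    """One forum message, the atomic corpus unit."""

    post_id: str
    raw_text: str
    thread_id: str | None = None
    board: str | None = None
    published_at: str | None = None


@dataclass(frozen=True)
class TokenizedPost:
    """A post after normalization: lowercase canonical lemmas, in order."""

    post_id: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


class Corpus:
    """Ordered collection of posts with unique ids and stable iteration order."""

    def __init__(self, posts: Iterable[Post], source_label: str = ""):
        self.posts: list[Post] = []
        self.source_label = source_label
        seen: set[str] = set()
        for i, post in enumerate(posts):
            if post.post_id in seen:
                raise DuplicatePostIdError(post.post_id, record_index=i)
            seen.add(post.post_id)
            self.posts.append(post)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts)

    def __len__(self) -> int:
        return len(self.posts)

    def __getitem__(self, i: int) -> Post:
        return self.posts[i]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Corpus)
            and self.posts == other.posts
            and self.source_label == other.source_label
        )


@dataclass
class Lexicon:
    """Term -> category map plus a synonym (variant -> canonical) map.

    ``entries`` hold curated terms with a category from :data:`CATEGORIES`;
    ``synonym_map`` sends surface variants (e.g. slang drug names) to one
    canonical term. Chains in the synonym map are resolved on construction so
    canonicalization is idempotent.
    """

    entries: dict[str, str] = field(default_factory=dict)
    synonym_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, cat in self.entries.items():
            if cat not in CATEGORIES:
                raise LexiconError(f"unknown category {cat!r} for term {term!r}")
        self.synonym_map = _resolve_chains(self.synonym_map)

    def canonicalize(self, token: str) -> str:
        return self.synonym_map.get(token, token)

    def category(self, term: str) -> str | None:
        return self.entries.get(term)

    def terms_in(self, categories: Iterable[str]) -> set[str]:
        wanted = set(categories)
        unknown = wanted - CATEGORIES
        if unknown:
            raise LexiconError(f"unknown categories: {sorted(unknown)}")
        return {t for t, c in self.entries.items() if c in wanted}

    def substances(self) -> set[str]:
        return self.terms_in({"substance"})

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Lexicon)
            and self.entries == other.entries
            and self.synonym_map == other.synonym_map
        )


def _resolve_chains(synonym_map: dict[str, str]) -> dict[str, str]:
    """Follow variant -> canonical chains to a fixed point; reject cycles."""
    resolved: dict[str, str] = {}
    for variant, target in synonym_map.items():
        seen = {variant}
        while target in synonym_map:
            if target in seen:
                raise LexiconError(f"synonym cycle involving {variant!r}")
            seen.add(target)
            target = synonym_map[target]
        resolved[variant] = target
    return resolved


@dataclass(frozen=True)
class RatingRecord:
    """One expert's answer to one questionnaire item for one post."""

    expert_id: str
    post_id: str
    question_id: int
    rating: int

    def __post_init__(self) -> None:
        if not 1 <= self.question_id <= 13:
            raise RatingFormatError(
                f"question_id {self.question_id} outside 1..13"
            )
        if self.rating not in (1, 2, 3, 4, 5):
            raise RatingFormatError(f"rating {self.rating} outside 1..5")


# ---------------------------------------------------------------------------
# posts


def read_posts(path: str | Path, format: str | None = None) -> Corpus:
    """Read a post corpus from JSONL or CSV, preserving record order.

    ``format`` is ``"jsonl"`` or ``"csv"``; when omitted it is inferred from
    the file suffix (default JSONL).
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        records = _iter_jsonl(path)
    elif fmt == "csv":
        records = _iter_csv(path)
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")

    posts: list[Post] = []
    seen: set[str] = set()
    for i, rec in records:
        if "post_id" not in rec or rec["post_id"] in ("", None):
            raise CorpusFormatError("missing post_id", record_index=i)
        if "raw_text" not in rec or rec["raw_text"] is None:
            raise CorpusFormatError("missing raw_text", record_index=i)
        pid = str(rec["post_id"])
        if pid in seen:
            raise DuplicatePostIdError(pid, record_index=i)
        seen.add(pid)
        posts.append(
            Post(
                post_id=pid,
                raw_text=str(rec["raw_text"]),
                thread_id=_opt(rec.get("thread_id")),
                board=_opt(rec.get("board")),
                published_at=_opt(rec.get("published_at")),
            )
        )
    return Corpus(posts, source_label=str(path))


def _opt(value) -> str | None:
    return None if value in (None, "") else str(value)


def _iter_jsonl(path: Path):
    with path.open(encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"invalid JSON ({exc})", record_index=i)
            if not isinstance(rec, dict):
                raise CorpusFormatError("record is not an object", record_index=i)
            yield i, rec


def _iter_csv(path: Path):
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for i, rec in enumerate(reader):
            yield i, rec


def write_posts(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for post in corpus:
                rec = {k: getattr(post, k) for k in POST_FIELDS}
                rec = {k: v for k, v in rec.items() if v is not None}
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(POST_FIELDS))
            writer.writeheader()
            for post in corpus:
                writer.writerow(
                    {k: getattr(post, k) or "" for k in POST_FIELDS}
                )
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")


# ---------------------------------------------------------------------------
# tokenized posts


def read_tokenized(path: str | Path) -> list[TokenizedPost]:
    """Read normalized posts (JSONL with ``post_id`` and ``tokens``)."""
    out: list[TokenizedPost] = []
    seen: set[str] = set()
    for i, rec in _iter_jsonl(Path(path)):
        if "post_id" not in rec or "tokens" not in rec:
            raise CorpusFormatError("missing post_id or tokens", record_index=i)
        pid = str(rec["post_id"])
        if pid in seen:
            raise DuplicatePostIdError(pid, record_index=i)
        seen.add(pid)
        out.append(TokenizedPost(pid, tuple(str(t) for t in rec["tokens"])))
    return out


def write_tokenized(posts: Iterable[TokenizedPost], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for post in posts:
            fh.write(
                json.dumps(
                    {"post_id": post.post_id, "tokens": list(post.tokens)},
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# lexicon


def read_lexicon(path: str | Path) -> Lexicon:
    """Read a tab-separated ``term / category / canonical`` lexicon."""
    entries: dict[str, str] = {}
    synonym_map: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise LexiconError(f"line {i}: expected term<TAB>category")
            term, category = parts[0].strip(), parts[1].strip()
            canonical = parts[2].strip() if len(parts) > 2 else ""
            if category not in CATEGORIES:
                raise LexiconError(f"line {i}: unknown category {category!r}")
            entries[term] = category
            if canonical and canonical != term:
                if term in synonym_map and synonym_map[term] != canonical:
                    raise LexiconError(
                        f"line {i}: variant {term!r} maps to both "
                        f"{synonym_map[term]!r} and {canonical!r}"
                    )
                synonym_map[term] = canonical
    return Lexicon(entries=entries, synonym_map=synonym_map)


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for term in sorted(lexicon.entries):
            canonical = lexicon.synonym_map.get(term, "")
            fh.write(f"{term}\t{lexicon.entries[term]}\t{canonical}\n")


# ---------------------------------------------------------------------------
# ratings


def read_ratings(path: str | Path) -> list[RatingRecord]:
    """Read long-format expert ratings, validating every record."""
    out: list[RatingRecord] = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"expert_id", "post_id", "question_id", "rating"}
        if reader.fieldnames is None:
            return out
        missing = required - set(reader.fieldnames)
        if missing:
            raise RatingFormatError(f"missing columns: {sorted(missing)}")
        for i, rec in enumerate(reader, start=2):  # header is row 1
            try:
                qid = int(rec["question_id"])
                rating = int(rec["rating"])
            except (TypeError, ValueError):
                raise RatingFormatError("non-integer question_id or rating", row=i)
            try:
                out.append(
                    RatingRecord(
                        expert_id=str(rec["expert_id"]),
                        post_id=str(rec["post_id"]),
                        question_id=qid,
                        rating=rating,
                    )
                )
            except RatingFormatError as exc:
                raise RatingFormatError(str(exc), row=i)
    return out


def write_ratings(records: Iterable[RatingRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["expert_id", "post_id", "question_id", "rating"])
        for r in records:
            writer.writerow([r.expert_id, r.post_id, r.question_id, r.rating])
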