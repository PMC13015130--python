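"""Health-keyword lexicon construction: frequency-seeded candidates, category
filtering against a curated lexicon, and embedding-based semantic expansion.

The frequency threshold keeps common words while leaving the candidate list
short enough for human verification; the curated-lexicon intersection stands
in for that manual selection step, making the pipeline reproducible while a
real user can substitute genuine expert review. Expansion is a single pass:
every vocabulary word whose cosine similarity to at least one seed strictly
exceeds the threshold is admitted, provided the curated lexicon vouches for
it (the verification step). No transitive closure — expanded words do not
recruit further words.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .corpus_io import CATEGORIES, Lexicon, TokenizedPost
from .errors import LexiconError
from .semantic_model import EmbeddingModel, neighbors

__all__ = [
    "FrequencyTable",
    "KeywordEntry",
    "KeywordSet",
    "count_frequencies",
    "frequency_filter",
    "seed_select",
    "expand",
    "write_keywords",
    "read_keywords",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_OCCURRENCES = 5000
DEFAULT_EXPANSION_THRESHOLD = 0.7


@dataclass(frozen=True)
class KeywordEntry:
    category: str
    provenance: str  # "seed" | "expanded"
    anchor: str | None = None
    similarity: float | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("seed", "expanded"):
            raise ValueError(f"bad provenance {self.provenance!r}")
        if self.provenance == "seed" and (self.anchor or self.similarity):
            raise ValueError("seed entries carry no anchor/similarity")
        if self.provenance == "expanded" and (
            self.anchor is None or self.similarity is None
        ):
            raise ValueError("expanded entries need anchor and similarity")


class KeywordSet(dict):
    """term -> :class:`KeywordEntry`; a dict with provenance helpers."""

    def seeds(self) -> set[str]:
        return {t for t, e in self.items() if e.provenance == "seed"}

    def expanded(self) -> set[str]:
        return {t for t, e in self.items() if e.provenance == "expanded"}

    def terms_in(self, categories: Iterable[str]) -> set[str]:
        wanted = set(categories)
        return {t for t, e in self.items() if e.category in wanted}


class FrequencyTable(Counter):
    """term -> corpus frequency; a Counter restricted to positive counts."""


def count_frequencies(corpus: Iterable[TokenizedPost]) -> FrequencyTable:
    table = FrequencyTable()
    for post in corpus:
        table.update(post.tokens)
    return table


def frequency_filter(freq: Mapping[str, int], min_occurrences: int) -> set[str]:
    """Terms occurring strictly more than ``min_occurrences`` times."""
    if min_occurrences < 0:
        raise ValueError("min_occurrences must be >= 0")
    return {t for t, c in freq.items() if c > min_occurrences}


def seed_select(
    candidates: Iterable[str],
    lexicon: Lexicon,
    categories: Iterable[str] | None = None,
) -> KeywordSet:
    """Keep the candidates the curated lexicon labels with an allowed
    category; provenance ``seed``."""
    cats = set(categories) if categories is not None else set(CATEGORIES)
    unknown = cats - CATEGORIES
    if unknown:
        raise LexiconError(f"unknown categories: {sorted(unknown)}")
    out = KeywordSet()
    for term in candidates:
        cat = lexicon.category(term)
        if cat in cats:
            out[term] = KeywordEntry(category=cat, provenance="seed")
    return out


def expand(
    seeds: KeywordSet,
    model: EmbeddingModel,
    threshold: float = DEFAULT_EXPANSION_THRESHOLD,
    lexicon: Lexicon | None = None,
    categories: Iterable[str] | None = None,
) -> KeywordSet:
    """One round of cosine expansion with lexicon verification.

    Each candidate must be a neighbor of at least one seed with similarity
    strictly above ``threshold`` *and* carry an allowed lexicon category
    (the verification step). Its ``anchor`` is the seed of maximal
    similarity. Seeds missing from the model vocabulary are retained without
    contributing neighbors (logged as a warning).
    """
    cats = set(categories) if categories is not None else set(CATEGORIES)
    out = KeywordSet(seeds)
    best: dict[str, tuple[float, str]] = {}
    for seed in sorted(seeds):
        if seed not in model:
            logger.warning("seed %r not in embedding vocabulary; kept without neighbors", seed)
            continue
        for term, sim in neighbors(model, seed, threshold):
            if term in seeds:
                continue
            if lexicon is not None:
                cat = lexicon.category(term)
                if cat is None or cat not in cats:
                    continue
            current = best.get(term)
            if current is None or sim > current[0]:
                best[term] = (sim, seed)
    for term, (sim, anchor) in best.items():
        category = lexicon.category(term) if lexicon is not None else "substance"
        out[term] = KeywordEntry(
            category=category, provenance="expanded", anchor=anchor, similarity=sim
        )
    return out


def write_keywords(keywords: KeywordSet, path: str | Path) -> None:
    """TSV export: term / category / provenance / anchor / similarity."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("term\tcategory\tprovenance\tanchor\tsimilarity\n")
        for term in sorted(keywords):
            e = keywords[term]
            anchor = e.anchor or ""
            sim = f"{e.similarity:.6f}" if e.similarity is not None else ""
            fh.write(f"{term}\t{e.category}\t{e.provenance}\t{anchor}\t{sim}\n")


def read_keywords(path: str | Path) -> KeywordSet:
    out = KeywordSet()
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            term, category, provenance, anchor, sim = line.rstrip("\n").split("\t")
            out[term] = KeywordEntry(
                category=category,
                provenance=provenance,
                anchor=anchor or None,
                similarity=float(sim) if sim else None,
            )
    return out
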