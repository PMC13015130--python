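"""Substance–topic semantic-association profiles (the radar-plot quantities).

A profile scores each (substance, topic) pair by aggregating the cosine
similarity between the substance's vector and the vectors of the topic's
keywords. This measures *shared context*, not co-occurrence: a substance and
a topic score highly when they appear in similar local contexts, even if the
words never meet in the same document. The default aggregation is the mean
over topic keywords; ``max`` is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import VocabularyError
from .semantic_model import EmbeddingModel, cosine
from .topic_discovery import TopicPartition

__all__ = ["SubstanceTopicProfile", "profile", "export_radar", "plot_radar"]

logger = logging.getLogger(__name__)


@dataclass
class SubstanceTopicProfile:
    """(substance, topic) -> association score in [-1, 1], or None when a
    topic has no in-vocabulary keyword (a missing value, never 0)."""

    values: dict[tuple[str, int], float | None]
    aggregation: str
    substances: tuple[str, ...]
    topic_ids: tuple[int, ...]
    topic_labels: dict[int, str]

    def score(self, substance: str, topic_id: int) -> float | None:
        return self.values[(substance, topic_id)]

    def ranked_topics(self, substance: str) -> list[int]:
        """Topic ids sorted by descending score (missing topics excluded)."""
        scored = [
            (t, v)
            for (s, t), v in self.values.items()
            if s == substance and v is not None
        ]
        return [t for t, _ in sorted(scored, key=lambda p: (-p[1], p[0]))]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "substance": s,
                "topic_id": t,
                "topic_label": self.topic_labels.get(t, f"topic_{t}"),
                "score": self.values[(s, t)],
            }
            for s in self.substances
            for t in self.topic_ids
        ]
        return pd.DataFrame(rows)


def profile(
    model: EmbeddingModel,
    substances: Iterable[str],
    partition: TopicPartition,
    aggregation: str = "mean",
) -> SubstanceTopicProfile:
    """Aggregate cosine similarities between substances and topic keywords.

    Substances missing from the vocabulary are dropped with a warning; if
    none remain, that is an error. Topics whose keywords are all out of
    vocabulary yield ``None`` scores.
    """
    if aggregation not in ("mean", "max"):
        raise ValueError("aggregation must be 'mean' or 'max'")
    requested = sorted(set(substances))
    kept = [s for s in requested if s in model]
    dropped = sorted(set(requested) - set(kept))
    if dropped:
        logger.warning("substances not in vocabulary, dropped: %s", dropped)
    if not kept:
        raise VocabularyError("no substance is present in the model vocabulary")
    topics = partition.topics
    if not topics:
        raise ValueError("partition has no topics")

    values: dict[tuple[str, int], float | None] = {}
    for s in kept:
        for t, words in topics.items():
            sims = [cosine(model, s, k) for k in sorted(words) if k in model]
            if not sims:
                values[(s, t)] = None
            elif aggregation == "mean":
                values[(s, t)] = float(sum(sims) / len(sims))
            else:
                values[(s, t)] = float(max(sims))
    return SubstanceTopicProfile(
        values=values,
        aggregation=aggregation,
        substances=tuple(kept),
        topic_ids=tuple(sorted(topics)),
        topic_labels={t: partition.label(t) for t in topics},
    )


def export_radar(profile: SubstanceTopicProfile, path: str | Path) -> None:
    """Long-format CSV substance / topic_id / topic_label / score, sorted by
    substance then topic id; missing scores written as empty cells."""
    if not profile.values:
        raise ValueError("cannot export an empty profile")
    frame = profile.to_frame().sort_values(["substance", "topic_id"])
    frame.to_csv(path, index=False, float_format="%.6f")


def plot_radar(profile: SubstanceTopicProfile, substance: str, path: str | Path) -> None:
    """Optional radar chart for one substance (requires matplotlib)."""
    import math

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    topics = [t for t in profile.topic_ids if profile.score(substance, t) is not None]
    scores = [profile.score(substance, t) for t in topics]
    angles = [2 * math.pi * i / len(topics) for i in range(len(topics))]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(angles + angles[:1], scores + scores[:1])
    ax.fill(angles + angles[:1], scores + scores[:1], alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels([profile.topic_labels.get(t, str(t)) for t in topics], fontsize=7)
    ax.set_title(substance)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
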