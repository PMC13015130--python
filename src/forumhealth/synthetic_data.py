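"""Synthetic forum corpora with planted topic structure, and synthetic
expert ratings, with ground truth attached.

The corpus generator plants topics through *co-occurrence*, not vector
geometry: each post is assigned one of K topics, and each token slot is
filled from that topic's word list with probability ``topic_purity`` (else
from a shared background vocabulary). Substances are extra tokens inserted
into posts whose topic matches the substance's configured affinity. Embedding
training must therefore actually discover the structure from local contexts —
the same mechanism the real pipeline relies on — before graph clustering can
recover it.

The rating generator draws each expert x post x question cell as
``clip(round(latent_quality[post] + expert_bias[expert] + N(0, noise_sd)))``
on the 1–5 scale: the simplest generative model consistent with a bounded
ordinal instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .corpus_io import Lexicon, RatingRecord, TokenizedPost, write_tokenized
from .errors import ConfigError
from .hiq_eval import Questionnaire, RatingSet

__all__ = [
    "CorpusGenConfig",
    "CorpusGroundTruth",
    "RatingGenConfig",
    "generate_corpus",
    "generate_lexicon",
    "generate_ratings",
    "exact_mean_design",
    "recovery_ari",
    "RecoveryResult",
    "evaluate_recovery",
    "export_corpus",
]

# Category cycle used when labelling planted topic words in the synthetic lexicon.
_MEDICAL_CYCLE = (
    "medicines_supplements",
    "medical_conditions",
    "medical_specializations",
    "medical_procedures",
    "body_parts_tissues",
    "organism_processes",
    "knowledge_sources",
)


@dataclass(frozen=True)
class CorpusGenConfig:
    """Planted-topic corpus parameters.

    Defaults match the package's reference recovery conditions: 4 topics of
    15 words, 2000 posts of 8–15 tokens, topic purity 0.85, a 100-word
    background vocabulary, 4 substances (one per topic) inserted with
    probability 0.8.
    """

    n_topics: int = 4
    words_per_topic: int = 15
    n_substances: int = 4
    substance_topic_affinity: Mapping[int, int] | None = None
    n_posts: int = 2000
    post_length: tuple[int, int] = (8, 15)
    topic_purity: float = 0.85
    background_vocab_size: int = 100
    substance_insert_prob: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 2:
            raise ConfigError("n_topics must be >= 2")
        if not 0.0 < self.topic_purity <= 1.0:
            raise ConfigError("topic_purity must be in (0, 1]")
        if self.topic_purity <= 1.0 / self.n_topics:
            raise ConfigError("topic_purity must exceed 1/n_topics (identifiability)")
        if min(self.words_per_topic, self.background_vocab_size) < 1:
            raise ConfigError("vocabulary sizes must be positive")
        if self.n_posts < 0 or self.n_substances < 0:
            raise ConfigError("n_posts and n_substances must be >= 0")
        lo, hi = self.post_length
        if not 1 <= lo <= hi:
            raise ConfigError("post_length must satisfy 1 <= min <= max")
        if not 0.0 <= self.substance_insert_prob <= 1.0:
            raise ConfigError("substance_insert_prob must be in [0, 1]")

    def affinity(self) -> dict[int, int]:
        if self.substance_topic_affinity is not None:
            aff = dict(self.substance_topic_affinity)
            if any(t not in range(self.n_topics) for t in aff.values()):
                raise ConfigError("affinity targets must be valid topic indices")
            return aff
        return {s: s % self.n_topics for s in range(self.n_substances)}

    def topic_words(self) -> list[list[str]]:
        return [
            [f"topic{k}_word{j:02d}" for j in range(self.words_per_topic)]
            for k in range(self.n_topics)
        ]

    def substance_terms(self) -> list[str]:
        return [f"substance{s:02d}" for s in range(self.n_substances)]

    def background_words(self) -> list[str]:
        return [f"bg_word{j:03d}" for j in range(self.background_vocab_size)]


@dataclass
class CorpusGroundTruth:
    """Planted labels: word -> topic, post -> topic, substance -> topic."""

    word_topic: dict[str, int]
    post_topic: dict[str, int]
    substance_affinity: dict[str, int]

    def export(self, directory: str | Path) -> None:
        directory = Path(directory)
        with (directory / "word_topic.tsv").open("w", encoding="utf-8") as fh:
            for w in sorted(self.word_topic):
                fh.write(f"{w}\t{self.word_topic[w]}\n")
        with (directory / "post_topic.tsv").open("w", encoding="utf-8") as fh:
            for p in sorted(self.post_topic):
                fh.write(f"{p}\t{self.post_topic[p]}\n")
        with (directory / "substance_affinity.tsv").open("w", encoding="utf-8") as fh:
            for s in sorted(self.substance_affinity):
                fh.write(f"{s}\t{self.substance_affinity[s]}\n")


def generate_corpus(
    cfg: CorpusGenConfig,
) -> tuple[list[TokenizedPost], CorpusGroundTruth]:
    """Generate a planted-topic corpus of already-normalized posts.

    Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    topic_words = cfg.topic_words()
    background = cfg.background_words()
    substances = cfg.substance_terms()
    affinity = cfg.affinity()

    posts: list[TokenizedPost] = []
    post_topic: dict[str, int] = {}
    lo, hi = cfg.post_length
    for i in range(cfg.n_posts):
        topic = int(rng.integers(0, cfg.n_topics))
        length = int(rng.integers(lo, hi + 1))
        tokens: list[str] = []
        for _ in range(length):
            if rng.random() < cfg.topic_purity:
                tokens.append(topic_words[topic][int(rng.integers(0, cfg.words_per_topic))])
            else:
                tokens.append(background[int(rng.integers(0, cfg.background_vocab_size))])
        for s_idx, s_topic in affinity.items():
            if s_topic == topic and rng.random() < cfg.substance_insert_prob:
                pos = int(rng.integers(0, len(tokens) + 1))
                tokens.insert(pos, substances[s_idx])
        post_id = f"synth-{i:05d}"
        posts.append(TokenizedPost(post_id, tuple(tokens)))
        post_topic[post_id] = topic

    word_topic = {
        w: k for k, words in enumerate(topic_words) for w in words
    }
    truth = CorpusGroundTruth(
        word_topic=word_topic,
        post_topic=post_topic,
        substance_affinity={substances[s]: t for s, t in affinity.items()},
    )
    return posts, truth


def generate_lexicon(cfg: CorpusGenConfig) -> Lexicon:
    """A curated lexicon consistent with the planted corpus: every topic word
    gets a medical category (cycled over the seven classes), every substance
    the ``substance`` category. Background words are absent, so they are
    rejected by lexicon-verified expansion exactly as non-health words are."""
    entries: dict[str, str] = {}
    for k, words in enumerate(cfg.topic_words()):
        for j, w in enumerate(words):
            entries[w] = _MEDICAL_CYCLE[(k + j) % len(_MEDICAL_CYCLE)]
    for s in cfg.substance_terms():
        entries[s] = "substance"
    return Lexicon(entries=entries)


# ---------------------------------------------------------------------------
# ratings


@dataclass(frozen=True)
class RatingGenConfig:
    """Synthetic expert-rating parameters.

    ``latent_quality`` maps each post to its true quality on the 1–5 scale;
    ``expert_bias`` shifts one rater's scores; ``noise_sd`` is the SD of the
    per-cell Gaussian noise before rounding and clipping.
    """

    n_experts: int
    latent_quality: Mapping[str, float]
    expert_bias: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ConfigError("n_experts must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if any(not 1.0 <= q <= 5.0 for q in self.latent_quality.values()):
            raise ConfigError("latent qualities must lie in [1, 5]")

    def expert_ids(self) -> list[str]:
        return [f"expert{e+1}" for e in range(self.n_experts)]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generate_ratings(cfg: RatingGenConfig, questionnaire: Questionnaire) -> RatingSet:
    """Complete expert x post x question design; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    records: list[RatingRecord] = []
    experts = cfg.expert_ids()
    for expert in experts:
        bias = float(cfg.expert_bias.get(expert, 0.0))
        for post_id in cfg.latent_quality:
            latent = float(cfg.latent_quality[post_id]) + bias
            for item in questionnaire.items:
                value = latent + (
                    rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
                )
                rating = min(5, max(1, _round_half_up(value)))
                records.append(
                    RatingRecord(
                        expert_id=expert,
                        post_id=post_id,
                        question_id=item.id,
                        rating=rating,
                    )
                )
    return RatingSet(records)


def exact_mean_design(
    question_means: Mapping[int, float],
    questionnaire: Questionnaire,
    n_experts: int = 4,
    n_posts: int = 25,
) -> RatingSet:
    """A complete integer design whose per-question means equal the given
    targets *exactly*.

    For each question the target mean m over n = n_experts * n_posts cells
    must satisfy ``m * n`` integer (to float tolerance) with m on the rating
    scale; the cells then receive ``floor(m)`` or ``floor(m) + 1`` in a fixed
    order. Useful for checking published question-level summary tables for
    internal consistency by running them through the full aggregation path.
    """
    n_cells = n_experts * n_posts
    experts = [f"expert{e+1}" for e in range(n_experts)]
    posts = [f"post{p+1:02d}" for p in range(n_posts)]
    records: list[RatingRecord] = []
    for item in questionnaire.items:
        m = float(question_means[item.id])
        total = m * n_cells
        s = int(round(total))
        if abs(total - s) > 1e-6:
            raise ConfigError(
                f"question {item.id}: mean {m} not realizable over {n_cells} cells"
            )
        base, extra = divmod(s, n_cells)
        if base < questionnaire.scale_min or base + (1 if extra else 0) > questionnaire.scale_max:
            raise ConfigError(f"question {item.id}: mean {m} outside the rating scale")
        cell = 0
        for expert in experts:
            for post in posts:
                rating = base + 1 if cell < extra else base
                records.append(RatingRecord(expert, post, item.id, rating))
                cell += 1
    return RatingSet(records)


# ---------------------------------------------------------------------------
# recovery metric


def recovery_ari(predicted: Mapping, truth: Mapping) -> float:
    """Adjusted Rand index between two labelings of the same items.

    1 for identical partitions up to relabeling; expectation ~0 under random
    labeling.
    """
    if set(predicted) != set(truth):
        missing = set(truth) ^ set(predicted)
        raise KeyError(f"partitions cover different items: {sorted(missing)[:5]} ...")
    keys = sorted(predicted)
    a = [predicted[k] for k in keys]
    b = [truth[k] for k in keys]
    return float(adjusted_rand_score(b, a))


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of one end-to-end planted-structure recovery run."""

    ari: float
    n_topics_found: int
    edge_threshold: float
    substances_ranked_first: int
    n_substances: int

    @property
    def all_substances_ranked_first(self) -> bool:
        return self.substances_ranked_first == self.n_substances


def evaluate_recovery(
    cfg: CorpusGenConfig,
    dimension: int = 50,
    epochs: int = 15,
    window: int = 10,
    edge_percentile: float = 90.0,
) -> RecoveryResult:
    """Run the whole chain on a planted corpus and measure recovery.

    Generates a corpus from ``cfg``, trains skip-gram embeddings, builds the
    keyword graph with the edge threshold set at ``edge_percentile`` of the
    pairwise keyword cosines (synthetic embedding scales differ from real
    corpora, so a percentile is more robust than a fixed cutoff), partitions
    it with Louvain, and returns the adjusted Rand index against the planted
    word-topic labels plus, for each substance, whether its planted topic is
    ranked first in the substance-topic association profile.
    """
    import numpy as np

    from .association import profile as association_profile
    from .semantic_model import EmbeddingParams, train_skipgram
    from .topic_discovery import TopicPartition, build_graph, louvain

    posts, truth = generate_corpus(cfg)
    model = train_skipgram(
        posts,
        EmbeddingParams(
            window=window, dimension=dimension, epochs=epochs, seed=cfg.seed
        ),
    )
    keywords = sorted(k for k in truth.word_topic if k in model)
    unit = model.unit_vectors[[model._idx(k) for k in keywords]]
    sims = unit @ unit.T
    pair_vals = sims[np.triu_indices(len(keywords), 1)]
    threshold = float(np.percentile(pair_vals, edge_percentile))

    graph = build_graph(model, keywords, edge_threshold=threshold)
    partition = louvain(graph, seed=cfg.seed)
    truth_restricted = {k: truth.word_topic[k] for k in partition.assignment}
    ari = recovery_ari(partition.assignment, truth_restricted)

    planted = TopicPartition(
        assignment={k: t for k, t in truth.word_topic.items() if k in model},
        modularity=0.0,
        resolution=1.0,
        seed=cfg.seed,
    )
    prof = association_profile(
        model, list(truth.substance_affinity), planted, aggregation="mean"
    )
    ranked_first = sum(
        1
        for s, t in truth.substance_affinity.items()
        if s in prof.substances and prof.ranked_topics(s)[0] == t
    )
    return RecoveryResult(
        ari=ari,
        n_topics_found=partition.n_topics,
        edge_threshold=threshold,
        substances_ranked_first=ranked_first,
        n_substances=len(truth.substance_affinity),
    )


def export_corpus(posts, truth: CorpusGroundTruth, directory: str | Path) -> None:
    """Write the generated corpus (JSONL) and its ground truth (TSV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_tokenized(posts, directory / "corpus_tokenized.jsonl")
    truth.export(directory)
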