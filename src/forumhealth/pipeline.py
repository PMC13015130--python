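"""Staged orchestration of the topic-discovery and quality-scoring pipeline.

Each stage reads its input artifacts from the output directory (falling back
to paths named in the config), writes its outputs there, and records a
manifest entry (inputs, parameters, seed, SHA-256 content digests) so any run
can be replayed and verified. Stages are linear:

    simulate -> preprocess -> build-lexicon -> train-embeddings -> expand
             -> filter-docs -> topics -> profiles          (topic branch)
    score-ratings                                          (quality branch)

``simulate`` is optional: with real data, ``paths.corpus`` / ``paths.lexicon``
/ ``paths.ratings`` point at existing files instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import association, corpus_io, hiq_eval, lexicon_builder, preprocess, semantic_model, synthetic_data, topic_discovery
from .errors import ConfigError, StageDependencyError

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "preprocess",
    "build-lexicon",
    "train-embeddings",
    "expand",
    "filter-docs",
    "topics",
    "profiles",
    "score-ratings",
    "all",
)

# stage -> (artifact filename, producing stage) for each required input
_DEPENDENCIES: dict[str, list[tuple[str, str]]] = {
    "preprocess": [("corpus.jsonl", "simulate")],
    "build-lexicon": [("tokenized.jsonl", "preprocess")],
    "train-embeddings": [("tokenized.jsonl", "preprocess")],
    "expand": [
        ("keywords_seed.tsv", "build-lexicon"),
        ("embeddings.txt", "train-embeddings"),
    ],
    "filter-docs": [("tokenized.jsonl", "preprocess"), ("keywords.tsv", "expand")],
    "topics": [
        ("embeddings.txt", "train-embeddings"),
        ("keywords.tsv", "expand"),
        ("documents.jsonl", "filter-docs"),
    ],
    "profiles": [("embeddings.txt", "train-embeddings"), ("topics.tsv", "topics")],
    "score-ratings": [("ratings.csv", "simulate")],
}


@dataclass
class PipelineConfig:
    """One structured config for the whole pipeline.

    Thresholds default to the pipeline's reference constants (seed words
    must occur more than 5000 times; expansion and graph edges keep cosines
    above 0.7; documents need more than five tokens); all are
    corpus-scale-dependent and meant to be overridden per corpus.
    """

    paths: dict[str, str] = field(default_factory=dict)
    preprocessing: dict[str, Any] = field(default_factory=dict)
    embedding: dict[str, Any] = field(default_factory=dict)
    thresholds: dict[str, Any] = field(default_factory=dict)
    louvain: dict[str, Any] = field(default_factory=dict)
    association: dict[str, Any] = field(default_factory=dict)
    simulate: dict[str, Any] | None = None
    questionnaire: str | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def threshold(self, name: str, default):
        return self.thresholds.get(name, default)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_manifest(out: Path) -> dict:
    path = out / "manifest.json"
    if path.exists():
        return json.loads(path.read_text(encoding="utf-8"))
    return {}


def _record(out: Path, stage: str, inputs: list[Path], outputs: list[Path], params: dict) -> None:
    manifest = _load_manifest(out)
    manifest[stage] = {
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "outputs": {p.name: _sha256(p) for p in outputs},
        "params": params,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def _resolve(out: Path, cfg: PipelineConfig, artifact: str, path_key: str | None = None) -> Path:
    """An input artifact: the out-dir copy if present, else the configured path."""
    candidate = out / artifact
    if candidate.exists():
        return candidate
    if path_key and path_key in cfg.paths:
        return Path(cfg.paths[path_key])
    return candidate


def _require(stage: str, out: Path, cfg: PipelineConfig) -> None:
    for artifact, producer in _DEPENDENCIES.get(stage, []):
        path_key = {
            "corpus.jsonl": "corpus",
            "ratings.csv": "ratings",
        }.get(artifact)
        if not _resolve(out, cfg, artifact, path_key).exists():
            raise StageDependencyError(stage, producer, artifact)


def _lexicon(out: Path, cfg: PipelineConfig) -> corpus_io.Lexicon:
    path = _resolve(out, cfg, "lexicon.tsv", "lexicon")
    if not path.exists():
        raise StageDependencyError("(any)", "simulate", "lexicon.tsv")
    return corpus_io.read_lexicon(path)


def _questionnaire(cfg: PipelineConfig) -> hiq_eval.Questionnaire:
    if cfg.questionnaire:
        return hiq_eval.Questionnaire.from_config(cfg.questionnaire)
    return hiq_eval.default_questionnaire()


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(out: Path, cfg: PipelineConfig) -> None:
    if not cfg.simulate:
        raise ConfigError("config has no 'simulate' section")
    corpus_cfg = synthetic_data.CorpusGenConfig(
        **{**cfg.simulate.get("corpus", {}), "seed": cfg.seed}
    )
    posts, truth = synthetic_data.generate_corpus(corpus_cfg)
    raw = corpus_io.Corpus(
        [corpus_io.Post(p.post_id, " ".join(p.tokens)) for p in posts],
        source_label="synthetic",
    )
    corpus_io.write_posts(raw, out / "corpus.jsonl")
    corpus_io.write_lexicon(synthetic_data.generate_lexicon(corpus_cfg), out / "lexicon.tsv")
    truth.export(out)

    ratings_cfg = cfg.simulate.get("ratings", {})
    n_rated = int(ratings_cfg.get("n_posts_rated", 25))
    quality_range = ratings_cfg.get("quality_range", [2.0, 4.0])
    rng = np.random.default_rng(cfg.seed)
    rated = [p.post_id for p in posts[:n_rated]]
    latent = {
        pid: float(rng.uniform(quality_range[0], quality_range[1])) for pid in rated
    }
    rg = synthetic_data.RatingGenConfig(
        n_experts=int(ratings_cfg.get("n_experts", 4)),
        latent_quality=latent,
        noise_sd=float(ratings_cfg.get("noise_sd", 0.7)),
        seed=cfg.seed,
    )
    ratings = synthetic_data.generate_ratings(rg, _questionnaire(cfg))
    corpus_io.write_ratings(ratings.records, out / "ratings.csv")
    with (out / "latent_quality.csv").open("w", encoding="utf-8") as fh:
        fh.write("post_id,latent_quality\n")
        for pid in rated:
            fh.write(f"{pid},{latent[pid]:.6f}\n")
    _record(
        out,
        "simulate",
        [],
        [out / "corpus.jsonl", out / "lexicon.tsv", out / "ratings.csv", out / "latent_quality.csv"],
        {"corpus": cfg.simulate.get("corpus", {}), "ratings": ratings_cfg, "seed": cfg.seed},
    )
    logger.info("simulate: %d posts, %d rated", len(posts), len(rated))


def _stage_preprocess(out: Path, cfg: PipelineConfig) -> None:
    _require("preprocess", out, cfg)
    corpus = corpus_io.read_posts(_resolve(out, cfg, "corpus.jsonl", "corpus"))
    lexicon = _lexicon(out, cfg)
    rules = preprocess.CleaningRules(
        artifact_patterns=list(cfg.preprocessing.get("patterns", [])),
        stopwords=set(cfg.preprocessing.get("stopwords", [])),
    )
    tokenized = preprocess.preprocess_corpus(corpus, lexicon, rules)
    corpus_io.write_tokenized(tokenized, out / "tokenized.jsonl")
    _record(
        out,
        "preprocess",
        [_resolve(out, cfg, "corpus.jsonl", "corpus")],
        [out / "tokenized.jsonl"],
        cfg.preprocessing,
    )
    logger.info("preprocess: %d posts in, %d out", len(corpus), len(tokenized))


def _stage_build_lexicon(out: Path, cfg: PipelineConfig) -> None:
    _require("build-lexicon", out, cfg)
    tokenized = corpus_io.read_tokenized(out / "tokenized.jsonl")
    lexicon = _lexicon(out, cfg)
    min_occ = int(cfg.threshold("min_occurrences", lexicon_builder.DEFAULT_MIN_OCCURRENCES))
    freq = lexicon_builder.count_frequencies(tokenized)
    candidates = lexicon_builder.frequency_filter(freq, min_occ)
    seeds = lexicon_builder.seed_select(candidates, lexicon)
    lexicon_builder.write_keywords(seeds, out / "keywords_seed.tsv")
    _record(
        out,
        "build-lexicon",
        [out / "tokenized.jsonl"],
        [out / "keywords_seed.tsv"],
        {"min_occurrences": min_occ},
    )
    logger.info(
        "build-lexicon: %d candidates above %d occurrences, %d seeds",
        len(candidates), min_occ, len(seeds),
    )


def _stage_train_embeddings(out: Path, cfg: PipelineConfig) -> None:
    _require("train-embeddings", out, cfg)
    tokenized = corpus_io.read_tokenized(out / "tokenized.jsonl")
    params = semantic_model.EmbeddingParams(
        **{"seed": cfg.seed, **cfg.embedding}
    )
    model = semantic_model.train_skipgram(tokenized, params)
    semantic_model.save_word2vec(model, out / "embeddings.txt")
    _record(
        out,
        "train-embeddings",
        [out / "tokenized.jsonl"],
        [out / "embeddings.txt"],
        {**cfg.embedding, "seed": params.seed},
    )
    logger.info("train-embeddings: vocabulary %d", len(model))


def _stage_expand(out: Path, cfg: PipelineConfig) -> None:
    _require("expand", out, cfg)
    seeds = lexicon_builder.read_keywords(out / "keywords_seed.tsv")
    model = semantic_model.load_word2vec(out / "embeddings.txt")
    lexicon = _lexicon(out, cfg)
    threshold = float(cfg.threshold("expansion", lexicon_builder.DEFAULT_EXPANSION_THRESHOLD))
    keywords = lexicon_builder.expand(seeds, model, threshold, lexicon)
    lexicon_builder.write_keywords(keywords, out / "keywords.tsv")
    _record(
        out,
        "expand",
        [out / "keywords_seed.tsv", out / "embeddings.txt"],
        [out / "keywords.tsv"],
        {"threshold": threshold},
    )
    logger.info("expand: %d seeds -> %d keywords", len(seeds), len(keywords))


def _stage_filter_docs(out: Path, cfg: PipelineConfig) -> None:
    _require("filter-docs", out, cfg)
    tokenized = corpus_io.read_tokenized(out / "tokenized.jsonl")
    keywords = lexicon_builder.read_keywords(out / "keywords.tsv")
    lexicon = _lexicon(out, cfg)
    fc = topic_discovery.FilterConfig(min_tokens=int(cfg.threshold("min_tokens", 6)))
    medical = set(keywords) - keywords.terms_in({"substance"})
    docs = topic_discovery.select_documents(
        tokenized, lexicon.substances() | keywords.terms_in({"substance"}), medical, fc
    )
    corpus_io.write_tokenized(
        [corpus_io.TokenizedPost(d.post_id, d.tokens) for d in docs],
        out / "documents.jsonl",
    )
    _record(
        out,
        "filter-docs",
        [out / "tokenized.jsonl", out / "keywords.tsv"],
        [out / "documents.jsonl"],
        {"min_tokens": fc.min_tokens},
    )
    logger.info("filter-docs: %d posts in, %d documents kept", len(tokenized), len(docs))


def _stage_topics(out: Path, cfg: PipelineConfig) -> None:
    _require("topics", out, cfg)
    model = semantic_model.load_word2vec(out / "embeddings.txt")
    keywords = lexicon_builder.read_keywords(out / "keywords.tsv")
    docs_tok = corpus_io.read_tokenized(out / "documents.jsonl")
    medical = sorted((set(keywords) - keywords.terms_in({"substance"})) & set(model.vocabulary))

    percentile = cfg.threshold("edge_percentile", None)
    if percentile is not None:
        unit = model.unit_vectors[[model._idx(k) for k in medical]]
        sims = unit @ unit.T
        edge_threshold = float(
            np.percentile(sims[np.triu_indices(len(medical), 1)], float(percentile))
        )
    else:
        edge_threshold = float(
            cfg.threshold("edge", topic_discovery.DEFAULT_EDGE_THRESHOLD)
        )
    graph = topic_discovery.build_graph(model, medical, edge_threshold)
    lv = cfg.louvain
    partition = topic_discovery.louvain(
        graph,
        resolution=float(lv.get("resolution", 1.0)),
        seed=int(lv.get("seed", cfg.seed)),
    )
    docs = topic_discovery.select_documents(
        docs_tok, set(), set(), topic_discovery.FilterConfig(1, False, False)
    )
    prevalence = topic_discovery.topic_prevalence(docs, partition)
    topic_discovery.write_edgelist(graph, out / "graph_edgelist.tsv")
    topic_discovery.write_graphml(graph, out / "graph.graphml")
    topic_discovery.write_partition(partition, out / "topics.tsv")
    topic_discovery.write_prevalence(prevalence, partition, out / "prevalence.csv")
    _record(
        out,
        "topics",
        [out / "embeddings.txt", out / "keywords.tsv", out / "documents.jsonl"],
        [out / "graph_edgelist.tsv", out / "topics.tsv", out / "prevalence.csv"],
        {
            "edge_threshold": edge_threshold,
            "resolution": float(lv.get("resolution", 1.0)),
            "seed": int(lv.get("seed", cfg.seed)),
            "modularity": partition.modularity,
        },
    )
    logger.info(
        "topics: %d nodes, %d edges, %d topics, Q=%.4f",
        len(graph), graph.graph.number_of_edges(), partition.n_topics, partition.modularity,
    )


def _stage_profiles(out: Path, cfg: PipelineConfig) -> None:
    _require("profiles", out, cfg)
    model = semantic_model.load_word2vec(out / "embeddings.txt")
    lexicon = _lexicon(out, cfg)
    assignment: dict[str, int] = {}
    with (out / "topics.tsv").open(encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            term, topic = line.rstrip("\n").split("\t")
            assignment[term] = int(topic)
    partition = topic_discovery.TopicPartition(
        assignment=assignment, modularity=0.0, resolution=1.0, seed=cfg.seed
    )
    prof = association.profile(
        model,
        lexicon.substances(),
        partition,
        aggregation=str(cfg.association.get("aggregation", "mean")),
    )
    association.export_radar(prof, out / "profiles.csv")
    _record(
        out,
        "profiles",
        [out / "embeddings.txt", out / "topics.tsv"],
        [out / "profiles.csv"],
        {"aggregation": prof.aggregation},
    )
    logger.info("profiles: %d substances x %d topics", len(prof.substances), len(prof.topic_ids))


def _stage_score_ratings(out: Path, cfg: PipelineConfig) -> None:
    _require("score-ratings", out, cfg)
    records = corpus_io.read_ratings(_resolve(out, cfg, "ratings.csv", "ratings"))
    questionnaire = _questionnaire(cfg)
    ratings = hiq_eval.RatingSet(records)
    summary = hiq_eval.summarize(ratings, questionnaire)
    summary.question_table(questionnaire).to_csv(out / "summary_questions.csv", index=False)
    summary.expert_table().to_csv(out / "summary_experts.csv", index=False)
    _record(
        out,
        "score-ratings",
        [_resolve(out, cfg, "ratings.csv", "ratings")],
        [out / "summary_questions.csv", out / "summary_experts.csv"],
        {
            "overall_post_mean": summary.overall_post_mean,
            "overall_question_mean": summary.overall_question_mean,
        },
    )
    logger.info(
        "score-ratings: %d records, post mean %.2f",
        len(ratings), summary.overall_post_mean,
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "build-lexicon": _stage_build_lexicon,
    "train-embeddings": _stage_train_embeddings,
    "expand": _stage_expand,
    "filter-docs": _stage_filter_docs,
    "topics": _stage_topics,
    "profiles": _stage_profiles,
    "score-ratings": _stage_score_ratings,
}


def run_stage(stage: str, config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run one pipeline stage (or ``all``); returns the output directory.

    Raises :class:`StageDependencyError` when a prerequisite stage's
    artifacts are missing.
    """
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if stage == "all":
        order = [s for s in STAGES if s not in ("all",)]
        if not config.simulate:
            order.remove("simulate")
        if "score-ratings" in order and not (
            _resolve(out, config, "ratings.csv", "ratings").exists() or config.simulate
        ):
            order.remove("score-ratings")
        for s in order:
            _STAGE_FUNCS[s](out, config)
    else:
        _STAGE_FUNCS[stage](out, config)
    return out
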