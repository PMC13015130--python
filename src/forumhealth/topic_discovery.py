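"""Document filtering, the keyword-similarity graph, Louvain topics, and
topic prevalence.

Documents enter the health corpus when they are long enough (strictly more
than five normalized tokens by default) and mention both a psychoactive
substance and at least one health keyword. Keywords become nodes of an
undirected graph whose edges carry cosine similarity; Louvain community
detection over that graph yields the topics. Prevalence counts how many
documents contain at least one keyword of each topic — multi-membership, so
a document mentioning two topics counts toward both.

Community detection is delegated to networkx's Louvain implementation with a
fixed seed; modularity is recomputed here from the weighted formula
``Q = sum_c [ w_in(c)/(2m) - gamma * (w_tot(c)/(2m))^2 ]`` and stored with
the partition, so every partition can be verified against its objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .corpus_io import TokenizedPost
from .errors import GraphError
from .semantic_model import EmbeddingModel

__all__ = [
    "FilterConfig",
    "HealthDocument",
    "KeywordGraph",
    "TopicPartition",
    "TopicPrevalence",
    "select_documents",
    "build_graph",
    "modularity",
    "louvain",
    "topic_prevalence",
    "write_edgelist",
    "write_graphml",
    "write_partition",
    "write_prevalence",
]

logger = logging.getLogger(__name__)

DEFAULT_EDGE_THRESHOLD = 0.7


@dataclass(frozen=True)
class FilterConfig:
    """Document filter: ``min_tokens`` = 6 enforces "more than five words"
    on the normalized token stream."""

    min_tokens: int = 6
    require_substance: bool = True
    require_medical_keyword: bool = True

    def __post_init__(self) -> None:
        if self.min_tokens < 1:
            raise ValueError("min_tokens must be >= 1")


@dataclass(frozen=True)
class HealthDocument:
    post_id: str
    tokens: tuple[str, ...]
    substances_present: frozenset[str]
    medical_keywords_present: frozenset[str]


def select_documents(
    corpus: Iterable[TokenizedPost],
    substances: Iterable[str],
    keywords: Iterable[str],
    cfg: FilterConfig = FilterConfig(),
) -> list[HealthDocument]:
    """Posts satisfying every enabled predicate, with the matched substance
    and keyword sets recorded per document."""
    substance_set = set(substances)
    keyword_set = set(keywords)
    out: list[HealthDocument] = []
    for post in corpus:
        if len(post.tokens) < cfg.min_tokens:
            continue
        toks = set(post.tokens)
        subs = toks & substance_set
        meds = toks & keyword_set
        if cfg.require_substance and not subs:
            continue
        if cfg.require_medical_keyword and not meds:
            continue
        out.append(
            HealthDocument(
                post_id=post.post_id,
                tokens=post.tokens,
                substances_present=frozenset(subs),
                medical_keywords_present=frozenset(meds),
            )
        )
    return out


@dataclass
class KeywordGraph:
    """Undirected keyword-similarity graph; edge weights are cosines strictly
    above ``edge_threshold``."""

    graph: nx.Graph
    edge_threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def build_graph(
    model: EmbeddingModel,
    keywords: Iterable[str],
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> KeywordGraph:
    """Edge {u, v} present iff cosine(u, v) > edge_threshold (strict).

    Out-of-vocabulary keywords are dropped with a warning; fewer than two
    surviving nodes is an error.
    """
    kept = sorted({k for k in keywords if k in model})
    dropped = sorted(set(keywords) - set(kept))
    if dropped:
        logger.warning("dropping %d out-of-vocabulary keywords: %s ...", len(dropped), dropped[:5])
    if len(kept) < 2:
        raise GraphError(
            f"need at least 2 in-vocabulary keywords, got {len(kept)}"
        )
    g = nx.Graph()
    g.add_nodes_from(kept)
    unit = model.unit_vectors
    idx = [model._idx(k) for k in kept]
    sub = unit[idx]
    sims = sub @ sub.T
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            w = float(min(1.0, max(-1.0, sims[a, b])))
            if w > edge_threshold:
                g.add_edge(kept[a], kept[b], weight=w)
    return KeywordGraph(graph=g, edge_threshold=edge_threshold)


def _as_nx(graph: KeywordGraph | nx.Graph) -> nx.Graph:
    return graph.graph if isinstance(graph, KeywordGraph) else graph


def modularity(
    graph: KeywordGraph | nx.Graph,
    assignment: Mapping[str, int],
    resolution: float = 1.0,
) -> float:
    """Weighted modularity of a node->community assignment.

    ``Q = sum_c [ w_in(c)/(2m) - resolution * (w_tot(c)/(2m))^2 ]`` where
    ``w_in(c)`` is twice the total weight inside community c and ``w_tot(c)``
    the summed weighted degree of its nodes.
    """
    g = _as_nx(graph)
    for node in g.nodes:
        if node not in assignment:
            raise GraphError(f"node {node!r} missing from assignment")
    two_m = sum(d for _, d in g.degree(weight="weight"))
    if two_m == 0:
        return 0.0
    w_in: dict[int, float] = {}
    w_tot: dict[int, float] = {}
    for node, deg in g.degree(weight="weight"):
        c = assignment[node]
        w_tot[c] = w_tot.get(c, 0.0) + deg
    for u, v, w in g.edges(data="weight", default=1.0):
        if assignment[u] == assignment[v]:
            w_in[assignment[u]] = w_in.get(assignment[u], 0.0) + 2.0 * w
    q = 0.0
    for c in w_tot:
        q += w_in.get(c, 0.0) / two_m - resolution * (w_tot[c] / two_m) ** 2
    return q


@dataclass
class TopicPartition:
    """Louvain communities over the keyword graph — the discovered topics.

    Topic ids are canonicalized to 0..C-1 in order of each community's
    lexicographically smallest member, so equal partitions always get equal
    labels.
    """

    assignment: dict[str, int]
    modularity: float
    resolution: float
    seed: int
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def topics(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for term, topic in self.assignment.items():
            out.setdefault(topic, set()).add(term)
        return out

    @property
    def n_topics(self) -> int:
        return len(set(self.assignment.values()))

    def label(self, topic_id: int) -> str:
        return self.labels.get(topic_id, f"topic_{topic_id}")


def louvain(
    graph: KeywordGraph | nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
) -> TopicPartition:
    """Louvain community detection; deterministic for a fixed seed."""
    g = _as_nx(graph)
    if g.number_of_nodes() < 2:
        raise GraphError("graph needs at least 2 nodes for community detection")
    communities = nx.algorithms.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    ordered = sorted(communities, key=lambda c: min(c))
    assignment = {node: i for i, comm in enumerate(ordered) for node in comm}
    q = modularity(g, assignment, resolution=1.0)
    return TopicPartition(
        assignment=assignment,
        modularity=q,
        resolution=resolution,
        seed=seed,
        labels={
            i: ", ".join(str(t) for t in sorted(comm)[:3])
            for i, comm in enumerate(ordered)
        },
    )


@dataclass
class TopicPrevalence:
    """Documents per topic (multi-membership) and their share of all
    documents."""

    counts: dict[int, int]
    shares: dict[int, float]
    n_documents: int


def topic_prevalence(
    docs: Iterable[HealthDocument], partition: TopicPartition
) -> TopicPrevalence:
    """counts[t] = number of documents containing >= 1 keyword of topic t."""
    docs = list(docs)
    topics = partition.topics
    counts = {t: 0 for t in topics}
    for doc in docs:
        toks = set(doc.tokens)
        for t, words in topics.items():
            if toks & words:
                counts[t] += 1
    n = len(docs)
    shares = {t: (c / n if n else 0.0) for t, c in counts.items()}
    return TopicPrevalence(counts=counts, shares=shares, n_documents=n)


# ---------------------------------------------------------------------------
# exports


def write_edgelist(graph: KeywordGraph, path: str | Path) -> None:
    g = graph.graph
    with Path(path).open("w", encoding="utf-8") as fh:
        for u, v, w in sorted(g.edges(data="weight", default=1.0)):
            fh.write(f"{u}\t{v}\t{w:.6f}\n")


def write_graphml(graph: KeywordGraph, path: str | Path) -> None:
    nx.write_graphml(graph.graph, str(path))


def write_partition(partition: TopicPartition, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("term\ttopic_id\n")
        for term in sorted(partition.assignment):
            fh.write(f"{term}\t{partition.assignment[term]}\n")


def write_prevalence(prevalence: TopicPrevalence, partition: TopicPartition, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write("topic_id,label,count,share\n")
        for t in sorted(prevalence.counts):
            label = partition.label(t).replace(",", ";")
            fh.write(f"{t},{label},{prevalence.counts[t]},{prevalence.shares[t]:.6f}\n")
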