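import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import random_model
from forumhealth.corpus_io import TokenizedPost
from forumhealth.errors import GraphError
from forumhealth.semantic_model import cosine
from forumhealth.topic_discovery import (
    FilterConfig,
    KeywordGraph,
    TopicPartition,
    build_graph,
    louvain,
    modularity,
    select_documents,
    topic_prevalence,
    write_edgelist,
    write_partition,
    write_prevalence,
)


def two_triangles() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")], weight=1.0)
    g.add_edges_from([("x", "y"), ("y", "z"), ("x", "z")], weight=1.0)
    return g


def set_partitions(items):
    """All partitions of a list (oracle for exhaustive modularity search)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [block + [first]] + partition[i + 1 :]
        yield partition + [[first]]


class TestSelectDocuments:
    KW = {"paracetamol"}
    SUBS = {"marijuana"}

    def make(self, n_tokens, with_sub=True, with_kw=True):
        tokens = ["filler"] * n_tokens
        if with_sub:
            tokens[0] = "marijuana"
        if with_kw:
            tokens[1] = "paracetamol"
        return TokenizedPost("p", tuple(tokens[:n_tokens]))

    def test_five_tokens_rejected_needs_more_than_five(self):
        docs = select_documents([self.make(5)], self.SUBS, self.KW, FilterConfig())
        assert docs == []

    def test_six_tokens_without_medical_keyword_rejected(self):
        docs = select_documents(
            [self.make(6, with_kw=False)], self.SUBS, self.KW, FilterConfig()
        )
        assert docs == []

    def test_six_tokens_with_both_accepted_with_sets(self):
        docs = select_documents([self.make(6)], self.SUBS, self.KW, FilterConfig())
        assert len(docs) == 1
        assert docs[0].substances_present == {"marijuana"}
        assert docs[0].medical_keywords_present == {"paracetamol"}

    def test_monotone_in_keyword_set(self):
        posts = [
            TokenizedPost(f"p{i}", tuple(f"w{j}" for j in range(i, i + 8)))
            for i in range(20)
        ]
        big = {f"w{j}" for j in range(30)}
        small = {f"w{j}" for j in range(0, 30, 3)}
        cfg = FilterConfig(require_substance=False)
        selected_big = {d.post_id for d in select_documents(posts, set(), big, cfg)}
        selected_small = {d.post_id for d in select_documents(posts, set(), small, cfg)}
        assert selected_small <= selected_big


class TestBuildGraph:
    def test_matches_brute_force_pairwise_filter(self):
        model = random_model(50, dim=5, seed=13)
        for thr in (0.0, 0.4, 0.8):
            kg = build_graph(model, model.vocabulary, thr)
            expected = {
                frozenset((a, b))
                for a, b in itertools.combinations(model.vocabulary, 2)
                if cosine(model, a, b) > thr
            }
            got = {frozenset(e) for e in kg.graph.edges}
            assert got == expected
            for u, v, w in kg.graph.edges(data="weight"):
                assert w == pytest.approx(cosine(model, u, v), abs=1e-9)

    def test_threshold_minus_one_complete_graph(self):
        model = random_model(10, dim=3, seed=1)
        kg = build_graph(model, model.vocabulary, -1.0)
        assert kg.graph.number_of_edges() == 10 * 9 // 2

    def test_all_keywords_out_of_vocabulary_error(self):
        model = random_model(5)
        with pytest.raises(GraphError):
            build_graph(model, ["nope1", "nope2"], 0.5)

    def test_oov_keywords_dropped_with_warning(self, caplog):
        import logging

        model = random_model(5)
        with caplog.at_level(logging.WARNING):
            kg = build_graph(model, list(model.vocabulary) + ["ghost"], -1.0)
        assert "ghost" not in kg.nodes
        assert "out-of-vocabulary" in caplog.text


class TestModularity:
    def test_two_triangles_closed_form(self):
        # 2 x (3/6 - (6/12)^2) = 0.5
        part = {"a": 0, "b": 0, "c": 0, "x": 1, "y": 1, "z": 1}
        assert modularity(two_triangles(), part) == pytest.approx(0.5, abs=1e-12)

    def test_single_community_is_zero(self):
        g = two_triangles()
        part = {n: 0 for n in g.nodes}
        assert modularity(g, part) == pytest.approx(0.0, abs=1e-12)

    def test_splitting_one_node_off_is_suboptimal(self):
        part = {"a": 0, "b": 1, "c": 1, "x": 2, "y": 2, "z": 2}
        assert modularity(two_triangles(), part) < 0.5

    def test_missing_node_error_names_it(self):
        with pytest.raises(GraphError, match="z"):
            modularity(two_triangles(), {n: 0 for n in "abcxy"})

    def test_agrees_with_networkx_on_weighted_graph(self):
        rng = np.random.default_rng(5)
        g = nx.gnm_random_graph(12, 30, seed=4)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
        part = {n: n % 3 for n in g.nodes}
        communities = [{n for n in g.nodes if n % 3 == c} for c in range(3)]
        expected = nx.algorithms.community.modularity(g, communities, weight="weight")
        assert modularity(g, part) == pytest.approx(expected, abs=1e-12)


class TestLouvain:
    def test_two_triangles_recovered_exactly(self):
        part = louvain(two_triangles(), seed=0)
        assert part.n_topics == 2
        topics = {frozenset(c) for c in part.topics.values()}
        assert topics == {frozenset("abc"), frozenset("xyz")}
        assert part.modularity == pytest.approx(0.5, abs=1e-12)

    def test_uniform_complete_graph_single_community(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = louvain(g, seed=0)
        assert part.n_topics == 1

    def test_deterministic_for_fixed_seed(self):
        model = random_model(30, dim=4, seed=21)
        kg = build_graph(model, model.vocabulary, 0.2)
        p1 = louvain(kg, seed=3)
        p2 = louvain(kg, seed=3)
        assert p1.assignment == p2.assignment

    def test_stored_modularity_matches_recomputation(self):
        model = random_model(30, dim=4, seed=21)
        kg = build_graph(model, model.vocabulary, 0.2)
        part = louvain(kg, seed=3)
        assert part.modularity == pytest.approx(
            modularity(kg, part.assignment), abs=1e-9
        )

    def test_near_optimal_on_small_graphs(self):
        # exhaustive search over all partitions of <= 8 nodes
        for seed in (0, 1, 2):
            g = nx.gnp_random_graph(7, 0.5, seed=seed)
            if g.number_of_edges() < 2:
                continue
            nx.set_edge_attributes(g, 1.0, "weight")
            best = max(
                modularity(g, {n: i for i, block in enumerate(p) for n in block})
                for p in set_partitions(list(g.nodes))
            )
            part = louvain(g, seed=0)
            assert part.modularity >= 0.95 * best

    def test_empty_graph_error(self):
        with pytest.raises(GraphError):
            louvain(nx.Graph(), seed=0)


class TestPrevalence:
    PART = TopicPartition(
        assignment={"k1": 0, "k2": 1}, modularity=0.0, resolution=1.0, seed=0
    )

    def doc(self, pid, tokens):
        from forumhealth.topic_discovery import HealthDocument

        return HealthDocument(pid, tuple(tokens), frozenset(), frozenset())

    def test_multi_membership_counting(self):
        docs = [self.doc("d1", ["k1", "x"]), self.doc("d2", ["k1", "k2"])]
        prev = topic_prevalence(docs, self.PART)
        assert prev.counts == {0: 2, 1: 1}
        assert prev.shares == {0: 1.0, 1: 0.5}

    def test_no_documents(self):
        prev = topic_prevalence([], self.PART)
        assert prev.counts == {0: 0, 1: 0}
        assert prev.shares == {0: 0.0, 1: 0.0}

    def test_every_doc_hits_every_topic(self):
        docs = [self.doc(f"d{i}", ["k1", "k2"]) for i in range(3)]
        prev = topic_prevalence(docs, self.PART)
        assert prev.shares == {0: 1.0, 1: 1.0}


def test_exports_are_plain_text(tmp_path):
    g = KeywordGraph(two_triangles(), edge_threshold=0.0)
    part = louvain(g, seed=0)
    docs = []
    prev = topic_prevalence(docs, part)
    write_edgelist(g, tmp_path / "edges.tsv")
    write_partition(part, tmp_path / "topics.tsv")
    write_prevalence(prev, part, tmp_path / "prev.csv")
    assert (tmp_path / "edges.tsv").read_text().splitlines()[0].count("\t") == 2
    assert (tmp_path / "topics.tsv").read_text().startswith("term\ttopic_id")
    assert (tmp_path / "prev.csv").read_text().startswith("topic_id,label,count,share")
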