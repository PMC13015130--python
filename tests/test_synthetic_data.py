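import numpy as np
import pytest

from forumhealth.errors import ConfigError
from forumhealth.hiq_eval import default_questionnaire, post_total
from forumhealth.synthetic_data import (
    CorpusGenConfig,
    RatingGenConfig,
    exact_mean_design,
    generate_corpus,
    generate_lexicon,
    generate_ratings,
    recovery_ari,
)


class TestGenerateCorpus:
    def test_deterministic_per_seed(self):
        cfg = CorpusGenConfig(n_posts=50, seed=5)
        posts1, truth1 = generate_corpus(cfg)
        posts2, truth2 = generate_corpus(cfg)
        assert posts1 == posts2
        assert truth1.post_topic == truth2.post_topic

    def test_full_purity_forces_topic_words(self):
        cfg = CorpusGenConfig(
            n_topics=3, words_per_topic=20, n_substances=0, n_posts=500,
            topic_purity=1.0, seed=1,
        )
        posts, truth = generate_corpus(cfg)
        for post in posts:
            topic = truth.post_topic[post.post_id]
            assert all(truth.word_topic[t] == topic for t in post.tokens)

    def test_purity_fraction_approximates_pi(self):
        cfg = CorpusGenConfig(n_substances=0, topic_purity=0.85, n_posts=1000, seed=2)
        posts, truth = generate_corpus(cfg)
        n_topic_tokens = sum(
            sum(t in truth.word_topic for t in p.tokens) for p in posts
        )
        n_tokens = sum(len(p) for p in posts)
        assert n_topic_tokens / n_tokens == pytest.approx(0.85, abs=0.02)

    def test_no_posts_empty_corpus(self):
        posts, truth = generate_corpus(CorpusGenConfig(n_posts=0))
        assert posts == [] and truth.post_topic == {}

    def test_substances_only_in_affiliated_topics(self):
        cfg = CorpusGenConfig(n_posts=300, substance_insert_prob=1.0, seed=3)
        posts, truth = generate_corpus(cfg)
        for post in posts:
            topic = truth.post_topic[post.post_id]
            for sub, aff in truth.substance_affinity.items():
                present = sub in post.tokens
                assert present == (aff == topic)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_topics": 1},
            {"topic_purity": 0.2, "n_topics": 5},
            {"post_length": (5, 3)},
            {"substance_insert_prob": 1.5},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            CorpusGenConfig(**kwargs)

    def test_lexicon_covers_planted_words_and_substances(self):
        cfg = CorpusGenConfig()
        lex = generate_lexicon(cfg)
        _, truth = generate_corpus(cfg)
        assert set(truth.word_topic) <= set(lex.entries)
        assert lex.substances() == set(truth.substance_affinity)


class TestGenerateRatings:
    Q = default_questionnaire()

    def test_noiseless_latent_three_gives_totals_39(self):
        cfg = RatingGenConfig(
            n_experts=2, latent_quality={"p1": 3.0, "p2": 3.0}, noise_sd=0.0, seed=0
        )
        ratings = generate_ratings(cfg, self.Q)
        assert all(r.rating == 3 for r in ratings.records)
        assert post_total(ratings, "p1", "expert1", self.Q) == 39

    def test_clipping_floor_and_ceiling(self):
        low = generate_ratings(
            RatingGenConfig(n_experts=1, latent_quality={"p": 1.0}, noise_sd=0.0), self.Q
        )
        high = generate_ratings(
            RatingGenConfig(n_experts=1, latent_quality={"p": 5.0}, noise_sd=0.0), self.Q
        )
        assert post_total(low, "p", "expert1", self.Q) == 13
        assert post_total(high, "p", "expert1", self.Q) == 65

    def test_complete_design_and_determinism(self):
        cfg = RatingGenConfig(
            n_experts=4, latent_quality={f"p{i}": 2.5 for i in range(25)}, seed=9
        )
        r1 = generate_ratings(cfg, self.Q)
        r2 = generate_ratings(cfg, self.Q)
        assert r1.is_complete(self.Q) and len(r1) == 4 * 25 * 13
        assert r1.records == r2.records

    def test_expert_bias_shifts_ratings(self):
        cfg = RatingGenConfig(
            n_experts=2,
            latent_quality={"p": 3.0},
            expert_bias={"expert2": 1.0},
            noise_sd=0.0,
        )
        ratings = generate_ratings(cfg, self.Q)
        assert post_total(ratings, "p", "expert1", self.Q) == 39
        assert post_total(ratings, "p", "expert2", self.Q) == 52

    def test_mean_total_tracks_latent_quality(self):
        # noise_sd 0.7, latent in [2, 4]: mean generated total within 2 points
        # of 13 x mean latent, averaged over seeds (clipping negligible)
        latent = {f"p{i:02d}": 2.0 + 2.0 * i / 24 for i in range(25)}
        target = 13 * np.mean(list(latent.values()))
        totals = []
        for seed in range(10):
            cfg = RatingGenConfig(
                n_experts=4, latent_quality=latent, noise_sd=0.7, seed=seed
            )
            ratings = generate_ratings(cfg, self.Q)
            totals.extend(
                post_total(ratings, p, e, self.Q)
                for p in ratings.posts
                for e in ratings.experts
            )
        assert abs(np.mean(totals) - target) < 2.0


class TestExactMeanDesign:
    def test_realizes_requested_means_exactly(self):
        q = default_questionnaire()
        means = {i: 2.0 + i / 13 for i in range(1, 14)}
        means = {i: round(m * 100) / 100 for i, m in means.items()}
        ratings = exact_mean_design(means, q)
        assert ratings.is_complete(q)
        frame = ratings.to_frame()
        for qid, target in means.items():
            got = frame.loc[frame.question_id == qid, "rating"].mean()
            assert got == pytest.approx(target, abs=1e-12)

    def test_unrealizable_mean_rejected(self):
        q = default_questionnaire()
        means = {i: 3.0 for i in range(1, 14)}
        means[1] = 3.0001
        with pytest.raises(ConfigError):
            exact_mean_design(means, q)


class TestRecoveryAri:
    def test_identical_partitions_give_one(self):
        labels = {f"w{i}": i % 3 for i in range(30)}
        assert recovery_ari(labels, labels) == pytest.approx(1.0)

    def test_one_cluster_vs_singletons_is_zero(self):
        # contingency formula: index = expected index, so ARI = 0
        pred = {c: 0 for c in "abcd"}
        truth = {c: i for i, c in enumerate("abcd")}
        assert recovery_ari(pred, truth) == pytest.approx(0.0, abs=1e-12)

    def test_null_distribution_centred_on_zero(self):
        rng = np.random.default_rng(0)
        truth = {f"w{i}": i % 3 for i in range(60)}
        aris = []
        for _ in range(200):
            labels = rng.integers(0, 3, size=60)
            pred = {f"w{i}": int(labels[i]) for i in range(60)}
            aris.append(recovery_ari(pred, truth))
        assert abs(np.mean(aris)) < 0.05

    def test_key_mismatch_rejected(self):
        with pytest.raises(KeyError):
            recovery_ari({"a": 0}, {"b": 0})
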