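"""Score how strongly each substance is semantically associated with each
topic (the radar-plot quantities).

The association is the mean cosine similarity between the substance's vector
and the topic's keyword vectors — shared context, not co-occurrence. On the
synthetic corpus each substance is planted to co-occur with one topic, so
that topic should come out on top.
"""

from forumhealth.association import export_radar, profile
from forumhealth.semantic_model import EmbeddingParams, train_skipgram
from forumhealth.synthetic_data import CorpusGenConfig, generate_corpus
from forumhealth.topic_discovery import TopicPartition

cfg = CorpusGenConfig(seed=42)
posts, truth = generate_corpus(cfg)
model = train_skipgram(posts, EmbeddingParams(window=10, dimension=50, epochs=15, seed=42))

partition = TopicPartition(
    assignment={w: t for w, t in truth.word_topic.items() if w in model},
    modularity=0.0, resolution=1.0, seed=42,
)
prof = profile(model, set(truth.substance_affinity), partition, aggregation="mean")

for substance in prof.substances:
    planted = truth.substance_affinity[substance]
    ranked = prof.ranked_topics(substance)
    scores = ", ".join(
        f"topic {t}: {prof.score(substance, t):+.3f}" for t in prof.topic_ids
    )
    marker = "ok" if ranked[0] == planted else "MISS"
    print(f"{substance} (planted topic {planted}, top-ranked {ranked[0]} -> {marker})")
    print(f"  {scores}")

export_radar(prof, "substance_topic_profiles.csv")
print("\nwrote substance_topic_profiles.csv (substance / topic_id / topic_label / score)")
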