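# Methods

## The pipeline model

`forumhealth` treats topic discovery on a drug forum as a chain of simple,
individually checkable operations rather than a single topic model. The
underlying assumption is distributional: words used in similar local
contexts acquire similar skip-gram vectors, so semantic fields ("blood
pressure" vocabulary, "psychotherapy" vocabulary) become dense regions in
embedding space. Thresholding pairwise cosine similarity turns those regions
into a graph, and modularity maximization turns the graph into discrete
topics. Substance–topic association is then read directly from embedding
geometry (mean cosine between a substance and a topic's keywords), which
deliberately measures shared context rather than document co-occurrence.

## Normalization

Artifact removal applies an ordered, configurable list of regular
expressions (leading publication dates, quote/report widgets, "user X said"
phrases, inactivity notices, mottos) and collapses the whitespace left
behind; it never inserts characters. Tokens are lowercase runs of word
characters that begin with a letter — this drops punctuation, bare numbers
and quantity fragments like "2g" while keeping alphanumeric slang names
like "ak47". Inside `normalize` the order is fixed: lemmatize →
canonicalize synonyms → remove stopwords. Synonym variants in curated drug
lexicons are surface or lemma forms, so canonicalization must see lemmas,
and removing stopwords last prevents a lemma from escaping removal.
Multiword variants are declared with underscores (`liquid_ecstasy`) and
matched greedily as n-grams before single-token mapping, because the
embedding stage operates on single tokens. Synonym chains are resolved to a
fixed point when a lexicon is constructed (cycles are an error), which makes
canonicalization — and therefore `normalize` with any idempotent
lemmatizer — idempotent.

The lemmatizer is an injected `token -> lemma` callable defaulting to the
identity. Morphologically rich source languages need a real lemmatizer
model; nothing downstream depends on which one, and the synthetic tests do
not depend on any.

## Embeddings

The trainer implements skip-gram with negative sampling: for each (center,
context) pair within a dynamically shrunk window (effective radius uniform
on 1..window per position, the conventional distance weighting),
`negative_samples` noise words are drawn from the unigram distribution
raised to 3/4. Defaults: window 10 (the context size the method is built
around), dimension 100, 5 epochs, 5 negatives, `min_count` 5, learning rate
0.025 decaying linearly to 1e-4. Input vectors are initialized uniformly in
±0.5/dimension, output vectors at zero; the trained input matrix is the
model. The inner loop is numba-compiled and single-threaded with a seeded
RNG, so training is bit-reproducible — a contract the tests rely on, since
multithreaded trainers are not. Vectors are L2-normalized lazily at query
time; the stored vectors stay raw and inspectable. Models persist in the
plain word2vec text format (`n d` header, one term + vector per line).

Cosine thresholds are read strictly (`> 0.7`, not `>=`), matching the
"above the threshold" reading used throughout.

## Lexicon construction

Seed selection is the intersection of the frequency-filtered vocabulary
(strictly more than `min_occurrences`, default 5000 — corpus-scale
dependent and always configurable) with a user-curated category lexicon.
This models a manual curation pass as a deterministic operation: the curated
lexicon *is* the human judgment, supplied as data. Expansion is a single
pass — candidates are neighbors of individual seeds (the per-seed reading of
"related to the list"), must exceed the threshold against at least one seed,
and must themselves be vouched for by the lexicon (the verification pass);
the recorded anchor is the most similar seed. No transitive closure:
expanded words do not recruit further words, which keeps the operation
monotone in the threshold.

## Topics and prevalence

Document filtering requires more than five tokens *after* normalization
(`min_tokens = 6`), at least one canonical substance and at least one
medical keyword; each predicate can be disabled. The keyword graph contains
an edge wherever cosine exceeds the edge threshold. By default that
threshold reuses the expansion value (0.7); for synthetic corpora, whose
cosine scale differs from a large natural corpus, the pipeline also accepts
a percentile specification (the recovery conditions use the 90th percentile
of pairwise keyword cosines). Louvain is delegated to networkx's
implementation with an explicit seed; community ids are canonicalized by
each community's lexicographically smallest member so identical partitions
always serialize identically. Modularity is computed in-package from the
weighted formula and stored with every partition; tests cross-check it
against networkx's implementation and closed forms, and verify Louvain
reaches ≥95% of the exhaustive-search optimum on small graphs (it is a
heuristic; optimality is not asserted). Prevalence is multi-membership — a
document counts toward every topic whose keywords it contains — because a
single-topic assignment rule would be an extra modeling commitment the
association analysis does not need.

## Substance–topic profiles

The score for (substance s, topic t) aggregates `cosine(s, k)` over the
topic's in-vocabulary keywords; the default aggregation is the mean (the
symmetric choice), with `max` available for sensitivity analysis. Topics
with no in-vocabulary keyword yield a missing value, never 0 — zero is a
meaningful cosine. Export is a long-format CSV; radar-chart rendering is a
thin optional layer with no exactness contract, since the scientific content
is the score matrix.

## The quality instrument

The 13 items, their three sections (reliability of knowledge and
evidence-based medicine, items 1–4; safety, items 5–9; authenticity and
personal experiences, items 10–12; a stand-alone summary item 13) and the
1–5 scale are fixed by the instrument; item texts ship as concise English
labels and can be replaced from a config file. Totals therefore range 13–65,
and item 13 is included in totals (13 × 5 = 65). Aggregation requires a
complete expert × post × question design and refuses anything less —
silently dropping or imputing cells would fabricate data. Under completeness
the aggregates obey exact linear identities (overall post mean = Σ question
means; section mean = equal-weight mean of its question means; overall
question mean = overall post mean / 13), which the tests assert both on
random designs and on the reference question-mean table. SDs are sample
(n−1) SDs pooled over all ratings entering a cell; the estimator choice
does not affect any mean. Display rounding is half-up to two decimals;
computation keeps full precision.

`exact_mean_design` builds a complete integer design whose per-question
means equal given targets exactly (possible whenever mean × cells is an
integer), so published question-level tables can be pushed through the full
aggregation path rather than a means-only shortcut.

## Synthetic data: what it emulates, what it does not

The corpus generator plants structure through co-occurrence: each post
draws a topic uniformly; each token slot is filled from the topic's word
list with probability π (`topic_purity`, default 0.85) or from a shared
background vocabulary; each substance is inserted (probability 0.8) into
posts of its affiliated topic. Reference conditions: K = 4 topics × 15
words, 2000 posts of 8–15 tokens, 100 background words, 4 substances. The
generator requires π > 1/K (below that, topic membership is statistically
unidentifiable). Because the structure lives in co-occurrence, recovery
tests exercise the *whole* chain — embedding training included — rather
than just the clustering step. The rating generator is a rounded, clipped
Gaussian around per-post latent quality plus per-expert bias: the simplest
generative model consistent with a bounded ordinal scale (rounding is
half-up; ties at .5 go up).

What the generator does not emulate: natural-language morphology and word
frequency tails (Zipfian distributions, inflection), thread/quote structure,
topic imbalance, polysemy, or raters whose noise depends on the item.
Passing recovery tests therefore shows the machinery is correct and the
statistical mechanism sound at realistic signal strengths — not that any
particular real corpus will yield clean topics at the default thresholds.

Recovery is measured with the adjusted Rand index (chance-corrected; 1 =
identical partitions, ≈0 under random labeling), computed via scikit-learn.
The reference recovery check trains 50-dimensional embeddings for 15 epochs,
thresholds the keyword graph at the 90th percentile of pairwise cosines, and
requires ARI ≥ 0.8 in at least 4 of 5 seeds; in the same runs each
substance's planted topic must rank first in its association profile in at
least 4 of 5 seeds. These problem sizes (≈25k tokens per corpus) keep a full
recovery evaluation to a few seconds per seed while leaving wide margin
above the thresholds (observed ARIs are typically ≥ 0.93).

## Numerical and degenerate-input choices

Cosines are clamped to [−1, 1] after floating-point dot products; cosine
self-similarity is exact to 1e-9. Neighbor lists break score ties
lexicographically. Stored partition modularity matches recomputation to
1e-9. Empty corpora, empty lexicons and zero-post generator configs are
valid and yield empty outputs; an empty effective vocabulary (nothing
reaches `min_count`), a keyword graph with fewer than two in-vocabulary
nodes, and an all-out-of-vocabulary substance set are structured errors.
Incomplete rating designs are refused with the missing cells named.

## Known limitations

Single-pass expansion cannot reach words related only to expanded terms;
the curated lexicon bounds recall by construction. Louvain output depends
on its seed on graphs with competing near-optimal partitions (the stored
seed and canonical labeling make any given run reproducible). The skip-gram
trainer is single-threaded by design; it is fast enough for corpora of
hundreds of thousands of tokens but is not a replacement for a parallel
trainer at web scale. Inter-rater reliability coefficients (ICC, kappa) are
not computed.
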