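"""Text normalization: platform-artifact removal, tokenization, stopword
removal, pluggable lemmatization and drug-synonym canonicalization.

The pipeline order inside :func:`normalize` is fixed:
lemmatize -> canonicalize synonyms -> remove stopwords. Synonym variants in
curated drug lexicons are surface or lemma forms, so canonicalization must see
lemmas; removing stopwords last guarantees no lemma escapes removal.

The lemmatizer is an injected ``token -> lemma`` callable with an identity
default: forum corpora in morphologically rich languages (the motivating case
is Polish) need a real lemmatizer model, but nothing downstream depends on a
specific one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import yaml

from .corpus_io import Corpus, Lexicon, TokenizedPost

Lemmatizer = Callable[[str], str]


def identity_lemmatizer(token: str) -> str:
    return token


@dataclass
class CleaningRules:
    """Ordered artifact-removal patterns plus a stopword set.

    ``artifact_patterns`` are regular expressions deleted from the raw text in
    the listed order (multiline mode): leading publication dates, quote/report
    UI widgets, "user X said" phrases, inactivity notices, trailing mottos and
    similar platform furniture. Stopword matching is case-insensitive (tokens
    are lowercased before the check).
    """

    artifact_patterns: list[str] = field(default_factory=list)
    stopwords: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._compiled = [
            re.compile(p, re.MULTILINE | re.IGNORECASE) for p in self.artifact_patterns
        ]
        self.stopwords = {s.lower() for s in self.stopwords}

    @classmethod
    def from_config(cls, path: str | Path) -> "CleaningRules":
        """Load rules from a YAML file with keys ``patterns`` and either
        ``stopwords`` (inline list) or ``stopword_file`` (one word per line,
        resolved relative to the config)."""
        path = Path(path)
        cfg = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        patterns = list(cfg.get("patterns", []))
        stopwords = set(cfg.get("stopwords", []))
        sw_file = cfg.get("stopword_file")
        if sw_file:
            sw_path = Path(sw_file)
            if not sw_path.is_absolute():
                sw_path = path.parent / sw_path
            stopwords |= {
                w.strip() for w in sw_path.read_text(encoding="utf-8").splitlines() if w.strip()
            }
        return cls(artifact_patterns=patterns, stopwords=stopwords)


_WS = re.compile(r"\s+")


def strip_artifacts(raw_text: str, rules: CleaningRules) -> str:
    """Delete every occurrence of each artifact pattern, in listed order.

    Whitespace runs left behind by deletions are collapsed; the text is
    otherwise unmodified. Empty output is allowed (a post that was pure
    platform furniture).
    """
    text = raw_text
    for pattern in rules._compiled:
        text = pattern.sub(" ", text)
    return _WS.sub(" ", text).strip()


# Word tokens: runs of unicode word characters. Tokens must begin with a
# letter — this drops pure numbers and quantity fragments like "2g" while
# keeping alphanumeric slang names like "ak47".
_TOKEN = re.compile(r"\w+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens; punctuation and number-led tokens dropped."""
    return [
        t for t in (m.group(0).lower() for m in _TOKEN.finditer(text)) if t[0].isalpha()
    ]


def _canonicalize(tokens: Sequence[str], lexicon: Lexicon) -> list[str]:
    """Replace synonym variants by canonicals, matching multiword variants
    (underscore-joined in the synonym map) greedily before single tokens."""
    multi = {
        tuple(v.split("_")): c for v, c in lexicon.synonym_map.items() if "_" in v
    }
    max_len = max((len(k) for k in multi), default=1)
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        if multi:
            for width in range(min(max_len, n - i), 1, -1):
                gram = tuple(tokens[i : i + width])
                if gram in multi:
                    out.append(multi[gram])
                    i += width
                    matched = True
                    break
        if not matched:
            out.append(lexicon.canonicalize(tokens[i]))
            i += 1
    return out


def normalize(
    tokens: Sequence[str],
    lexicon: Lexicon,
    rules: CleaningRules,
    lemmatizer: Lemmatizer = identity_lemmatizer,
) -> list[str]:
    """Lemmatize, canonicalize drug synonyms, then remove stopwords."""
    lemmas = [lemmatizer(t) for t in tokens]
    canonical = _canonicalize(lemmas, lexicon)
    return [t for t in canonical if t.lower() not in rules.stopwords]


def preprocess_corpus(
    corpus: Corpus,
    lexicon: Lexicon,
    rules: CleaningRules,
    lemmatizer: Lemmatizer = identity_lemmatizer,
) -> list[TokenizedPost]:
    """Run the full normalization chain over a corpus, preserving order."""
    out = []
    for post in corpus:
        cleaned = strip_artifacts(post.raw_text, rules)
        toks = normalize(tokenize(cleaned), lexicon, rules, lemmatizer)
        out.append(TokenizedPost(post.post_id, tuple(toks)))
    return out


def vocabulary(posts: Iterable[TokenizedPost]) -> set[str]:
    vocab: set[str] = set()
    for post in posts:
        vocab.update(post.tokens)
    return vocab
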