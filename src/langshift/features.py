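"""Turn the posts inside one comparison window into a named feature vector.

Feature groups, mirroring the three families used for measuring language
change plus posting metadata:

* ``dict:<category>`` — relative frequency of dictionary-category matches
  (matched tokens / total tokens in the window);
* ``topic:<id>`` — topic loadings from a pre-fitted topic-word table,
  computed as the frequency-weighted mixture of per-word conditional topic
  distributions;
* ``lex:<name>`` — weighted-lexicon scores (intercept + Σ weight·relative
  frequency);
* ``meta:*`` — posts per 3-hour clock bin, total posts, mean tokens/post;
* optionally ``ngram:<gram>`` — raw 1–3-gram relative frequencies (excluded
  from the default model matrix).

The tokenizer here is the package's reference tokenizer: lowercasing, URL
stripping, a fixed emoticon list kept as single tokens, apostrophe
contractions kept intact, and splitting on everything else.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .corpus_io import (
    CategoryDictionary,
    PostRecord,
    TopicTable,
    WeightedLexicon,
)

__all__ = [
    "EMOTICONS",
    "tokenize",
    "TokenizedWindow",
    "build_window",
    "ngram_counts",
    "dictionary_features",
    "TopicLoadings",
    "topic_loadings",
    "lexicon_score",
    "meta_features",
    "FeatureResources",
    "feature_names",
    "featurize",
    "featurize_cohort",
    "ResourceError",
]


class ResourceError(ValueError):
    """A required featurization resource is missing."""


#: Emoticons preserved as single tokens (longest first so ":-)" wins over ":-").
EMOTICONS: tuple[str, ...] = (
    ":'(", ":-)", ":-(", ":-d", ":-p", "^_^", "</3",
    ":)", ":(", ":d", ":p", ":/", ";)", ";(", "<3", "=)", "=(", "xd",
)

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_TOKEN_RE = re.compile(
    "|".join(re.escape(e) for e in EMOTICONS) + r"|[a-z0-9_#@]+(?:'[a-z0-9]+)?"
)


def tokenize(text: str) -> list[str]:
    """Lowercase, strip URLs, keep emoticons and contractions, split the rest.

    >>> tokenize("I'm so sick :(")
    ["i'm", 'so', 'sick', ':(']
    """
    return _TOKEN_RE.findall(_URL_RE.sub(" ", text.lower()))


@dataclass
class TokenizedWindow:
    """All posts of one patient falling inside one comparison window."""

    patient_id: str
    role: str  # "earlier" | "recent"
    post_tokens: list[list[str]]
    post_timestamps: list[datetime]

    @property
    def post_count(self) -> int:
        return len(self.post_tokens)

    @property
    def tokens(self) -> list[str]:
        return [tok for post in self.post_tokens for tok in post]

    @property
    def token_count(self) -> int:
        return sum(len(post) for post in self.post_tokens)

    @property
    def degenerate(self) -> bool:
        """True when the window holds no tokens; features are then all zero."""
        return self.token_count == 0

    def token_counter(self) -> Counter:
        counter: Counter = Counter()
        for post in self.post_tokens:
            counter.update(post)
        return counter


def build_window(posts: Sequence[PostRecord], start: date, end: date,
                 role: str, patient_id: str) -> TokenizedWindow:
    """Tokenize the posts of ``patient_id`` dated within [start, end]."""
    tokens, stamps = [], []
    for rec in posts:
        if rec.patient_id == patient_id and start <= rec.timestamp.date() <= end:
            tokens.append(tokenize(rec.text))
            stamps.append(rec.timestamp)
    return TokenizedWindow(patient_id=patient_id, role=role,
                           post_tokens=tokens, post_timestamps=stamps)


def ngram_counts(post_tokens: Sequence[Sequence[str]], max_n: int = 3) -> Counter:
    """Contiguous 1..max_n-gram counts; grams never span post boundaries."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    counts: Counter = Counter()
    for post in post_tokens:
        for n in range(1, max_n + 1):
            for i in range(len(post) - n + 1):
                counts["_".join(post[i:i + n])] += 1
    return counts


def dictionary_features(window: TokenizedWindow,
                        dictionary: CategoryDictionary) -> dict[str, float]:
    """Per category: matched-token count divided by total window tokens.

    Trailing-wildcard patterns match any token sharing the stem prefix; a
    token matching patterns in several categories counts once in each.
    """
    total = window.token_count
    out = {cat: 0.0 for cat in dictionary.categories}
    if total == 0:
        return out
    counter = window.token_counter()
    for cat, (exact, stems) in dictionary.compiled().items():
        matched = 0
        for token, count in counter.items():
            if token in exact or any(token.startswith(s) for s in stems):
                matched += count
        out[cat] = matched / total
    return out


class TopicLoadings(NamedTuple):
    values: np.ndarray  # aligned with TopicTable.topic_ids
    defined: bool  # False when the window has no in-vocabulary token


def topic_loadings(window: TokenizedWindow, topics: TopicTable) -> TopicLoadings:
    """Loading(t) = Σ_w freq(w | window) · p(t | w).

    Frequencies are relative to the in-vocabulary tokens, so the loadings
    form a probability vector whenever at least one token is in vocabulary;
    otherwise an all-zero vector flagged ``defined=False`` is returned.
    """
    table = topics.p_topic_given_word()
    loadings = np.zeros(len(topics.topic_ids))
    mass = 0
    for token, count in window.token_counter().items():
        vec = table.get(token)
        if vec is not None:
            loadings += count * vec
            mass += count
    if mass == 0:
        return TopicLoadings(loadings, False)
    return TopicLoadings(loadings / mass, True)


def lexicon_score(window: TokenizedWindow, lexicon: WeightedLexicon) -> float:
    """intercept + Σ_w weight(w) · count(w)/total-tokens."""
    total = window.token_count
    if total == 0:
        return lexicon.intercept
    score = 0.0
    for token, count in window.token_counter().items():
        weight = lexicon.weights.get(token)
        if weight is not None:
            score += weight * count
    return lexicon.intercept + score / total


#: Eight half-open 3-hour clock bins, [start, end) in hours.
_META_BINS: tuple[tuple[int, int], ...] = tuple(
    (h, h + 3) for h in range(0, 24, 3)
)


def meta_features(window: TokenizedWindow) -> dict[str, float]:
    """Posting statistics: posts per 3-hour clock bin, totals, mean length."""
    out = {f"meta:posts_{lo:02d}_{hi:02d}": 0.0 for lo, hi in _META_BINS}
    for stamp in window.post_timestamps:
        lo = (stamp.hour // 3) * 3
        out[f"meta:posts_{lo:02d}_{lo + 3:02d}"] += 1.0
    out["meta:total_posts"] = float(window.post_count)
    out["meta:mean_tokens_per_post"] = (
        window.token_count / window.post_count if window.post_count else 0.0
    )
    return out


@dataclass
class FeatureResources:
    """The loaded resources featurize() needs, with a stable feature order."""

    dictionaries: list[CategoryDictionary] = field(default_factory=list)
    topics: TopicTable | None = None
    lexica: list[WeightedLexicon] = field(default_factory=list)
    include_ngrams: bool = False
    ngram_max_n: int = 3


def feature_names(resources: FeatureResources) -> list[str]:
    """The fixed, stable feature-name order used by every FeatureVector."""
    names: list[str] = []
    for dictionary in resources.dictionaries:
        names.extend(f"dict:{cat}" for cat in dictionary.categories)
    if resources.topics is not None:
        names.extend(f"topic:{tid}" for tid in resources.topics.topic_ids)
    names.extend(f"lex:{lex.name}" for lex in resources.lexica)
    names.extend(f"meta:posts_{lo:02d}_{hi:02d}" for lo, hi in _META_BINS)
    names.extend(["meta:total_posts", "meta:mean_tokens_per_post"])
    return names


def featurize(window: TokenizedWindow, resources: FeatureResources) -> pd.Series:
    """Concatenate all feature groups into one named vector.

    A pure function of (window, resources): repeated calls are bit-identical.
    N-gram relative frequencies are appended only when
    ``resources.include_ngrams`` is set; they are excluded from the default
    model matrix.
    """
    if not resources.dictionaries and resources.topics is None \
            and not resources.lexica:
        raise ResourceError("no featurization resources loaded")
    values: dict[str, float] = {}
    for dictionary in resources.dictionaries:
        for cat, freq in dictionary_features(window, dictionary).items():
            values[f"dict:{cat}"] = freq
    if resources.topics is not None:
        loadings = topic_loadings(window, resources.topics)
        for tid, value in zip(resources.topics.topic_ids, loadings.values):
            values[f"topic:{tid}"] = float(value)
    for lexicon in resources.lexica:
        values[f"lex:{lexicon.name}"] = lexicon_score(window, lexicon)
    values.update(meta_features(window))
    vector = pd.Series(values, dtype=float).reindex(feature_names(resources))
    if resources.include_ngrams:
        total = window.token_count
        grams = ngram_counts(window.post_tokens, resources.ngram_max_n)
        gram_series = pd.Series(
            {f"ngram:{g}": c / total for g, c in sorted(grams.items())},
            dtype=float,
        )
        vector = pd.concat([vector, gram_series])
    return vector


def featurize_cohort(posts: Sequence[PostRecord], cohort,
                     resources: FeatureResources) -> pd.DataFrame:
    """Feature panel for a case-control cohort.

    Rows are indexed by (patient_id, event in {true, null}, window in
    {earlier, recent}); columns follow :func:`feature_names`.
    """
    by_patient: dict[str, list[PostRecord]] = {}
    for rec in posts:
        by_patient.setdefault(rec.patient_id, []).append(rec)

    rows, index = [], []
    for pair in cohort.pairs:
        patient_posts = by_patient.get(pair.patient_id, [])
        for event_role, windows in (("true", pair.true_windows),
                                    ("null", pair.null_windows)):
            for window_role in ("earlier", "recent"):
                interval = getattr(windows, window_role)
                window = TokenizedWindow(
                    patient_id=pair.patient_id, role=window_role,
                    post_tokens=[], post_timestamps=[])
                for rec in patient_posts:
                    d = rec.timestamp.date()
                    if interval.start <= d <= interval.end:
                        window.post_tokens.append(tokenize(rec.text))
                        window.post_timestamps.append(rec.timestamp)
                rows.append(featurize(window, resources))
                index.append((pair.patient_id, event_role, window_role))
    frame = pd.DataFrame(rows)
    frame.index = pd.MultiIndex.from_tuples(
        index, names=["patient_id", "event", "window"])
    return frame
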