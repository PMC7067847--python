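"""Tokenization and window featurization against hand-worked values."""

from __future__ import annotations

from datetime import date, datetime

import numpy as np
import pandas as pd
import pytest

import oracles
from langshift.corpus_io import (
    CategoryDictionary,
    TopicTable,
    WeightedLexicon,
)
from langshift.features import (
    FeatureResources,
    ResourceError,
    TokenizedWindow,
    dictionary_features,
    feature_names,
    featurize,
    featurize_cohort,
    lexicon_score,
    meta_features,
    ngram_counts,
    tokenize,
    topic_loadings,
)


def window_of(posts: list[list[str]], stamps=None) -> TokenizedWindow:
    stamps = stamps or [datetime(2014, 3, 1, 10, 0)] * len(posts)
    return TokenizedWindow("p", "recent", posts, stamps)


# --- tokenizer ------------------------------------------------------------


@pytest.mark.parametrize("text,expected", [
    ("I'm so sick :(", ["i'm", "so", "sick", ":("]),
    ("", []),
    ("LOL Lol lol", ["lol", "lol", "lol"]),
    ("love this <3 :)", ["love", "this", "<3", ":)"]),
    ("read http://t.co/abc now", ["read", "now"]),
    ("pain, pain... PAIN!", ["pain", "pain", "pain"]),
])
def test_tokenize(text, expected):
    assert tokenize(text) == expected


# --- n-grams --------------------------------------------------------------


def test_ngram_enumeration_matches_brute_force():
    counts = ngram_counts([["a", "b", "c"]])
    assert counts == {"a": 1, "b": 1, "c": 1, "a_b": 1, "b_c": 1, "a_b_c": 1}


def test_ngrams_do_not_span_posts():
    counts = ngram_counts([["a"], ["b"]])
    assert counts == {"a": 1, "b": 1}


def test_single_token_yields_only_unigram():
    assert ngram_counts([["lol"]]) == {"lol": 1}


# --- dictionary features --------------------------------------------------


def test_relative_frequency_formula():
    tokens = ["sick"] * 5 + ["x"] * 95
    window = window_of([tokens])
    d = CategoryDictionary("d", {"health": ["sick"]})
    assert dictionary_features(window, d) == {"health": 0.05}


def test_wildcard_matches_prefix():
    d = CategoryDictionary("d", {"health": ["hosp*"]})
    window = window_of([["hospital", "pain"]])
    assert dictionary_features(window, d)["health"] == 0.5


def test_token_counts_once_per_category():
    d = CategoryDictionary("d", {"health": ["sick"], "negemo": ["sick"]})
    window = window_of([["sick", "ok"]])
    features = dictionary_features(window, d)
    assert features == {"health": 0.5, "negemo": 0.5}


def test_empty_window_gives_zero_features():
    d = CategoryDictionary("d", {"health": ["sick"]})
    window = window_of([])
    assert window.degenerate
    assert dictionary_features(window, d) == {"health": 0.0}


# --- topic loadings -------------------------------------------------------


def test_single_topic_word_gives_unit_loading():
    topics = TopicTable(entries={(3, "pain"): 0.7})
    loadings = topic_loadings(window_of([["pain", "zzz"]]), topics)
    assert loadings.defined
    assert list(loadings.values) == [1.0]


def test_two_word_mixture_matches_hand_computation():
    # p(t1|a)=0.9, p(t1|b)=0.25; freq a=2/3, b=1/3
    topics = TopicTable(entries={(1, "a"): 0.9, (2, "a"): 0.1,
                                 (1, "b"): 0.2, (2, "b"): 0.6})
    loadings = topic_loadings(window_of([["a", "a", "b"]]), topics)
    assert loadings.values == pytest.approx([2 / 3 * 0.9 + 1 / 3 * 0.25,
                                             2 / 3 * 0.1 + 1 / 3 * 0.75])
    assert loadings.values.sum() == pytest.approx(1.0)


def test_out_of_vocabulary_window_flagged():
    topics = TopicTable(entries={(1, "pain"): 1.0})
    loadings = topic_loadings(window_of([["zzz"]]), topics)
    assert not loadings.defined
    assert not loadings.values.any()


# --- lexicon scores -------------------------------------------------------


def test_lexicon_weighted_frequency_sum():
    lex = WeightedLexicon("valence", {"sick": 2.0, "happy": -1.0})
    window = window_of([["sick", "sick", "happy"]])
    assert lexicon_score(window, lex) == pytest.approx(1.0)


def test_empty_overlap_returns_intercept():
    lex = WeightedLexicon("anxious", {"worry": 1.0}, intercept=0.3)
    assert lexicon_score(window_of([["calm"]]), lex) == 0.3


def test_score_invariant_under_token_duplication():
    lex = WeightedLexicon("valence", {"sick": 2.0, "fun": -0.5})
    tokens = ["sick", "fun", "other"]
    once = lexicon_score(window_of([tokens]), lex)
    twice = lexicon_score(window_of([tokens, tokens]), lex)
    assert once == pytest.approx(twice)


# --- meta features --------------------------------------------------------


def test_clock_bins():
    window = window_of([["a"], ["b"]],
                       stamps=[datetime(2014, 3, 1, 9, 30),
                               datetime(2014, 3, 1, 13, 0)])
    meta = meta_features(window)
    assert meta["meta:posts_09_12"] == 1
    assert meta["meta:posts_12_15"] == 1
    assert meta["meta:total_posts"] == 2


def test_noon_boundary_is_half_open():
    window = window_of([["a"]], stamps=[datetime(2014, 3, 1, 12, 0, 0)])
    meta = meta_features(window)
    assert meta["meta:posts_12_15"] == 1
    assert meta["meta:posts_09_12"] == 0


def test_zero_posts_meta():
    meta = meta_features(window_of([]))
    assert meta["meta:total_posts"] == 0
    assert meta["meta:mean_tokens_per_post"] == 0


# --- featurize ------------------------------------------------------------


def test_feature_vector_arity_and_order(tiny_resources):
    names = feature_names(tiny_resources)
    n_cats = sum(len(d.categories) for d in tiny_resources.dictionaries)
    n_topics = len(tiny_resources.topics.topic_ids)
    assert len(names) == n_cats + n_topics + len(tiny_resources.lexica) + 10
    vector = featurize(window_of([["sick", "lol"]]), tiny_resources)
    assert list(vector.index) == names


def test_featurize_is_pure(tiny_resources):
    window = window_of([["sick", "pain", ":)"]])
    a = featurize(window, tiny_resources)
    b = featurize(window, tiny_resources)
    assert (a == b).all()


def test_featurize_relative_features_invariant_under_duplication(tiny_resources):
    posts = [["sick", "lol", "fun"], ["pain", "u"]]
    stamps = [datetime(2014, 3, 1, 10), datetime(2014, 3, 2, 15)]
    base = featurize(window_of(posts, stamps), tiny_resources)
    doubled = featurize(window_of(posts + posts, stamps + stamps),
                        tiny_resources)
    relative = [n for n in base.index if not n.startswith("meta:")]
    assert base[relative].values == pytest.approx(doubled[relative].values)


def test_featurize_requires_resources():
    with pytest.raises(ResourceError):
        featurize(window_of([["x"]]), FeatureResources())


def test_topic_features_form_probability_vector(tiny_resources):
    vector = featurize(window_of([["sick", "pain", "lol", "zzz"]]),
                       tiny_resources)
    topic_vals = vector[[n for n in vector.index if n.startswith("topic:")]]
    assert (topic_vals >= 0).all()
    assert topic_vals.sum() == pytest.approx(1.0)


def test_window_features_match_naive_oracle(tiny_resources):
    posts = [tokenize(t) for t in ["I'm so sick :( lol",
                                   "hospital visit for pain",
                                   "fun day", "worry worry lol"]]
    window = window_of(posts)
    vector = featurize(window, tiny_resources)
    tokens = [t for post in posts for t in post]
    d = tiny_resources.dictionaries[0]
    for cat, patterns in d.categories.items():
        assert vector[f"dict:{cat}"] == pytest.approx(
            oracles.dict_relative_frequency(tokens, patterns), abs=1e-12)
    for tid in tiny_resources.topics.topic_ids:
        assert vector[f"topic:{tid}"] == pytest.approx(
            oracles.topic_loading(tokens, tiny_resources.topics.entries, tid),
            abs=1e-12)
    for lex in tiny_resources.lexica:
        assert vector[f"lex:{lex.name}"] == pytest.approx(
            oracles.lexicon_score(tokens, lex.weights, lex.intercept),
            abs=1e-12)
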