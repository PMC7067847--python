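"""Shared fixtures: a tiny hand-checkable corpus and matching resources.

The fixture corpus holds 3 patients posting every other day over March
2014 (48 posts), with texts cycling through a pool that exercises
emoticons, URLs, empty posts, wildcard stems and words shared between
categories.  Window geometry is shrunk (5-day windows, 2-day gap, >=2
posts per window) so every quantity stays small enough to verify by hand
or with the naive oracles in tests/oracles.py.
"""

from __future__ import annotations

from datetime import date, datetime

import pytest

from langshift.corpus_io import (
    CategoryDictionary,
    PipelineConfig,
    PostRecord,
    TopicTable,
    VisitEvent,
    VisitType,
    WeightedLexicon,
)
from langshift.features import FeatureResources

TEXT_POOL = [
    "I'm so sick :( see http://example.com/x",
    "LOL u know it",
    "hospital visit for pain",
    "fun day with family",
    "sad and sick again",
    "",
    "worry worry lol",
    "feeling good today",
]


@pytest.fixture(scope="session")
def fixture_config() -> PipelineConfig:
    return PipelineConfig(window_length_days=5, gap_days=2,
                          min_posts_per_window=2, rng_seed=7)


@pytest.fixture(scope="session")
def fixture_posts() -> list[PostRecord]:
    posts = []
    for p_idx, pid in enumerate(["p1", "p2", "p3"]):
        for day in range(1, 32, 2):
            text = TEXT_POOL[(p_idx * 7 + day) % len(TEXT_POOL)]
            posts.append(PostRecord(
                pid, datetime(2014, 3, day, (9 + day) % 24, 30), text))
    return posts


@pytest.fixture(scope="session")
def fixture_events() -> list[VisitEvent]:
    return [
        VisitEvent("p1", date(2014, 3, 25), VisitType.ED),
        VisitEvent("p2", date(2014, 3, 28), VisitType.ED),
        VisitEvent("p3", date(2014, 3, 27), VisitType.ED),
    ]


@pytest.fixture(scope="session")
def tiny_resources() -> FeatureResources:
    dictionary = CategoryDictionary(name="tiny", categories={
        "health": ["sick", "pain", "hosp*"],
        "informal": ["lol", "u", ":)"],
        "negemo": ["sick", "sad"],
    })
    topics = TopicTable(entries={
        (1, "sick"): 0.9, (2, "sick"): 0.1,
        (1, "pain"): 0.5, (2, "pain"): 0.5,
        (2, "lol"): 1.0,
        (1, "hospital"): 0.3, (3, "hospital"): 0.7,
        (3, "fun"): 1.0,
    })
    lexica = [
        WeightedLexicon("valence", {"sick": -2.0, "fun": 1.0, "sad": -1.0,
                                    "lol": 0.5}),
        WeightedLexicon("anxious", {"worry": 1.0, "sick": 0.5},
                        intercept=0.1),
    ]
    return FeatureResources(dictionaries=[dictionary], topics=topics,
                            lexica=lexica)
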