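"""Case-crossover construction: window geometry, eligibility, null sampling."""

from __future__ import annotations

from datetime import date, datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from langshift.corpus_io import (
    PipelineConfig,
    PostRecord,
    VisitEvent,
    VisitType,
)
from langshift.design import (
    CohortError,
    assemble_cohort,
    build_window_pair,
    cohort_manifest,
    sample_null_event,
    select_true_event,
)


def posts_every_day(pid: str, start: date, n_days: int,
                    per_day: int = 1) -> list[PostRecord]:
    return [
        PostRecord(pid, datetime.combine(start + timedelta(days=d),
                                         datetime.min.time())
                   + timedelta(hours=10, minutes=m), "sick lol")
        for d in range(n_days) for m in range(per_day)
    ]


def test_default_geometry_matches_day_arithmetic():
    # event at ordinal day 100: recent=[70,99], gap=[55,69], earlier=[25,54]
    event = date.fromordinal(735000 + 100)
    wp = build_window_pair(event, PipelineConfig())
    day = lambda d: date.fromordinal(735000 + d)
    assert (wp.recent.start, wp.recent.end) == (day(70), day(99))
    assert (wp.gap.start, wp.gap.end) == (day(55), day(69))
    assert (wp.earlier.start, wp.earlier.end) == (day(25), day(54))


def test_event_day_excluded_from_recent_window():
    event = date(2014, 6, 1)
    wp = build_window_pair(event, PipelineConfig())
    assert not wp.recent.contains(event)


def test_degenerate_single_day_windows():
    config = PipelineConfig(window_length_days=1, gap_days=0,
                            min_posts_per_window=1)
    wp = build_window_pair(date(2014, 6, 10), config)
    assert wp.gap is None
    assert wp.recent == wp.recent._replace(start=date(2014, 6, 9),
                                           end=date(2014, 6, 9))
    assert wp.earlier.start == wp.earlier.end == date(2014, 6, 8)


@settings(max_examples=200, derandomize=True)
@given(
    ordinal=st.integers(min_value=700000, max_value=740000),
    window=st.integers(min_value=1, max_value=60),
    gap=st.integers(min_value=0, max_value=30),
)
def test_window_geometry_property(ordinal, window, gap):
    """Exact lengths, pairwise disjointness, event-day exclusion."""
    config = PipelineConfig(window_length_days=window, gap_days=gap)
    event = date.fromordinal(ordinal)
    wp = build_window_pair(event, config)
    assert wp.earlier.n_days == window
    assert wp.recent.n_days == window
    assert wp.recent.end == event - timedelta(days=1)
    if gap:
        assert wp.gap.n_days == gap
        assert wp.earlier.end < wp.gap.start
        assert wp.gap.end < wp.recent.start
    else:
        assert wp.earlier.end < wp.recent.start
    assert wp.span.n_days == 2 * window + gap


# --- true-event selection -------------------------------------------------


def test_most_recent_qualifying_visit_selected():
    config = PipelineConfig(min_posts_per_window=5)
    posts = posts_every_day("p1", date(2014, 1, 1), 200)
    visits = [VisitEvent("p1", date(2014, 4, 1), VisitType.ED),
              VisitEvent("p1", date(2014, 6, 1), VisitType.ED)]
    assert select_true_event(visits, posts, config) == (date(2014, 6, 1),
                                                        VisitType.ED)


def test_scan_back_when_latest_visit_fails():
    config = PipelineConfig(min_posts_per_window=21)
    # posting stops in May: the July visit has empty windows, March qualifies
    posts = posts_every_day("p1", date(2014, 1, 1), 120)
    visits = [VisitEvent("p1", date(2014, 7, 20), VisitType.ED),
              VisitEvent("p1", date(2014, 4, 1), VisitType.ED)]
    assert select_true_event(visits, posts, config) == (date(2014, 4, 1),
                                                        VisitType.ED)
    assert select_true_event(visits, posts, config, strict=True) is None


def test_no_qualifying_visit_returns_none():
    config = PipelineConfig()
    posts = posts_every_day("p1", date(2014, 1, 1), 10)
    visits = [VisitEvent("p1", date(2014, 1, 9), VisitType.ED)]
    assert select_true_event(visits, posts, config) is None


# --- null-event sampling --------------------------------------------------


def test_null_sampling_deterministic_given_seed():
    config = PipelineConfig(min_posts_per_window=5)
    posts = posts_every_day("p1", date(2014, 1, 1), 300)
    true_event = date(2014, 10, 1)
    d1 = sample_null_event(posts, true_event, config,
                           np.random.default_rng(11))
    d2 = sample_null_event(posts, true_event, config,
                           np.random.default_rng(11))
    assert d1 == d2 is not None


def test_null_forced_into_early_history_and_disjoint():
    """150 days of dense history, event at the end: the only feasible null
    periods sit in the first half; verified non-overlapping."""
    config = PipelineConfig(min_posts_per_window=5)
    posts = posts_every_day("p1", date(2014, 1, 1), 150)
    true_event = date(2014, 1, 1) + timedelta(days=150)
    null_date = sample_null_event(posts, true_event, config,
                                  np.random.default_rng(0))
    assert null_date is not None
    assert (null_date - date(2014, 1, 1)).days <= 75
    null_span = build_window_pair(null_date, config).span
    true_span = build_window_pair(true_event, config).span
    assert not null_span.overlaps(true_span)


def test_short_history_yields_no_null():
    config = PipelineConfig(min_posts_per_window=5)
    posts = posts_every_day("p1", date(2014, 1, 1), 80)
    assert sample_null_event(posts, date(2014, 3, 20), config,
                             np.random.default_rng(0)) is None


# --- cohort assembly ------------------------------------------------------


def make_population():
    posts, events = [], []
    for i, pid in enumerate(["a", "b", "c"]):
        n_days = 60 if pid == "c" else 300  # "c" cannot satisfy inclusion
        posts += posts_every_day(pid, date(2014, 1, 1), n_days)
        events.append(VisitEvent(pid, date(2014, 1, 1)
                                 + timedelta(days=n_days - 5), VisitType.ED))
    return posts, events


def test_assemble_retains_qualifying_drops_rest(caplog):
    posts, events = make_population()
    config = PipelineConfig(min_posts_per_window=5)
    cohort = assemble_cohort(posts, events, "ED", config, rng=1)
    assert sorted(cohort.patient_ids) == ["a", "b"]
    assert cohort.n_dropped == 1
    manifest = cohort_manifest(cohort, posts)
    assert (manifest[["true_earlier_posts", "true_recent_posts",
                      "null_earlier_posts", "null_recent_posts"]] >= 5).all().all()


def test_pairing_completeness():
    posts, events = make_population()
    cohort = assemble_cohort(posts, events,
                             VisitType.ED, PipelineConfig(min_posts_per_window=5),
                             rng=3)
    for pair in cohort.pairs:
        assert pair.true_date != pair.null_date
    assert len({p.patient_id for p in cohort.pairs}) == len(cohort.pairs)


def test_reseeding_changes_only_null_side():
    posts, events = make_population()
    config = PipelineConfig(min_posts_per_window=5)
    c1 = assemble_cohort(posts, events, "ED", config, rng=1)
    c2 = assemble_cohort(posts, events, "ED", config, rng=2)
    assert [p.true_date for p in c1.pairs] == [p.true_date for p in c2.pairs]
    assert [p.true_windows for p in c1.pairs] == [p.true_windows for p in c2.pairs]


def test_empty_eligible_cohort_raises():
    posts = posts_every_day("a", date(2014, 1, 1), 10)
    events = [VisitEvent("a", date(2014, 1, 8), VisitType.ED)]
    with pytest.raises(CohortError):
        assemble_cohort(posts, events, "ED", PipelineConfig(), rng=0)
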