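"""Paired case-crossover construction.

Each eligible patient contributes exactly two events — the true event (a
hospital visit) and a null event (a random date) — so that every patient is
their own control.  Before each event lies a 75-day lookback: two 30-day
comparison windows ("earlier" and "recent") separated by a 15-day gap, all
ending the day before the event, which itself is excluded.  Patients are
included only when both windows of an event contain at least
``min_posts_per_window`` posts (the "more than 20 posts per month" rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .corpus_io import PipelineConfig, PostRecord, VisitEvent, VisitType

log = logging.getLogger("langshift")

__all__ = [
    "DateInterval",
    "WindowPair",
    "EventPair",
    "CaseControlCohort",
    "CohortError",
    "build_window_pair",
    "select_true_event",
    "sample_null_event",
    "assemble_cohort",
    "cohort_manifest",
]


class CohortError(ValueError):
    """No patient satisfied the eligibility criteria."""


class DateInterval(NamedTuple):
    """Whole-day interval with inclusive endpoints."""

    start: date
    end: date

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def contains(self, day: date) -> bool:
        return self.start <= day <= self.end

    def overlaps(self, other: "DateInterval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class WindowPair:
    """The 30/15/30-day lookback geometry before one event.

    With defaults and an event on day e: recent = [e-30, e-1],
    gap = [e-45, e-31], earlier = [e-75, e-46].  ``gap`` is None when the
    configured gap length is zero.
    """

    earlier: DateInterval
    gap: DateInterval | None
    recent: DateInterval

    @property
    def span(self) -> DateInterval:
        return DateInterval(self.earlier.start, self.recent.end)


def build_window_pair(event_date: date, config: PipelineConfig) -> WindowPair:
    """Lay out the two comparison windows and the gap before ``event_date``."""
    w, g = config.window_length_days, config.gap_days
    recent = DateInterval(event_date - timedelta(days=w),
                          event_date - timedelta(days=1))
    gap = None
    if g > 0:
        gap = DateInterval(event_date - timedelta(days=w + g),
                           event_date - timedelta(days=w + 1))
    earlier = DateInterval(event_date - timedelta(days=2 * w + g),
                           event_date - timedelta(days=w + g + 1))
    return WindowPair(earlier=earlier, gap=gap, recent=recent)


def _count_in(post_ordinals: np.ndarray, interval: DateInterval) -> int:
    """Number of posts dated inside the interval; ordinals must be sorted."""
    lo = np.searchsorted(post_ordinals, interval.start.toordinal(), "left")
    hi = np.searchsorted(post_ordinals, interval.end.toordinal(), "right")
    return int(hi - lo)


def _qualifies(post_ordinals: np.ndarray, windows: WindowPair,
               config: PipelineConfig) -> bool:
    return (_count_in(post_ordinals, windows.earlier) >= config.min_posts_per_window
            and _count_in(post_ordinals, windows.recent) >= config.min_posts_per_window)


def _post_ordinals(posts: Sequence[PostRecord]) -> np.ndarray:
    return np.sort(np.array([p.timestamp.date().toordinal() for p in posts],
                            dtype=np.int64))


def select_true_event(visits: Sequence[VisitEvent],
                      posts: Sequence[PostRecord],
                      config: PipelineConfig,
                      strict: bool = False) -> tuple[date, VisitType] | None:
    """Pick the patient's case date: the most recent qualifying visit.

    Visits are scanned from most recent to earliest, returning the first
    whose lookback windows both satisfy the posts-per-window rule.  In
    ``strict`` mode only the single most recent visit is considered and the
    patient is dropped if it fails — the alternative literal reading of
    "the most recent visit date".
    """
    if not visits:
        return None
    ordinals = _post_ordinals(posts)
    ordered = sorted(visits, key=lambda v: v.visit_date, reverse=True)
    if strict:
        ordered = ordered[:1]
    for visit in ordered:
        if _qualifies(ordinals, build_window_pair(visit.visit_date, config), config):
            return visit.visit_date, visit.visit_type
    return None


def sample_null_event(posts: Sequence[PostRecord], true_event: date,
                      config: PipelineConfig, rng: np.random.Generator,
                      max_draws: int = 200,
                      allow_overlap: bool = False) -> date | None:
    """Draw the patient's control date uniformly from the posting span.

    Candidates come from [first_post + period, last_post] so the full 75-day
    lookback exists; a candidate is accepted when both its windows satisfy
    the inclusion rule and (unless ``allow_overlap``) its lookback period is
    disjoint from the true event's.  Returns None after ``max_draws``
    rejections or when no feasible support exists.
    """
    if not posts:
        return None
    ordinals = _post_ordinals(posts)
    lo = int(ordinals[0]) + config.period_days
    hi = int(ordinals[-1])
    if lo > hi:
        return None
    true_span = build_window_pair(true_event, config).span
    for _ in range(max_draws):
        candidate = date.fromordinal(int(rng.integers(lo, hi + 1)))
        windows = build_window_pair(candidate, config)
        if not _qualifies(ordinals, windows, config):
            continue
        if not allow_overlap and windows.span.overlaps(true_span):
            continue
        return candidate
    return None


@dataclass(frozen=True)
class EventPair:
    """One patient's paired true/null events with their window geometry."""

    patient_id: str
    true_date: date
    visit_type: VisitType
    true_windows: WindowPair
    null_date: date
    null_windows: WindowPair


@dataclass
class CaseControlCohort:
    """All retained patients of one analysis arm with their event pairs."""

    arm: VisitType
    pairs: list[EventPair]
    config: PipelineConfig
    n_dropped: int = 0

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.pairs]


def assemble_cohort(posts: Sequence[PostRecord], events: Sequence[VisitEvent],
                    arm: VisitType | str, config: PipelineConfig,
                    rng: np.random.Generator | int | None = None,
                    strict: bool = False,
                    allow_overlap: bool = False) -> CaseControlCohort:
    """Build the paired cohort for one arm: one EventPair per retained patient.

    True-event selection is deterministic; only the null date consumes
    randomness, so regenerating an independent control set with a new seed
    leaves every true-side quantity identical.
    """
    arm = VisitType.parse(arm) if isinstance(arm, str) else arm
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.rng_seed if rng is None else rng)

    posts_by_patient: dict[str, list[PostRecord]] = {}
    for rec in posts:
        posts_by_patient.setdefault(rec.patient_id, []).append(rec)
    visits_by_patient: dict[str, list[VisitEvent]] = {}
    for ev in events:
        if ev.visit_type == arm:
            visits_by_patient.setdefault(ev.patient_id, []).append(ev)

    pairs: list[EventPair] = []
    n_dropped = 0
    for patient_id in sorted(visits_by_patient):
        patient_posts = posts_by_patient.get(patient_id, [])
        selected = select_true_event(visits_by_patient[patient_id],
                                     patient_posts, config, strict=strict)
        if selected is None:
            n_dropped += 1
            log.info("patient %s dropped: no qualifying visit", patient_id)
            continue
        true_date, visit_type = selected
        null_date = sample_null_event(patient_posts, true_date, config, rng,
                                      allow_overlap=allow_overlap)
        if null_date is None:
            n_dropped += 1
            log.info("patient %s dropped: no feasible null event", patient_id)
            continue
        pairs.append(EventPair(
            patient_id=patient_id,
            true_date=true_date,
            visit_type=visit_type,
            true_windows=build_window_pair(true_date, config),
            null_date=null_date,
            null_windows=build_window_pair(null_date, config),
        ))
    if not pairs:
        raise CohortError(f"no eligible patient in arm {arm.value}")
    log.info("arm %s: retained %d patients, dropped %d",
             arm.value, len(pairs), n_dropped)
    return CaseControlCohort(arm=arm, pairs=pairs, config=config,
                             n_dropped=n_dropped)


def cohort_manifest(cohort: CaseControlCohort,
                    posts: Sequence[PostRecord]) -> pd.DataFrame:
    """Audit table: per patient, event dates and posts per window."""
    by_patient: dict[str, list[PostRecord]] = {}
    for rec in posts:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    rows = []
    for pair in cohort.pairs:
        ordinals = _post_ordinals(by_patient.get(pair.patient_id, []))
        rows.append({
            "patient_id": pair.patient_id,
            "arm": cohort.arm.value,
            "true_date": pair.true_date.isoformat(),
            "null_date": pair.null_date.isoformat(),
            "true_earlier_posts": _count_in(ordinals, pair.true_windows.earlier),
            "true_recent_posts": _count_in(ordinals, pair.true_windows.recent),
            "null_earlier_posts": _count_in(ordinals, pair.null_windows.earlier),
            "null_recent_posts": _count_in(ordinals, pair.null_windows.recent),
        })
    return pd.DataFrame(rows)
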