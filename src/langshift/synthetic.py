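"""Synthetic patient cohorts with injected lexical effects of known size.

The real corpus behind this kind of analysis — patients' social-media posts
linked to their visit records — cannot be shared, so this module generates a
cohort whose statistical structure matches what the pipeline assumes: each
patient emits posts as a homogeneous Poisson process over their history,
every post draws i.i.d. tokens from a mixture vocabulary containing the
dictionary-category words, and a configurable multiplicative shift is
applied to chosen category words inside the 30 days immediately preceding
that patient's visit (the recent pre-event window only, not the gap).

Because the injection is multiplicative on emission probabilities with
renormalization, the induced standardized paired effect (Cohen's d_z of the
diff-of-diff of the category's relative frequency) has a closed form, which
:func:`expected_effect` computes and :func:`multiplier_for_effect` inverts.
That analytic truth is what downstream parameter-recovery tests check the
pipeline against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .corpus_io import (
    CategoryDictionary,
    ConfigError,
    PostRecord,
    TopicTable,
    VisitEvent,
    VisitType,
    WeightedLexicon,
)
from .features import FeatureResources

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "default_vocabulary",
    "default_dictionary",
    "default_resources",
    "generate_cohort",
    "expected_effect",
    "multiplier_for_effect",
]

_SECONDS_PER_DAY = 86400

# Vocabulary blocks.  Category words sit alongside high-frequency filler so
# that category relative frequencies live in the few-percent range typical
# of closed-vocabulary dictionary features.
_CATEGORY_WORDS: dict[str, tuple[str, ...]] = {
    "health": ("sick", "pain", "hurt", "tired", "hospital", "doctor",
               "meds", "ill", "ache", "fever"),
    "informal": ("lol", "u", "da", "smh", "lmao", "haha", "ya", "bro",
                 "omg", "idk"),
    "family": ("baby", "son", "family", "mom", "kids", "daughter",
               "mother", "home"),
    "leisure": ("fun", "play", "nap", "movie", "game", "party", "music",
                "chill"),
    "negemo": ("sad", "mad", "cry", "ugh", "hate", "worry", "stress",
               "alone"),
    "social": ("friends", "we", "our", "love", "talk", "hang", "crew",
               "together"),
}

_FILLER_WORDS: tuple[str, ...] = (
    "the", "a", "to", "and", "i", "you", "is", "it", "of", "in", "on",
    "for", "my", "me", "so", "be", "at", "this", "that", "with", "just",
    "not", "get", "go", "day", "good", "time", "today", "now", "all",
)


def default_vocabulary() -> dict[str, float]:
    """Zipf-weighted filler words plus flat-weighted category words.

    Weights: filler word at rank r gets 1/(r+1); every category word gets
    0.02, putting each category's total baseline emission probability near
    0.04-0.05 after normalization.
    """
    weights = {w: 1.0 / (r + 1) for r, w in enumerate(_FILLER_WORDS)}
    for words in _CATEGORY_WORDS.values():
        for w in words:
            weights[w] = 0.02
    total = sum(weights.values())
    return {w: v / total for w, v in weights.items()}


def default_dictionary() -> CategoryDictionary:
    """The synthetic closed-vocabulary dictionary matching the generator.

    One pattern per category word, with a stem wildcard standing in for the
    LIWC convention ("ach*" covers "ache").
    """
    categories = {}
    for cat, words in _CATEGORY_WORDS.items():
        patterns = [w for w in words if w != "ache"] + (
            ["ach*"] if "ache" in words else [])
        categories[cat] = patterns
    return CategoryDictionary(name="synthetic-dict", categories=categories)


def _default_topics() -> TopicTable:
    """Eight synthetic topics: one per category, two spanning the filler."""
    entries: dict[tuple[int, str], float] = {}
    for tid, (cat, words) in enumerate(_CATEGORY_WORDS.items()):
        for w in words:
            entries[(tid, w)] = 0.8
            entries[(6 + tid % 2, w)] = 0.2
    for r, w in enumerate(_FILLER_WORDS):
        entries[(6 + r % 2, w)] = 1.0
    return TopicTable(entries=entries)


def _default_lexica() -> list[WeightedLexicon]:
    return [
        WeightedLexicon("valence", {
            "fun": 1.0, "love": 1.0, "good": 1.0, "play": 0.5,
            "sad": -1.0, "cry": -1.0, "hate": -1.0, "pain": -1.0,
            "sick": -0.5}),
        WeightedLexicon("arousal", {
            "party": 1.0, "omg": 1.0, "mad": 1.0, "stress": 0.5,
            "nap": -1.0, "chill": -1.0, "tired": -0.5}),
        WeightedLexicon("anxious", {
            "worry": 1.0, "stress": 1.0, "fever": 0.5, "alone": 0.5,
            "ugh": 0.5}),
        WeightedLexicon("depressed", {
            "sad": 1.0, "cry": 1.0, "alone": 1.0, "tired": 0.5,
            "hate": 0.5}),
        WeightedLexicon("extraverted", {
            "friends": 1.0, "party": 1.0, "talk": 1.0, "crew": 1.0,
            "hang": 1.0, "alone": -1.0}),
    ]


def default_resources() -> FeatureResources:
    """Dictionary + topic table + five lexica matched to the generator."""
    return FeatureResources(
        dictionaries=[default_dictionary()],
        topics=_default_topics(),
        lexica=_default_lexica(),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic cohort.

    ``effect_specs`` lists (category, multiplier) pairs; each multiplies the
    emission probability of that category's words (with renormalization)
    inside the ``window_length_days`` immediately before a patient's visit.
    """

    n_patients: int
    history_days: int = 365
    posts_per_day_rate: float = 1.5
    words_per_post: float = 12.0
    background_vocab: Mapping[str, float] | None = None
    effect_specs: tuple[tuple[str, float], ...] = ()
    event_fraction: float = 1.0
    visit_type: VisitType = VisitType.ED
    window_length_days: int = 30
    gap_days: int = 15
    start_date: date = date(2014, 1, 1)
    rng_seed: int = 0
    dictionary: CategoryDictionary | None = None

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if self.posts_per_day_rate <= 0 or self.words_per_post <= 0:
            raise ConfigError("rates must be positive")
        if not 0 < self.event_fraction <= 1:
            raise ConfigError("event_fraction must lie in (0, 1]")
        span = 2 * self.window_length_days + self.gap_days
        if self.history_days < 2 * span:
            raise ConfigError(
                f"history_days must be >= {2 * span} to fit two disjoint "
                f"{span}-day lookback periods")
        vocab = dict(self.background_vocab) if self.background_vocab is not None \
            else default_vocabulary()
        if abs(sum(vocab.values()) - 1.0) > 1e-9:
            raise ConfigError("background_vocab probabilities must sum to 1")
        object.__setattr__(self, "background_vocab", vocab)
        for cat, mult in self.effect_specs:
            if mult <= 0:
                raise ConfigError(f"multiplier for {cat!r} must be positive")
        object.__setattr__(self, "effect_specs", tuple(
            (c, float(m)) for c, m in self.effect_specs))
        if self.dictionary is None:
            object.__setattr__(self, "dictionary", default_dictionary())

    @property
    def period_days(self) -> int:
        return 2 * self.window_length_days + self.gap_days

    def with_(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)


@dataclass
class SyntheticCohort:
    """Generated posts, events, and the injected ground truth."""

    posts: list[PostRecord]
    events: list[VisitEvent]
    truth: dict[str, dict[str, float]]
    config: SimulationConfig


def _category_mask(config: SimulationConfig, words: Sequence[str],
                   category: str) -> np.ndarray:
    """Boolean mask over the vocabulary for one dictionary category."""
    assert config.dictionary is not None
    compiled = config.dictionary.compiled()
    if category not in compiled:
        raise KeyError(f"unknown category {category!r}")
    exact, stems = compiled[category]
    return np.array([
        w in exact or any(w.startswith(s) for s in stems) for w in words
    ])


def _effect_vectors(config: SimulationConfig,
                    words: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(baseline probs, boosted-and-renormalized probs) over the vocabulary."""
    p = np.array([config.background_vocab[w] for w in words])
    mult = np.ones(len(words))
    for cat, m in config.effect_specs:
        mask = _category_mask(config, words, cat)
        mult[mask] *= m
    boosted = p * mult
    return p, boosted / boosted.sum()


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate the cohort; deterministic given ``config.rng_seed``.

    Per patient: daily post counts are Poisson(``posts_per_day_rate``), post
    lengths are Poisson(``words_per_post``) truncated at >=1 word, and tokens
    are i.i.d. draws from the background vocabulary — switched to the
    boosted distribution for posts dated within the recent pre-event window.
    """
    rng = np.random.default_rng(config.rng_seed)
    words = sorted(config.background_vocab)
    vocab_arr = np.array(words)
    p_base, p_boost = _effect_vectors(config, words)

    n = config.n_patients
    n_events = int(round(config.event_fraction * n))
    event_patients = np.sort(rng.permutation(n)[:n_events])
    min_day = config.period_days
    if min_day > config.history_days - 1:
        raise ConfigError(
            f"patient 0: no feasible event day in a {config.history_days}-day "
            "history")
    event_days = rng.integers(min_day, config.history_days, n_events)
    event_day_of = dict(zip(event_patients.tolist(), event_days.tolist()))

    base_dt = datetime.combine(config.start_date, time(0, 0))
    posts: list[PostRecord] = []
    events: list[VisitEvent] = []
    lam = config.words_per_post

    for i in range(n):
        pid = f"p{i:04d}"
        daily = rng.poisson(config.posts_per_day_rate, config.history_days)
        total = int(daily.sum())
        day_idx = np.repeat(np.arange(config.history_days), daily)
        secs = rng.integers(0, _SECONDS_PER_DAY, total)
        order = np.lexsort((secs, day_idx))
        day_idx, secs = day_idx[order], secs[order]
        lengths = np.maximum(rng.poisson(lam, total), 1)

        event_day = event_day_of.get(i)
        if event_day is not None:
            boosted = (day_idx >= event_day - config.window_length_days) \
                & (day_idx <= event_day - 1)
            events.append(VisitEvent(
                pid, config.start_date + timedelta(days=int(event_day)),
                config.visit_type))
        else:
            boosted = np.zeros(total, dtype=bool)

        texts = np.empty(total, dtype=object)
        for regime, probs in ((False, p_base), (True, p_boost)):
            sel = np.flatnonzero(boosted == regime)
            if sel.size == 0:
                continue
            n_tokens = int(lengths[sel].sum())
            token_counts = rng.multinomial(n_tokens, probs)
            tokens = np.repeat(np.arange(len(words)), token_counts)
            rng.shuffle(tokens)
            bounds = np.cumsum(lengths[sel])[:-1]
            for post_pos, chunk in zip(sel, np.split(tokens, bounds)):
                texts[post_pos] = " ".join(vocab_arr[chunk])

        for d, s, text in zip(day_idx, secs, texts):
            posts.append(PostRecord(
                pid, base_dt + timedelta(days=int(d), seconds=int(s)), text))

    truth = {
        cat: {"multiplier": m, "expected_d": expected_effect(config, cat)}
        for cat, m in config.effect_specs
    }
    return SyntheticCohort(posts=posts, events=events, truth=truth,
                           config=config)


def _window_token_moments(config: SimulationConfig) -> tuple[float, float]:
    """(E[N], E[1/N]) for the token count N of one comparison window.

    N is compound Poisson: posts ~ Poisson(rate x window days), lengths
    max(1, Poisson(lambda)).  E[1/N] uses the second-order delta
    approximation E[1/N] ~ (1 + Var(N)/E[N]^2) / E[N].
    """
    lam = config.words_per_post
    n_posts = config.posts_per_day_rate * config.window_length_days
    p0 = math.exp(-lam)
    mean_len = lam + p0            # E[max(1, X)] = E[X] + P(X = 0)
    mean_sq_len = lam + lam ** 2 + p0
    mean_n = n_posts * mean_len
    var_n = n_posts * mean_sq_len  # compound-Poisson variance
    inv_mean_n = (1.0 + var_n / mean_n ** 2) / mean_n
    return mean_n, inv_mean_n


def expected_effect(config: SimulationConfig, category: str) -> float:
    """Analytic expected paired standardized effect (Cohen's d_z).

    The diff-of-diff of the category's relative frequency is
    D = (f_recent^true - f_earlier^true) - (f_recent^null - f_earlier^null),
    where each window frequency is approximately Binomial(N, p)/N with N the
    window's token count.  Only the true event's recent window uses the
    boosted probability p1 = m*p0 / Z (Z the renormalizer), so
    E[D] = p1 - p0 and
    Var(D) = p1(1-p1)*E[1/N] + 3*p0(1-p0)*E[1/N];
    d_z = E[D] / sqrt(Var(D)).
    """
    if category not in {c for c, _ in config.effect_specs}:
        raise KeyError(f"category {category!r} not in effect_specs")
    words = sorted(config.background_vocab)
    p_base, p_boost = _effect_vectors(config, words)
    mask = _category_mask(config, words, category)
    p0 = float(p_base[mask].sum())
    p1 = float(p_boost[mask].sum())
    _, inv_n = _window_token_moments(config)
    var_d = (p1 * (1 - p1) + 3 * p0 * (1 - p0)) * inv_n
    if var_d == 0:
        return 0.0
    return (p1 - p0) / math.sqrt(var_d)


def multiplier_for_effect(config: SimulationConfig, category: str,
                          target_d: float) -> float:
    """Invert :func:`expected_effect`: the multiplier giving ``target_d``.

    Calibration considers the category alone (any other effect_specs are
    ignored while solving).
    """
    if target_d == 0:
        return 1.0

    def gap(m: float) -> float:
        probe = config.with_(effect_specs=((category, m),))
        return expected_effect(probe, category) - target_d

    lo, hi = (1.0, 1e4) if target_d > 0 else (1e-6, 1.0)
    return float(brentq(gap, lo, hi, xtol=1e-10))
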