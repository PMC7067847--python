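"""Domain types, configuration, and readers/writers for every external format.

The pipeline touches five kinds of files: timestamped post streams (JSON
Lines or CSV), hospital-visit event tables (CSV), closed-vocabulary category
dictionaries (LIWC-style ``.dic`` or a two-column CSV), topic-word weight
tables (CSV), and weighted affect/trait lexica (CSV).  All parsers are
line-streaming and total: a malformed row either raises a typed error or is
counted, logged and skipped — never silently corrupted.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np

log = logging.getLogger("langshift")

__all__ = [
    "VisitType",
    "PostRecord",
    "VisitEvent",
    "CategoryDictionary",
    "TopicTable",
    "WeightedLexicon",
    "PipelineConfig",
    "CorpusFormatError",
    "PatternError",
    "ConfigError",
    "read_posts",
    "write_posts",
    "read_events",
    "write_events",
    "read_dictionary",
    "write_dictionary",
    "read_topic_table",
    "write_topic_table",
    "read_lexicon",
    "write_lexicon",
    "file_sha256",
]


class CorpusFormatError(ValueError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class PatternError(ValueError):
    """A dictionary pattern violates the wildcard rules."""


class ConfigError(ValueError):
    """A configuration value violates its invariants."""


class VisitType(str, Enum):
    """The two analysis arms: ED visit without admission vs inpatient stay."""

    ED = "ED"
    INPATIENT = "inpatient"

    @classmethod
    def parse(cls, raw: str) -> "VisitType":
        norm = raw.strip()
        for member in cls:
            if norm.lower() == member.value.lower():
                return member
        raise CorpusFormatError(f"unknown visit_type {raw!r}; expected ED or inpatient")


class PostRecord(NamedTuple):
    """One authored message: who wrote it, when, and the raw text."""

    patient_id: str
    timestamp: datetime
    text: str


class VisitEvent(NamedTuple):
    """One hospital-visit event for a patient, tagged with its analysis arm."""

    patient_id: str
    visit_date: date
    visit_type: VisitType


def _parse_timestamp(raw: str) -> datetime:
    """Parse an ISO-8601 timestamp; bare dates are assigned 12:00 local.

    Date-only exports are common in EMR-adjacent data; noon keeps such posts
    inside the waking-hours clock bins used by the meta features.
    """
    raw = raw.strip()
    try:
        ts = datetime.fromisoformat(raw)
    except ValueError as exc:
        raise CorpusFormatError(f"unparseable timestamp {raw!r}") from exc
    if len(raw) == 10:  # plain YYYY-MM-DD
        ts = datetime.combine(ts.date(), time(12, 0))
    return ts


# ---------------------------------------------------------------------------
# posts


def _post_from_mapping(row: Mapping[str, object]) -> PostRecord:
    missing = {"patient_id", "timestamp", "text"} - set(row)
    if missing:
        raise CorpusFormatError(f"missing required field(s) {sorted(missing)}")
    text = row["text"]
    return PostRecord(
        patient_id=str(row["patient_id"]),
        timestamp=_parse_timestamp(str(row["timestamp"])),
        text="" if text is None else str(text),
    )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise ValueError(f"format must be 'jsonl' or 'csv', got {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    if suffix in (".csv", ".tsv"):
        return "csv"
    raise ValueError(f"cannot infer posts format from suffix {suffix!r}")


def read_posts(path: str | Path, format: str | None = None) -> list[PostRecord]:
    """Read a post stream, returning records sorted by (patient_id, timestamp).

    Rows with an unparseable timestamp are skipped with a row-numbered
    diagnostic; a missing required column aborts with
    :class:`CorpusFormatError`.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    records: list[PostRecord] = []
    n_bad = 0
    with path.open("r", encoding="utf-8", newline="") as handle:
        if fmt == "jsonl":
            rows: Iterator[tuple[int, Mapping[str, object]]] = (
                (i, json.loads(line))
                for i, line in enumerate(handle, start=1)
                if line.strip()
            )
        else:
            reader = csv.DictReader(handle)
            if reader.fieldnames is None:
                log.warning("posts file %s is empty", path)
                return []
            missing = {"patient_id", "timestamp", "text"} - set(reader.fieldnames)
            if missing:
                raise CorpusFormatError(
                    f"{path}: posts CSV missing column(s) {sorted(missing)}"
                )
            rows = enumerate(reader, start=2)  # header is line 1
        for lineno, row in rows:
            try:
                records.append(_post_from_mapping(row))
            except CorpusFormatError as exc:
                n_bad += 1
                log.warning("%s row %d rejected: %s", path, lineno, exc)
    if n_bad:
        log.warning("%s: skipped %d malformed row(s)", path, n_bad)
    if not records:
        log.warning("%s: no post records read", path)
    records.sort(key=lambda r: (r.patient_id, r.timestamp))
    return records


def write_posts(records: Sequence[PostRecord], path: str | Path,
                format: str | None = None) -> None:
    """Write posts in the same dialects :func:`read_posts` accepts."""
    path = Path(path)
    fmt = _infer_format(path, format)
    with path.open("w", encoding="utf-8", newline="") as handle:
        if fmt == "jsonl":
            for rec in records:
                handle.write(json.dumps({
                    "patient_id": rec.patient_id,
                    "timestamp": rec.timestamp.isoformat(),
                    "text": rec.text,
                }) + "\n")
        else:
            writer = csv.writer(handle)
            writer.writerow(["patient_id", "timestamp", "text"])
            for rec in records:
                writer.writerow([rec.patient_id, rec.timestamp.isoformat(), rec.text])


# ---------------------------------------------------------------------------
# events


def read_events(path: str | Path) -> list[VisitEvent]:
    """Read the visit-event table: CSV with patient_id, visit_date, visit_type."""
    path = Path(path)
    events: list[VisitEvent] = []
    with path.open("r", encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            log.warning("events file %s is empty", path)
            return []
        missing = {"patient_id", "visit_date", "visit_type"} - set(reader.fieldnames)
        if missing:
            raise CorpusFormatError(
                f"{path}: events CSV missing column(s) {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                visit_date = date.fromisoformat(row["visit_date"].strip())
            except ValueError as exc:
                raise CorpusFormatError(
                    f"{path} row {lineno}: bad visit_date {row['visit_date']!r}"
                ) from exc
            events.append(VisitEvent(
                patient_id=str(row["patient_id"]),
                visit_date=visit_date,
                visit_type=VisitType.parse(row["visit_type"]),
            ))
    return events


def write_events(events: Sequence[VisitEvent], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["patient_id", "visit_date", "visit_type"])
        for ev in events:
            writer.writerow([ev.patient_id, ev.visit_date.isoformat(),
                             ev.visit_type.value])


# ---------------------------------------------------------------------------
# category dictionaries


def _validate_pattern(pattern: str) -> str:
    pattern = pattern.strip().lower()
    if not pattern:
        raise PatternError("empty dictionary pattern")
    if "*" in pattern[:-1]:
        raise PatternError(
            f"wildcard only allowed as final character, got {pattern!r}"
        )
    return pattern


@dataclass
class CategoryDictionary:
    """A closed-vocabulary dictionary: category name → word/stem patterns.

    Patterns are lowercase literal words, or stems with a single trailing
    ``*`` wildcard matching any token with that prefix (the LIWC convention).
    """

    name: str
    categories: dict[str, list[str]]

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for cat, patterns in self.categories.items():
            seen: dict[str, None] = {}
            for pat in patterns:
                seen.setdefault(_validate_pattern(pat), None)
            if not seen:
                raise PatternError(f"category {cat!r} has no patterns")
            cleaned[cat] = list(seen)
        if not cleaned:
            raise PatternError(f"dictionary {self.name!r} has no categories")
        self.categories = cleaned
        self._compiled: dict[str, tuple[frozenset[str], tuple[str, ...]]] | None = None

    def compiled(self) -> dict[str, tuple[frozenset[str], tuple[str, ...]]]:
        """Per category: (exact-word set, stem prefixes) for fast matching."""
        if self._compiled is None:
            out = {}
            for cat, patterns in self.categories.items():
                exact = frozenset(p for p in patterns if not p.endswith("*"))
                stems = tuple(p[:-1] for p in patterns if p.endswith("*"))
                out[cat] = (exact, stems)
            self._compiled = out
        return self._compiled

    def matches(self, token: str, category: str) -> bool:
        exact, stems = self.compiled()[category]
        return token in exact or any(token.startswith(s) for s in stems)


def _read_dic(path: Path) -> CategoryDictionary:
    """Parse the classic LIWC ``.dic`` layout.

    A ``%``-delimited header maps numeric ids to category names, followed by
    ``word<TAB>id id ...`` body lines.
    """
    id_to_name: dict[str, str] = {}
    categories: dict[str, list[str]] = {}
    with path.open("r", encoding="utf-8") as handle:
        lines = [ln.rstrip("\n") for ln in handle]
    seps = [i for i, ln in enumerate(lines) if ln.strip() == "%"]
    if len(seps) < 2:
        raise CorpusFormatError(f"{path}: .dic file needs a %%-delimited header")
    for ln in lines[seps[0] + 1:seps[1]]:
        if not ln.strip():
            continue
        parts = ln.split()
        if len(parts) < 2:
            raise CorpusFormatError(f"{path}: bad category header line {ln!r}")
        id_to_name[parts[0]] = parts[1]
        categories[parts[1]] = []
    for ln in lines[seps[1] + 1:]:
        if not ln.strip():
            continue
        parts = ln.split()
        word, ids = parts[0], parts[1:]
        if not ids:
            raise CorpusFormatError(f"{path}: word {word!r} has no category ids")
        for cid in ids:
            if cid not in id_to_name:
                raise CorpusFormatError(f"{path}: unknown category id {cid!r}")
            categories[id_to_name[cid]].append(word)
    categories = {c: pats for c, pats in categories.items() if pats}
    return CategoryDictionary(name=path.stem, categories=categories)


def _read_dict_csv(path: Path) -> CategoryDictionary:
    categories: dict[str, list[str]] = {}
    with path.open("r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle)
        for lineno, row in enumerate(reader, start=1):
            if not row or (lineno == 1 and [c.lower() for c in row[:2]]
                           == ["category", "pattern"]):
                continue
            if len(row) < 2:
                raise CorpusFormatError(f"{path} row {lineno}: need category,pattern")
            categories.setdefault(row[0].strip(), []).append(row[1])
    return CategoryDictionary(name=path.stem, categories=categories)


def read_dictionary(path: str | Path) -> CategoryDictionary:
    """Read a category dictionary from ``.dic`` or two-column CSV."""
    path = Path(path)
    if path.suffix.lower() == ".dic":
        return _read_dic(path)
    return _read_dict_csv(path)


def write_dictionary(dictionary: CategoryDictionary, path: str | Path) -> None:
    """Write a dictionary in the two-column CSV dialect."""
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["category", "pattern"])
        for cat, patterns in dictionary.categories.items():
            for pat in patterns:
                writer.writerow([cat, pat])


# ---------------------------------------------------------------------------
# topic tables


@dataclass
class TopicTable:
    """Topic-word weights from a pre-fitted topic model.

    ``entries`` maps ``(topic_id, word)`` to a non-negative weight.  The
    loading computation uses the per-word conditional topic distribution
    p(topic | word), i.e. each word's weights normalized over topics.
    """

    entries: dict[tuple[int, str], float]
    n_topics: int = 0

    def __post_init__(self) -> None:
        for (tid, word), weight in self.entries.items():
            if weight < 0:
                raise CorpusFormatError(
                    f"negative weight {weight} for topic {tid}, word {word!r}"
                )
        topic_ids = sorted({tid for tid, _ in self.entries})
        if not topic_ids:
            raise CorpusFormatError("topic table is empty")
        totals: dict[int, float] = {}
        for (tid, _), weight in self.entries.items():
            totals[tid] = totals.get(tid, 0.0) + weight
        for tid, total in totals.items():
            if total <= 0:
                raise CorpusFormatError(f"topic {tid} has no positive weight")
        self.topic_ids: list[int] = topic_ids
        if not self.n_topics:
            self.n_topics = len(topic_ids)
        self._p_topic_given_word: dict[str, np.ndarray] | None = None

    def p_topic_given_word(self) -> dict[str, np.ndarray]:
        """word → probability vector over ``self.topic_ids`` (sums to 1)."""
        if self._p_topic_given_word is None:
            index = {tid: i for i, tid in enumerate(self.topic_ids)}
            table: dict[str, np.ndarray] = {}
            for (tid, word), weight in self.entries.items():
                vec = table.setdefault(word, np.zeros(len(self.topic_ids)))
                vec[index[tid]] += weight
            normalized = {}
            for word, vec in table.items():
                total = vec.sum()
                if total > 0:
                    normalized[word] = vec / total
            self._p_topic_given_word = normalized
        return self._p_topic_given_word

    @property
    def vocabulary(self) -> set[str]:
        return set(self.p_topic_given_word())


def read_topic_table(path: str | Path) -> TopicTable:
    """Read a topic table: CSV with columns topic, word, weight."""
    path = Path(path)
    entries: dict[tuple[int, str], float] = {}
    with path.open("r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if lineno == 1 and not row[0].strip().lstrip("-").isdigit():
                continue  # header
            if len(row) < 3:
                raise CorpusFormatError(f"{path} row {lineno}: need topic,word,weight")
            try:
                tid, weight = int(row[0]), float(row[2])
            except ValueError as exc:
                raise CorpusFormatError(f"{path} row {lineno}: {exc}") from exc
            entries[(tid, row[1].strip().lower())] = (
                entries.get((tid, row[1].strip().lower()), 0.0) + weight
            )
    return TopicTable(entries=entries)


def write_topic_table(topics: TopicTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["topic", "word", "weight"])
        for (tid, word), weight in sorted(topics.entries.items()):
            writer.writerow([tid, word, repr(weight)])


# ---------------------------------------------------------------------------
# weighted lexica


@dataclass
class WeightedLexicon:
    """A word → weight table scoring a construct (valence, arousal, ...)."""

    name: str
    weights: dict[str, float]
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.weights = {w.strip().lower(): float(v) for w, v in self.weights.items()}
        if not any(v != 0 for v in self.weights.values()):
            raise CorpusFormatError(f"lexicon {self.name!r} has no nonzero weight")


def read_lexicon(path: str | Path, name: str | None = None) -> WeightedLexicon:
    """Read a weighted lexicon: CSV with columns word, weight.

    A row whose word is the literal ``_intercept`` sets the model intercept.
    """
    path = Path(path)
    weights: dict[str, float] = {}
    intercept = 0.0
    with path.open("r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if lineno == 1 and [c.lower() for c in row[:2]] == ["word", "weight"]:
                continue
            if len(row) < 2:
                raise CorpusFormatError(f"{path} row {lineno}: need word,weight")
            try:
                value = float(row[1])
            except ValueError as exc:
                raise CorpusFormatError(f"{path} row {lineno}: {exc}") from exc
            if row[0].strip() == "_intercept":
                intercept = value
            else:
                weights[row[0]] = value
    return WeightedLexicon(name=name or path.stem, weights=weights,
                           intercept=intercept)


def write_lexicon(lexicon: WeightedLexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["word", "weight"])
        if lexicon.intercept:
            writer.writerow(["_intercept", repr(lexicon.intercept)])
        for word, weight in lexicon.weights.items():
            writer.writerow([word, repr(weight)])


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the case-crossover analysis.

    ``window_length_days``/``gap_days`` give the 30/15/30-day geometry; the
    two comparison windows end the day before the event.
    ``min_posts_per_window`` encodes the "more than 20 posts" inclusion rule
    as a strict >20, i.e. >=21, threshold.
    """

    window_length_days: int = 30
    gap_days: int = 15
    min_posts_per_window: int = 21
    n_topics: int = 200
    cv_folds: int = 5
    alpha: float = 0.05
    pca_variance_retained: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_length_days", "min_posts_per_window", "n_topics",
                     "cv_folds"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.gap_days < 0:
            raise ConfigError("gap_days must be non-negative")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0 < self.pca_variance_retained <= 1:
            raise ConfigError("pca_variance_retained must lie in (0, 1]")

    @property
    def period_days(self) -> int:
        """Total pre-event lookback: two windows plus the gap (75 by default)."""
        return 2 * self.window_length_days + self.gap_days

    def with_(self, **overrides) -> "PipelineConfig":
        return replace(self, **overrides)


def file_sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with Path(path).open("rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()
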