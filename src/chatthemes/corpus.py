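"""Canonical data model for helpline chat corpora.

A corpus is a collection of conversations — timestamped, speaker-tagged
message sequences — with an optional partial map of expert labels.  Labels
cover three families of binary indicators: six conversation themes, seven
volunteer intervention strategies, and three mental-health issues.  A flag
may be 0, 1, or unknown (``None``); unknown is a distinct state and is never
coerced to 0.

Two on-disk dialects are supported: JSON-lines (one conversation object per
line) and a flat CSV (one row per message, labels in a sidecar CSV keyed by
conversation id).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

THEMES = (
    "self_image",
    "violence",
    "sexual_diversity",
    "relational",
    "emotional_crisis",
    "performance",
)
STRATEGIES = (
    "exploration",
    "containment",
    "resources",
    "reflection",
    "validation",
    "psychoeducation",
    "derivation",
)
ISSUES = ("suicidal", "depressive", "anxious")

SPEAKERS = ("user", "volunteer")


class CorpusSchemaError(ValueError):
    """A record is missing a required field or has a malformed value."""


class CorpusIntegrityError(ValueError):
    """Cross-record constraint violated (duplicate ids, dangling labels)."""


@dataclass(frozen=True)
class Message:
    """One chat turn: who spoke, what they wrote, and its ordinal position."""

    speaker: str
    text: str
    index: int

    def __post_init__(self) -> None:
        if self.speaker not in SPEAKERS:
            raise CorpusSchemaError(
                f"message speaker must be one of {SPEAKERS}, got {self.speaker!r}"
            )
        if self.text is None:
            raise CorpusSchemaError("message text may be empty but not absent")
        if self.index < 0:
            raise CorpusSchemaError("message index must be non-negative")


def _validate_flags(kind: str, names: Sequence[str], flags: Mapping[str, object]) -> dict:
    out: dict = {}
    for name in names:
        v = flags.get(name, None)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            out[name] = None
        elif v in (0, 1):
            out[name] = int(v)
        else:
            raise CorpusSchemaError(f"{kind} flag {name!r} must be 0, 1 or unknown, got {v!r}")
    unknown_keys = set(flags) - set(names)
    if unknown_keys:
        raise CorpusSchemaError(f"unknown {kind} flag name(s): {sorted(unknown_keys)}")
    return out


@dataclass(frozen=True)
class LabelSet:
    """Binary indicators for themes, strategies and issues.

    Each flag is 0, 1 or ``None`` (unknown).  Missing names default to
    unknown, never to 0.
    """

    themes: Mapping[str, Optional[int]] = field(default_factory=dict)
    strategies: Mapping[str, Optional[int]] = field(default_factory=dict)
    issues: Mapping[str, Optional[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "themes", _validate_flags("theme", THEMES, self.themes))
        object.__setattr__(
            self, "strategies", _validate_flags("strategy", STRATEGIES, self.strategies)
        )
        object.__setattr__(self, "issues", _validate_flags("issue", ISSUES, self.issues))

    def known(self) -> dict:
        """All flags with a known 0/1 value, as a flat {name: value} dict."""
        out = {}
        for group in (self.themes, self.strategies, self.issues):
            out.update({k: v for k, v in group.items() if v is not None})
        return out


@dataclass(frozen=True)
class Conversation:
    """A single helpline conversation: id, calendar month, ordered messages."""

    id: str
    year: int
    month: int
    messages: tuple
    age: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusSchemaError("conversation id must be a non-empty string")
        if not (1 <= int(self.month) <= 12):
            raise CorpusSchemaError(
                f"conversation {self.id!r}: month must be in 1..12, got {self.month}"
            )
        msgs = tuple(self.messages)
        for i, m in enumerate(msgs):
            if m.index != i:
                raise CorpusSchemaError(
                    f"conversation {self.id!r}: message indices must be 0-based and "
                    f"contiguous (position {i} has index {m.index})"
                )
        object.__setattr__(self, "messages", msgs)
        if self.age is not None and self.age < 0:
            raise CorpusSchemaError(f"conversation {self.id!r}: age must be non-negative")

    @property
    def n_messages(self) -> int:
        return len(self.messages)

    @property
    def word_count(self) -> int:
        # Whitespace tokens of the raw text, before any normalization;
        # this is the descriptive statistic, not the model input.
        return sum(len(m.text.split()) for m in self.messages)


@dataclass
class Corpus:
    """Conversations plus a partial id → LabelSet map."""

    conversations: list
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.conversations]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise CorpusIntegrityError(f"duplicate conversation id {dup!r}")
        dangling = set(self.labels) - set(ids)
        if dangling:
            raise CorpusIntegrityError(
                f"labels refer to missing conversation id(s): {sorted(dangling)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.conversations)

    def __iter__(self):
        return iter(self.conversations)

    def ids(self) -> list:
        return [c.id for c in self.conversations]


# ---------------------------------------------------------------------------
# I/O


def _labelset_to_obj(ls: LabelSet) -> dict:
    def keep(d):
        return {k: v for k, v in d.items() if v is not None}

    return {"themes": keep(ls.themes), "strategies": keep(ls.strategies), "issues": keep(ls.issues)}


def _conversation_from_obj(obj: dict, where: str) -> tuple:
    for fld in ("id", "year", "month", "messages"):
        if fld not in obj:
            raise CorpusSchemaError(f"{where}: missing required field {fld!r}")
    msgs = []
    for i, m in enumerate(obj["messages"]):
        for fld in ("speaker", "text"):
            if fld not in m:
                raise CorpusSchemaError(f"{where}: message {i} missing field {fld!r}")
        msgs.append(Message(speaker=m["speaker"], text=m["text"], index=i))
    conv = Conversation(
        id=str(obj["id"]),
        year=int(obj["year"]),
        month=int(obj["month"]),
        messages=tuple(msgs),
        age=None if obj.get("age") is None else float(obj["age"]),
    )
    labels = None
    if "labels" in obj and obj["labels"] is not None:
        lab = obj["labels"]
        labels = LabelSet(
            themes=lab.get("themes", {}),
            strategies=lab.get("strategies", {}),
            issues=lab.get("issues", {}),
        )
    return conv, labels


def read_corpus(path, format: str = "jsonl", labels_path=None) -> Corpus:
    """Read a corpus from disk.

    Parameters
    ----------
    path : path-like
        JSON-lines file (``format="jsonl"``) or per-message CSV
        (``format="csv"``).
    labels_path : path-like, optional
        For the CSV dialect only: sidecar label CSV keyed by
        ``conversation_id``.

    Unparseable records raise :class:`CorpusSchemaError` naming the record;
    duplicate ids raise :class:`CorpusIntegrityError`.  Records are never
    skipped silently.
    """
    path = Path(path)
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "csv":
        return _read_csv(path, labels_path)
    raise ValueError(f"unknown corpus format {format!r}")


def _read_jsonl(path: Path) -> Corpus:
    conversations, labels = [], {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusSchemaError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
            conv, ls = _conversation_from_obj(obj, f"{path}:{lineno}")
            conversations.append(conv)
            if ls is not None:
                labels[conv.id] = ls
    return Corpus(conversations=conversations, labels=labels)


def _read_csv(path: Path, labels_path) -> Corpus:
    rows_by_id: dict = {}
    order: list = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"conversation_id", "year", "month", "msg_index", "speaker", "text"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise CorpusSchemaError(f"{path}: missing CSV column(s) {sorted(missing)}")
        for rowno, row in enumerate(reader, start=2):
            cid = row["conversation_id"]
            if not cid:
                raise CorpusSchemaError(f"{path}: row {rowno}: empty conversation_id")
            if cid not in rows_by_id:
                rows_by_id[cid] = []
                order.append(cid)
            rows_by_id[cid].append((rowno, row))
    conversations = []
    for cid in order:
        rows = sorted(rows_by_id[cid], key=lambda r: int(r[1]["msg_index"]))
        first = rows[0][1]
        msgs = []
        for i, (rowno, row) in enumerate(rows):
            if int(row["msg_index"]) != i:
                raise CorpusSchemaError(
                    f"{path}: conversation {cid!r}: msg_index not contiguous at row {rowno}"
                )
            msgs.append(Message(speaker=row["speaker"], text=row["text"], index=i))
        age = first.get("age")
        conversations.append(
            Conversation(
                id=cid,
                year=int(first["year"]),
                month=int(first["month"]),
                messages=tuple(msgs),
                age=float(age) if age not in (None, "") else None,
            )
        )
    labels = {}
    if labels_path is not None:
        with open(labels_path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if "conversation_id" not in (reader.fieldnames or []):
                raise CorpusSchemaError(f"{labels_path}: missing column 'conversation_id'")
            for row in reader:
                cid = row.pop("conversation_id")
                groups = {"themes": {}, "strategies": {}, "issues": {}}
                for key, val in row.items():
                    if val in (None, ""):
                        continue
                    if key in THEMES:
                        groups["themes"][key] = int(val)
                    elif key in STRATEGIES:
                        groups["strategies"][key] = int(val)
                    elif key in ISSUES:
                        groups["issues"][key] = int(val)
                    else:
                        raise CorpusSchemaError(f"{labels_path}: unknown label column {key!r}")
                labels[cid] = LabelSet(**groups)
    return Corpus(conversations=conversations, labels=labels)


def write_corpus(corpus: Corpus, path, format: str = "jsonl", labels_path=None) -> None:
    """Write a corpus in either dialect; round-trips through :func:`read_corpus`."""
    path = Path(path)
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for conv in corpus.conversations:
                obj: dict = {
                    "id": conv.id,
                    "year": conv.year,
                    "month": conv.month,
                    "messages": [{"speaker": m.speaker, "text": m.text} for m in conv.messages],
                }
                if conv.age is not None:
                    obj["age"] = conv.age
                if conv.id in corpus.labels:
                    obj["labels"] = _labelset_to_obj(corpus.labels[conv.id])
                fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")
    elif format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["conversation_id", "year", "month", "msg_index", "speaker", "text", "age"]
            )
            for conv in corpus.conversations:
                for m in conv.messages:
                    writer.writerow(
                        [
                            conv.id,
                            conv.year,
                            conv.month,
                            m.index,
                            m.speaker,
                            m.text,
                            "" if conv.age is None else conv.age,
                        ]
                    )
        if labels_path is not None:
            cols = list(THEMES) + list(STRATEGIES) + list(ISSUES)
            with open(labels_path, "w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh)
                writer.writerow(["conversation_id"] + cols)
                for conv in corpus.conversations:
                    if conv.id not in corpus.labels:
                        continue
                    ls = corpus.labels[conv.id]
                    flat = {**ls.themes, **ls.strategies, **ls.issues}
                    writer.writerow(
                        [conv.id] + ["" if flat[c] is None else flat[c] for c in cols]
                    )
    else:
        raise ValueError(f"unknown corpus format {format!r}")


# ---------------------------------------------------------------------------
# Inclusion filter and descriptives


def filter_min_messages(corpus: Corpus, min_messages: int = 10) -> Corpus:
    """Drop conversations with fewer than ``min_messages`` messages.

    The default threshold of 10 is the study inclusion rule: a conversation
    with exactly 10 messages is retained.  Returns a new Corpus; the input
    is unchanged.  Idempotent.
    """
    if min_messages < 0:
        raise ValueError("min_messages must be non-negative")
    kept = [c for c in corpus.conversations if c.n_messages >= min_messages]
    kept_ids = {c.id for c in kept}
    return Corpus(
        conversations=kept,
        labels={cid: ls for cid, ls in corpus.labels.items() if cid in kept_ids},
    )


@dataclass(frozen=True)
class CorpusSummary:
    n_conversations: int
    counts_per_year: dict
    mean_words: Optional[float]
    age_mean: Optional[float]
    age_sd: Optional[float]
    age_n: int
    label_coverage: dict  # group -> number of conversations with >=1 known flag


def corpus_summary(corpus: Corpus) -> CorpusSummary:
    """Descriptive statistics: yearly counts, mean raw words, known-age stats.

    Mean words uses whitespace tokenization of raw message text (the
    descriptive convention, computed before preprocessing).  Age statistics
    use conversations with a known age only.  On an empty corpus the means
    are reported as absent (``None``), never NaN.
    """
    n = len(corpus.conversations)
    counts_per_year: dict = {}
    total_words = 0
    ages = []
    for c in corpus.conversations:
        counts_per_year[c.year] = counts_per_year.get(c.year, 0) + 1
        total_words += c.word_count
        if c.age is not None:
            ages.append(c.age)
    mean_words = total_words / n if n else None
    if ages:
        age_mean = sum(ages) / len(ages)
        age_sd = (
            math.sqrt(sum((a - age_mean) ** 2 for a in ages) / (len(ages) - 1))
            if len(ages) > 1
            else 0.0
        )
    else:
        age_mean = age_sd = None
    coverage = {"themes": 0, "strategies": 0, "issues": 0}
    for ls in corpus.labels.values():
        for group, flags in (
            ("themes", ls.themes),
            ("strategies", ls.strategies),
            ("issues", ls.issues),
        ):
            if any(v is not None for v in flags.values()):
                coverage[group] += 1
    return CorpusSummary(
        n_conversations=n,
        counts_per_year=dict(sorted(counts_per_year.items())),
        mean_words=mean_words,
        age_mean=age_mean,
        age_sd=age_sd,
        age_n=len(ages),
        label_coverage=coverage,
    )


def month_index(year: int, month: int) -> int:
    """Months since year 0, for calendar arithmetic and ordering."""
    return year * 12 + (month - 1)


def month_range(start: tuple, end: tuple) -> list:
    """Inclusive list of (year, month) pairs from start to end."""
    out = []
    i, j = month_index(*start), month_index(*end)
    if j < i:
        raise ValueError("end month precedes start month")
    for k in range(i, j + 1):
        out.append((k // 12, k % 12 + 1))
    return out
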