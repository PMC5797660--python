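"""Data model and I/O for situation corpora, vocabularies, and gold lexicons.

A *situation* is one learning event in a caregiver--infant interaction: the
caregiver produces an utterance (a sequence of word tokens) while a set of
objects is visible, exactly one of which is jointly attended by caregiver and
child.  Optionally each word carries a scalar prosodic feature (the difference
between the 75th-percentile pitch of the word and of its utterance, in Hz).

Corpora are stored as JSON lines, one situation per line::

    {"id": 1, "utterance": ["look", "a", "book"], "objects": ["book", "bird"],
     "attended": "book", "prosody": [1.2, -0.3, 24.0]}

Gold lexicons are two-column TSV files (``word<TAB>object``), one word-object
pair per row; a word may map to several objects (e.g. "bird" -> bird, duck).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


class CorpusError(ValueError):
    """Raised when a corpus file or situation violates the format contract."""


def tokenize_utterance(text: str) -> list[str]:
    """Split a raw utterance into lowercase word tokens.

    Whitespace-delimited, lowercased, no stemming; punctuation attached to a
    word stays with it.  The empty string yields an empty token list.
    """
    return text.lower().split()


def strip_plural_suffix(token: str) -> str:
    """Optional normalizer mapping a plural surface form to its base form.

    Off by default everywhere: word identity in this package is the exact
    vocabulary token.  Transcribed child-directed speech sometimes treats
    "books" and "book" as the same lexical action; callers who want that
    behaviour can map tokens through this function before building a corpus.
    """
    if len(token) > 3 and token.endswith("s") and not token.endswith("ss"):
        return token[:-1]
    return token


@dataclass
class Situation:
    """One learning event: utterance, visible objects, attended object.

    Parameters
    ----------
    index : int
        1-based ordinal of the situation within its corpus.
    words : sequence of str
        Utterance tokens, in order; length ``d >= 1``.
    visible_objects : collection of str
        Labels of the objects present in the scene (at most a handful;
        referential uncertainty comes from there being more than one).
    attended_object : str
        The jointly-attended object; must be one of ``visible_objects``.
    prosody : sequence of float, optional
        Per-word prosodic feature values (Hz), aligned with ``words``.
    """

    index: int
    words: tuple[str, ...]
    visible_objects: frozenset[str]
    attended_object: str
    prosody: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.words = tuple(self.words)
        self.visible_objects = frozenset(self.visible_objects)
        if self.prosody is not None:
            self.prosody = tuple(float(v) for v in self.prosody)
        self.validate()

    def validate(self) -> None:
        if len(self.words) < 1:
            raise CorpusError(f"situation {self.index}: utterance is empty")
        if self.attended_object not in self.visible_objects:
            raise CorpusError(
                f"situation {self.index}: attended object "
                f"{self.attended_object!r} not among visible objects "
                f"{sorted(self.visible_objects)}"
            )
        if self.prosody is not None and len(self.prosody) != len(self.words):
            raise CorpusError(
                f"situation {self.index}: prosody length {len(self.prosody)} "
                f"!= utterance length {len(self.words)}"
            )


@dataclass
class Corpus:
    """An ordered sequence of situations plus the object inventory.

    ``object_inventory`` lists every object label occurring in any situation's
    visible set, in first-occurrence order (scan front to back, visible sets
    iterated in situation file order).
    """

    situations: list[Situation]
    object_inventory: list[str]

    def __post_init__(self) -> None:
        inventory = set(self.object_inventory)
        if len(inventory) != len(self.object_inventory):
            raise CorpusError("object inventory contains duplicates")
        for sit in self.situations:
            missing = sit.visible_objects - inventory
            if missing:
                raise CorpusError(
                    f"situation {sit.index}: objects {sorted(missing)} "
                    "missing from inventory"
                )
        for expected, sit in enumerate(self.situations, start=1):
            if sit.index != expected:
                raise CorpusError(
                    f"situation indices must be consecutive from 1; "
                    f"found {sit.index} at position {expected}"
                )

    @classmethod
    def from_situations(cls, situations: Iterable[Situation]) -> "Corpus":
        """Build a corpus, deriving the inventory in first-occurrence order."""
        situations = list(situations)
        inventory: dict[str, None] = {}
        for sit in situations:
            # frozensets have no stable order; sort within a situation so the
            # derived inventory is reproducible.
            for label in sorted(sit.visible_objects):
                inventory.setdefault(label, None)
        return cls(situations, list(inventory))

    def __len__(self) -> int:
        return len(self.situations)

    def __iter__(self):
        return iter(self.situations)

    @property
    def n_objects(self) -> int:
        return len(self.object_inventory)

    def object_index(self, label: str) -> int:
        try:
            return self.object_inventory.index(label)
        except ValueError:
            raise KeyError(f"unknown object label {label!r}") from None

    @property
    def has_prosody(self) -> bool:
        return all(s.prosody is not None for s in self.situations)


@dataclass
class Vocabulary:
    """Ordered set of distinct word tokens with 0-based column indices.

    Order equals first occurrence over the corpus scanned front to back, so
    the vocabulary grows incrementally as new words are heard.
    """

    words: list[str]
    index_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index_of = {w: i for i, w in enumerate(self.words)}
        if len(self.index_of) != len(self.words):
            raise CorpusError("vocabulary contains duplicate tokens")

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, token: str) -> bool:
        return token in self.index_of

    def __getitem__(self, token: str) -> int:
        try:
            return self.index_of[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None


def build_vocabulary(corpus: Corpus) -> Vocabulary:
    """Collect distinct utterance tokens in first-occurrence order."""
    seen: dict[str, None] = {}
    for sit in corpus:
        for token in sit.words:
            seen.setdefault(token, None)
    return Vocabulary(list(seen))


@dataclass
class GoldLexicon:
    """Reference word-object pairs against which a learned lexicon is scored."""

    pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = set(self.pairs)
        if not all(isinstance(w, str) and isinstance(o, str) for w, o in self.pairs):
            raise CorpusError("gold lexicon pairs must be (word, object) strings")

    @property
    def gold_words(self) -> list[str]:
        """Distinct words of the lexicon, sorted for reproducibility."""
        return sorted({w for w, _ in self.pairs})

    def objects_for(self, word: str) -> set[str]:
        return {o for w, o in self.pairs if w == word}

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _situation_to_record(sit: Situation) -> dict:
    record = {
        "id": sit.index,
        "utterance": list(sit.words),
        "objects": sorted(sit.visible_objects),
        "attended": sit.attended_object,
    }
    if sit.prosody is not None:
        record["prosody"] = list(sit.prosody)
    return record


def read_corpus(path: str | Path) -> Corpus:
    """Read a JSON-lines situation corpus.

    Raises :class:`CorpusError` naming the offending line on malformed input
    or invariant violations (e.g. attended object absent from the scene).
    """
    situations: list[Situation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            try:
                situations.append(
                    Situation(
                        index=int(record["id"]),
                        words=tuple(record["utterance"]),
                        visible_objects=frozenset(record["objects"]),
                        attended_object=record["attended"],
                        prosody=tuple(record["prosody"])
                        if "prosody" in record
                        else None,
                    )
                )
            except KeyError as exc:
                raise CorpusError(f"{path}:{lineno}: missing field {exc}") from exc
            except CorpusError as exc:
                raise CorpusError(f"{path}:{lineno}: {exc}") from exc
    return Corpus.from_situations(situations)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the JSON-lines dialect read by :func:`read_corpus`."""
    with open(path, "w", encoding="utf-8") as fh:
        for sit in corpus:
            fh.write(json.dumps(_situation_to_record(sit)) + "\n")


def read_gold_lexicon(path: str | Path) -> GoldLexicon:
    """Read a two-column TSV gold lexicon (word <TAB> object, no header)."""
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if len(row) != 2:
                raise CorpusError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(row)}"
                )
            pairs.add((row[0], row[1]))
    return GoldLexicon(pairs)


def write_gold_lexicon(gold: GoldLexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for word, obj in sorted(gold.pairs):
            writer.writerow([word, obj])
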