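"""Construction of cue→outcome learning events from tokenized text.

Two event streams feed the discrimination networks:

* **G2L** (grapheme-to-lexome): letter n-gram cues extracted from a word's
  (or multi-word expression's) orthography, with the unit's lexome as the
  sole outcome.  The word-boundary / space character is written ``#``, so
  cross-word n-grams such as ``k#t`` (from *kick the bucket*) arise
  naturally.
* **L2L** (lexome-to-lexome): a sliding window over the token stream; the
  center token is the outcome and the flanking tokens are the cues.  Row
  vectors of the resulting weight matrix serve as distributional semantic
  vectors.

Lexomes are opaque identifiers for locations in semantic space.  They are
not one-to-one with orthographic words: several surface expressions may
share one lexome (synonymy, idioms), and a :class:`LexomeDictionary` maps
surface sequences — including multi-word expressions — onto lexome labels.
Tokens without a dictionary entry fall back to an identity lexome equal to
the token string.
"""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "LearningEvent",
    "EventStream",
    "LexomeDictionary",
    "tokenize",
    "extract_letter_ngrams",
    "build_g2l_events",
    "build_l2l_events",
    "count_lexome_frequencies",
    "read_events",
    "write_events",
]

BOUNDARY = "#"


@dataclass(frozen=True)
class LearningEvent:
    """One training exposure: active cues, present outcomes, a repeat count.

    Cues and outcomes are *sets*: duplicates within one event collapse.
    ``count`` expresses how many identical consecutive exposures the event
    stands for (type-based training); incremental trainers expand it.
    """

    cues: frozenset[str]
    outcomes: frozenset[str]
    count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "cues", frozenset(self.cues))
        object.__setattr__(self, "outcomes", frozenset(self.outcomes))
        if not self.cues:
            raise ValueError("a learning event requires at least one cue")
        if not self.outcomes:
            raise ValueError("a learning event requires at least one outcome")
        if self.count < 1:
            raise ValueError(f"event count must be >= 1, got {self.count}")


# An event stream is any ordered sequence of events; list is the canonical
# concrete type.  Iteration order must be deterministic given the source.
EventStream = Sequence[LearningEvent]


class LexomeDictionary:
    """Maps surface token sequences (length >= 1) onto lexome identifiers.

    Multiple surface sequences may share one lexome (e.g. *pass away*,
    *kick the bucket* and *die* all pointing to the same 'dying' lexome);
    each surface sequence maps to exactly one lexome.  Lookup during
    segmentation is greedy longest-match-first.
    """

    def __init__(self, entries: Iterable[tuple[Sequence[str], str]] = ()) -> None:
        self._entries: dict[tuple[str, ...], str] = {}
        for surface, lexome in entries:
            self.add(surface, lexome)

    def add(self, surface: Sequence[str], lexome: str) -> None:
        if isinstance(surface, str):
            surface = tuple(surface.split())
        key = tuple(surface)
        if not key:
            raise ValueError("surface sequence must contain at least one token")
        if key in self._entries and self._entries[key] != lexome:
            raise ValueError(
                f"surface {' '.join(key)!r} already maps to {self._entries[key]!r}"
            )
        self._entries[key] = lexome

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, surface: Sequence[str]) -> bool:
        if isinstance(surface, str):
            surface = tuple(surface.split())
        return tuple(surface) in self._entries

    def max_length(self) -> int:
        """Longest surface sequence in the dictionary (0 when empty)."""
        return max((len(k) for k in self._entries), default=0)

    def match_at(self, tokens: Sequence[str], start: int) -> tuple[int, str] | None:
        """Longest dictionary match beginning at ``tokens[start]``.

        Returns ``(length, lexome)`` for the longest matching surface
        sequence, or None when no entry matches.
        """
        limit = min(self.max_length(), len(tokens) - start)
        for length in range(limit, 0, -1):
            key = tuple(tokens[start : start + length])
            lexome = self._entries.get(key)
            if lexome is not None:
                return length, lexome
        return None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LexomeDictionary":
        """Read a two-column TSV with header ``surface<TAB>lexome``."""
        d = cls()
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["surface", "lexome"]:
                raise ValueError(f"expected header 'surface\\tlexome', got {header}")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                surface, lexome = line.split("\t")[:2]
                d.add(tuple(surface.split()), lexome)
        return d

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("surface\tlexome\n")
            for surface, lexome in sorted(self._entries.items()):
                fh.write(f"{' '.join(surface)}\t{lexome}\n")


def tokenize(text: str) -> list[str]:
    """Whitespace-split, lowercase, strip punctuation at token edges.

    Tokens that are pure punctuation vanish.
    """
    out = []
    for raw in text.lower().split():
        tok = raw.strip(string.punctuation)
        if tok:
            out.append(tok)
    return out


def extract_letter_ngrams(
    form: str, n: int = 3, *, boundaries: bool = True
) -> list[str]:
    """All contiguous letter ``n``-grams of a word or phrase, left to right.

    With ``boundaries`` (the default) the form is wrapped in ``#`` and
    internal spaces become ``#``, so *corner* yields ``#co ... er#`` and a
    phrase like *pass away* yields cross-word cues such as ``s#a``.
    Without boundaries only the raw letter windows are returned (the
    convention of the worked five-word bigram example).

    Parameters
    ----------
    form:
        Word or space-separated phrase; must be nonempty after trimming.
    n:
        Window width, at least 2.
    """
    form = form.strip()
    if not form:
        raise ValueError("cannot extract n-grams from an empty form")
    if n < 2:
        raise ValueError(f"n-gram width must be >= 2, got {n}")
    joined = form.replace(" ", BOUNDARY)
    if boundaries:
        joined = f"{BOUNDARY}{joined}{BOUNDARY}"
    if len(joined) < n:
        # padding guarantees at least one window for boundary-marked forms;
        # a boundary-free form shorter than n has none
        return []
    return [joined[i : i + n] for i in range(len(joined) - n + 1)]


def build_g2l_events(
    tokens: Sequence[str],
    dictionary: LexomeDictionary | None = None,
    n: int = 3,
    *,
    boundaries: bool = True,
) -> list[LearningEvent]:
    """Segment a token stream into grapheme-to-lexome learning events.

    The stream is segmented greedily by longest dictionary match; each
    matched unit yields one event whose cues are the unit's letter n-grams
    (cross-word n-grams included for multi-word units) and whose single
    outcome is the matched lexome.  Tokens with no dictionary entry map to
    an identity lexome equal to the token string.
    """
    if not tokens:
        raise ValueError("token sequence must be nonempty")
    if dictionary is None:
        dictionary = LexomeDictionary()
    events: list[LearningEvent] = []
    i = 0
    while i < len(tokens):
        match = dictionary.match_at(tokens, i)
        if match is not None:
            length, lexome = match
            surface = " ".join(tokens[i : i + length])
        else:
            length, lexome = 1, tokens[i]
            surface = tokens[i]
        cues = extract_letter_ngrams(surface, n, boundaries=boundaries)
        events.append(LearningEvent(frozenset(cues), frozenset({lexome})))
        i += length
    return events


def build_l2l_events(
    tokens: Sequence[str], window: int = 3
) -> list[LearningEvent]:
    """Slide a window over tokens; center is the outcome, flanks are cues.

    One event per window position, stepping by one token.  At the sequence
    edges truncated windows are emitted as long as at least one flanking
    cue exists; a single-token sequence therefore yields an empty stream.
    Window events never cross the boundary of the token sequence passed in,
    so callers segment their corpus into documents beforehand.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    half = window // 2
    events: list[LearningEvent] = []
    for center in range(len(tokens)):
        lo = max(0, center - half)
        hi = min(len(tokens), center + half + 1)
        cues = frozenset(tokens[lo:center]) | frozenset(tokens[center + 1 : hi])
        if not cues:
            continue
        events.append(LearningEvent(cues, frozenset({tokens[center]})))
    return events


def count_lexome_frequencies(stream: EventStream) -> dict[str, int]:
    """Occurrence count per outcome lexome, weighted by event counts."""
    counts: Counter[str] = Counter()
    for event in stream:
        for outcome in event.outcomes:
            counts[outcome] += event.count
    return dict(counts)


def write_events(stream: EventStream, path: str | Path) -> None:
    """Write a tab-separated event file.

    Columns ``cues`` and ``outcomes`` hold '_'-joined elements; a third
    integer column ``frequency`` is emitted when any event count exceeds 1.
    """
    with_counts = any(e.count != 1 for e in stream)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cues\toutcomes\tfrequency\n" if with_counts else "cues\toutcomes\n")
        for e in stream:
            cues = "_".join(sorted(e.cues))
            outs = "_".join(sorted(e.outcomes))
            if with_counts:
                fh.write(f"{cues}\t{outs}\t{e.count}\n")
            else:
                fh.write(f"{cues}\t{outs}\n")


def read_events(path: str | Path) -> list[LearningEvent]:
    """Read a tab-separated event file written by :func:`write_events`."""
    events: list[LearningEvent] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["cues", "outcomes"]:
            raise ValueError(f"expected columns 'cues', 'outcomes'; got {header}")
        has_freq = len(header) > 2 and header[2] == "frequency"
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            count = int(parts[2]) if has_freq and len(parts) > 2 else 1
            events.append(
                LearningEvent(
                    frozenset(parts[0].split("_")),
                    frozenset(parts[1].split("_")),
                    count,
                )
            )
    return events
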