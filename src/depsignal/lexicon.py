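"""Keyword lexicon with LIWC-style prefix wildcards, and tweet matching.

Patterns come in two flavours, following the LIWC convention:

* literal  -- matches a token by exact, whole-token equality.  Inflections
  are enumerated separately in the source list ("lose", "loses", "losing"),
  which is why literals never match substrings.
* wildcard -- written ``stem*``; matches any token that starts with the
  stem ("jitter*" matches "jittery", "jitters", ...).

All matching is over normalized lowercase tokens (see
:func:`depsignal.features.tokenize`), so creative spellings and missing
spaces ("sodepressed") are not matched; that is a documented limitation of
whole-token semantics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "KeywordPattern",
    "LexiconEntry",
    "Lexicon",
    "KeywordHit",
    "LexiconParseError",
    "load_lexicon",
    "match_token",
    "find_hits",
    "packaged_lexicon_path",
]


class LexiconParseError(ValueError):
    """A malformed lexicon row; the message names the offending line."""


@dataclass(frozen=True, order=True)
class KeywordPattern:
    """A literal token or prefix-wildcard keyword pattern."""

    stem: str
    wildcard: bool = False

    def __post_init__(self) -> None:
        if not self.stem:
            raise ValueError("pattern stem must be non-empty")
        if "*" in self.stem:
            raise ValueError(f"pattern stem may not contain '*': {self.stem!r}")
        if any(ch.isspace() for ch in self.stem):
            raise ValueError(f"pattern stem may not contain whitespace: {self.stem!r}")
        if self.stem != self.stem.lower():
            raise ValueError(f"pattern stem must be lowercase: {self.stem!r}")

    def render(self) -> str:
        """Reproduce the printed form (stem plus trailing ``*`` if wildcard)."""
        return self.stem + "*" if self.wildcard else self.stem

    def matches(self, token: str) -> bool:
        """Whole-token match against a normalized lowercase token."""
        if self.wildcard:
            return token.startswith(self.stem)
        return token == self.stem

    @classmethod
    def parse(cls, text: str) -> "KeywordPattern":
        """Parse a printed pattern; a single terminal ``*`` marks a wildcard."""
        if text.endswith("*"):
            return cls(stem=text[:-1], wildcard=True)
        return cls(stem=text, wildcard=False)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.render()


@dataclass(frozen=True)
class LexiconEntry:
    """One lexicon row: the block it was listed under, and its pattern."""

    block: str
    pattern: KeywordPattern


class Lexicon:
    """Ordered list of (block, pattern) entries.

    ``len(lexicon)`` counts rows including cross-block duplicates (the
    packaged list has 110 rows); :meth:`unique_patterns` reports the
    deduplicated patterns (109 for the packaged list, because ``neglect*``
    is listed under two blocks).  Duplicate patterns *within* one block are
    rejected at construction.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.entries: list[LexiconEntry] = list(entries)
        seen: set[tuple[str, KeywordPattern]] = set()
        for e in self.entries:
            key = (e.block, e.pattern)
            if key in seen:
                raise ValueError(
                    f"duplicate pattern {e.pattern.render()!r} within block {e.block!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries)

    def unique_patterns(self) -> list[KeywordPattern]:
        """Distinct patterns in first-appearance order."""
        out: list[KeywordPattern] = []
        seen: set[KeywordPattern] = set()
        for e in self.entries:
            if e.pattern not in seen:
                seen.add(e.pattern)
                out.append(e.pattern)
        return out

    def pattern_by_rendered(self, rendered: str) -> KeywordPattern:
        """Look up a unique pattern by its printed form (e.g. ``"jitter*"``)."""
        wanted = KeywordPattern.parse(rendered)
        for p in self.unique_patterns():
            if p == wanted:
                return p
        raise KeyError(f"pattern not in lexicon: {rendered!r}")

    def matching_patterns(self, token: str) -> list[KeywordPattern]:
        """All unique patterns that match a normalized token."""
        return [p for p in self.unique_patterns() if p.matches(token)]

    def render(self) -> str:
        """Serialize back to the TSV form (block<TAB>pattern per line)."""
        return "\n".join(f"{e.block}\t{e.pattern.render()}" for e in self.entries) + (
            "\n" if self.entries else ""
        )


def packaged_lexicon_path() -> Path:
    """Filesystem path of the packaged 110-keyword lexicon."""
    return Path(str(resources.files("depsignal").joinpath("data/liwc_sad_lexicon.tsv")))


def load_lexicon(
    path: str | Path | None = None, *, assume_divorc_wildcard: bool = False
) -> Lexicon:
    """Load a lexicon from a two-column TSV (block_label<TAB>pattern).

    ``#`` comment lines and blank lines are skipped.  With ``path=None`` the
    packaged keyword list is loaded.  ``assume_divorc_wildcard`` optionally
    treats the source list's bare ``divorc`` entry as ``divorc*`` instead of
    preserving it verbatim as a (never-matching) literal.

    Raises :class:`LexiconParseError` naming the line for malformed rows:
    a missing column, whitespace inside a pattern, or an internal ``*``.
    """
    if path is None:
        path = packaged_lexicon_path()
    path = Path(path)
    entries: list[LexiconEntry] = []
    with path.open(encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if len(row) != 2:
                raise LexiconParseError(f"{path.name}:{lineno}: expected 2 columns, got {len(row)}")
            block, raw = row[0].strip(), row[1].strip()
            if not block or not raw:
                raise LexiconParseError(f"{path.name}:{lineno}: empty column")
            if "*" in raw[:-1]:
                raise LexiconParseError(
                    f"{path.name}:{lineno}: internal wildcard in pattern {raw!r}"
                )
            if any(ch.isspace() for ch in raw):
                raise LexiconParseError(
                    f"{path.name}:{lineno}: whitespace inside pattern {raw!r}"
                )
            if assume_divorc_wildcard and raw == "divorc":
                raw = "divorc*"
            try:
                pattern = KeywordPattern.parse(raw.lower())
            except ValueError as exc:
                raise LexiconParseError(f"{path.name}:{lineno}: {exc}") from exc
            entries.append(LexiconEntry(block=block, pattern=pattern))
    return Lexicon(entries)


def match_token(pattern: KeywordPattern, token: str) -> bool:
    """Whether a pattern matches one normalized lowercase token."""
    return pattern.matches(token)


@dataclass(frozen=True)
class KeywordHit:
    """One (tweet, pattern, token position) retrieval event."""

    tweet_id: str
    pattern: KeywordPattern
    token: str
    token_index: int


def find_hits(tweet, lexicon: Lexicon, tokens: list[str] | None = None) -> list[KeywordHit]:
    """All per-token lexicon matches in one tweet.

    Hits are reported per token position (a repeated token yields repeated
    hits); callers that count *tweet hits* deduplicate per (tweet, pattern),
    see :func:`depsignal.precision.keyword_precision`.
    """
    from .features import tokenize  # local import: features also imports lexicon types

    if tokens is None:
        tokens = tokenize(tweet.text)
    hits: list[KeywordHit] = []
    unique = lexicon.unique_patterns()
    for idx, token in enumerate(tokens):
        for pattern in unique:
            if pattern.matches(token):
                hits.append(
                    KeywordHit(tweet_id=tweet.tweet_id, pattern=pattern, token=token, token_index=idx)
                )
    return hits
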