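"""Letter-string normalization and open-bigram extraction.

An *open bigram* is an ordered pair of letters drawn from a string, either
contiguous or separated by intervening letters.  A word is coded as an
unordered set of such pairs; extraction is governed by a
:class:`CodingPolicy` (maximum gap, optional word-boundary markers,
per-gap weights, positional noise width).

Conventions
-----------
* Letter positions are 1-based.
* Bigram identity is the ordered letter pair only.  The gap at which a pair
  occurred is provenance: when the same pair occurs at several gaps the
  entry keeps the most favorable (maximum) weight.
* Boundary markers use ``#`` and are off by default.
"""

from __future__ import annotations

import dataclasses
import string as _string
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "EDGE_MARKER",
    "ValidationError",
    "LetterString",
    "OpenBigram",
    "CodingPolicy",
    "BigramCode",
    "normalize_string",
    "extract_open_bigrams",
    "count_open_bigrams",
]

EDGE_MARKER = "#"

_LETTERS = frozenset(_string.ascii_uppercase)


class ValidationError(ValueError):
    """Raised when an input string or policy violates its contract."""


@dataclass(frozen=True)
class LetterString:
    """A normalized word: uppercase letters A-Z, positions 1..n."""

    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValidationError("letter string must be non-empty")
        for pos, ch in enumerate(self.text, start=1):
            if ch not in _LETTERS:
                raise ValidationError(
                    f"non-alphabetic character {ch!r} at position {pos}"
                )

    @property
    def n(self) -> int:
        return len(self.text)

    @property
    def has_repeats(self) -> bool:
        """Whether any letter occurs more than once."""
        return len(set(self.text)) < len(self.text)

    def letter(self, i: int) -> str:
        """Letter at 1-based position ``i``."""
        if not 1 <= i <= self.n:
            raise ValidationError(f"position {i} out of range 1..{self.n}")
        return self.text[i - 1]

    def reversed(self) -> "LetterString":
        return LetterString(self.text[::-1])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


@dataclass(frozen=True)
class OpenBigram:
    """An ordered letter pair.

    ``gap`` (intervening letters in the source string) and ``edge`` (whether
    one member is the boundary marker) are provenance only: equality and
    hashing use the letter pair alone, giving set semantics in which the
    same pair occurring at different gaps collapses to one entry.
    """

    first: str
    second: str
    gap: int = field(default=0, compare=False)
    edge: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValidationError("gap must be >= 0")

    @property
    def pair(self) -> str:
        return self.first + self.second

    def reversed(self) -> "OpenBigram":
        return OpenBigram(self.second, self.first, self.gap, self.edge)

    def __repr__(self) -> str:
        return f"OpenBigram({self.pair})"


@dataclass(frozen=True)
class CodingPolicy:
    """Parameters controlling open-bigram extraction and matching.

    Parameters
    ----------
    max_gap:
        Maximum number of intervening letters allowed between the two
        members of a bigram; ``None`` means unbounded.
    include_edges:
        Whether boundary bigrams (``#C``, ``A#``) are extracted; their
        weight is 1.0.
    gap_weights:
        Optional map gap -> weight in [0, 1].  When absent, every allowed
        gap has weight 1 (binary coding).  Gaps not in the map, or beyond
        ``max_gap``, have weight 0.
    noise_sd:
        Positional noise width in letter-position units; 0 means noiseless.
    """

    max_gap: int | None = None
    include_edges: bool = False
    gap_weights: Mapping[int, float] | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.max_gap is not None and self.max_gap < 0:
            raise ValidationError("max_gap must be >= 0 or None")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.gap_weights is not None:
            gw = dict(self.gap_weights)
            for g, w in gw.items():
                if g < 0:
                    raise ValidationError("gap_weights keys must be >= 0")
                if not 0.0 <= w <= 1.0:
                    raise ValidationError("gap weights must lie in [0, 1]")
                if self.max_gap is not None and g > self.max_gap and w != 0.0:
                    raise ValidationError(
                        f"gap {g} exceeds max_gap {self.max_gap} but has "
                        f"nonzero weight {w}"
                    )
            object.__setattr__(self, "gap_weights", gw)

    @classmethod
    def binary(cls, max_gap: int | None = None, include_edges: bool = False) -> "CodingPolicy":
        """Presence/absence coding: every allowed gap weighs 1."""
        return cls(max_gap=max_gap, include_edges=include_edges)

    @classmethod
    def seriol(cls, include_edges: bool = False, noise_sd: float = 0.0) -> "CodingPolicy":
        """Distance-weighted coding: 1.0 / 0.8 / 0.4 for gaps 0 / 1 / 2, else 0."""
        return cls(
            max_gap=2,
            include_edges=include_edges,
            gap_weights={0: 1.0, 1: 0.8, 2: 0.4},
            noise_sd=noise_sd,
        )

    def with_noise(self, noise_sd: float) -> "CodingPolicy":
        return dataclasses.replace(self, noise_sd=noise_sd)

    def gap_allowed(self, gap: int) -> bool:
        return self.max_gap is None or gap <= self.max_gap

    def weight(self, gap: int) -> float:
        """Weight of a bigram whose members are ``gap`` letters apart."""
        if not self.gap_allowed(gap):
            return 0.0
        if self.gap_weights is None:
            return 1.0
        return self.gap_weights.get(gap, 0.0)


@dataclass(frozen=True)
class BigramCode:
    """The weighted set of open bigrams extracted from one string."""

    source: LetterString
    policy: CodingPolicy
    entries: Mapping[OpenBigram, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        if any(w == 0.0 for w in self.entries.values()):
            raise ValidationError("zero-weight entries must be dropped")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, bigram: OpenBigram) -> bool:
        return bigram in self.entries

    def pairs(self) -> frozenset[OpenBigram]:
        return frozenset(self.entries)

    def weight_of(self, bigram: OpenBigram) -> float:
        return self.entries.get(bigram, 0.0)

    @property
    def total_weight(self) -> float:
        return sum(self.entries.values())


def normalize_string(text: str) -> LetterString:
    """Case-fold raw text to an uppercase :class:`LetterString`.

    Raises :class:`ValidationError` naming the 1-based position of the
    first non-alphabetic character.
    """
    stripped = text.strip()
    if not stripped:
        raise ValidationError("empty string after stripping whitespace")
    return LetterString(stripped.upper())


def extract_open_bigrams(s: LetterString, policy: CodingPolicy) -> BigramCode:
    """All ordered letter pairs (i < j) of ``s`` allowed by ``policy``.

    Repeated pairs collapse to a single entry carrying the maximum weight
    over occurrences (the most favorable gap).  Edge bigrams, when enabled,
    pair the boundary marker with the first and last letter at weight 1.
    """
    entries: dict[OpenBigram, float] = {}

    def add(bigram: OpenBigram, weight: float) -> None:
        if weight <= 0.0:
            return
        prev = entries.get(bigram)
        if prev is None or weight > prev:
            entries[bigram] = weight

    text = s.text
    for i in range(s.n - 1):
        for j in range(i + 1, s.n):
            gap = j - i - 1
            if not policy.gap_allowed(gap):
                break  # larger j only increases the gap
            add(OpenBigram(text[i], text[j], gap=gap), policy.weight(gap))
    if policy.include_edges:
        add(OpenBigram(EDGE_MARKER, text[0], gap=0, edge=True), 1.0)
        add(OpenBigram(text[-1], EDGE_MARKER, gap=0, edge=True), 1.0)
    return BigramCode(source=s, policy=policy, entries=entries)


def count_open_bigrams(n: int, policy: CodingPolicy) -> int:
    """Closed-form bigram count for a length-``n`` string with no repeated
    letters: sum over distances d = 1..min(max_gap + 1, n - 1) of (n - d),
    plus 2 when edge bigrams are enabled."""
    if n < 1:
        raise ValidationError("length must be >= 1")
    d_max = n - 1 if policy.max_gap is None else min(policy.max_gap + 1, n - 1)
    count = sum(n - d for d in range(1, d_max + 1))
    if policy.include_edges:
        count += 2
    return count
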