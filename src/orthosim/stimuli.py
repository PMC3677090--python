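"""Construction of masked-priming primes from target words.

Prime kinds
-----------
identity
    The target itself, lowercase.
TL (transposed letter)
    Two adjacent letters swapped.
SL (substituted letter)
    One or more letters replaced by letters absent from the word.
bigram
    A two-letter prime taken from word-internal positions, optionally
    reversed; labelled 0L / 1L / 3L by the number of intervening letters.
ALD (all letters different)
    A prime sharing no letters with the target.

Primes are emitted lowercase and targets uppercase, mirroring the
cross-case convention of the same-different task.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .orthography import LetterString, ValidationError, normalize_string

__all__ = [
    "PrimeSpec",
    "GAP_LABELS",
    "make_identity_prime",
    "make_tl_prime",
    "make_sl_prime",
    "make_bigram_prime",
    "make_ald_prime",
    "build_condition_set",
]

# gap label -> number of intervening letters between the bigram's members
GAP_LABELS = {"0L": 0, "1L": 1, "3L": 3}


@dataclass(frozen=True)
class PrimeSpec:
    """A bigram-prime recipe: which internal positions to take, whether to
    reverse them, and the gap label the pair must realize."""

    positions: tuple[int, int]
    reversed: bool = False
    gap_label: str | None = None

    def __post_init__(self) -> None:
        i, j = self.positions
        if i >= j:
            raise ValidationError("positions must be increasing")
        if self.gap_label is not None:
            if self.gap_label not in GAP_LABELS:
                raise ValidationError(
                    f"unknown gap label {self.gap_label!r}; "
                    f"expected one of {sorted(GAP_LABELS)}"
                )
            expected_gap = GAP_LABELS[self.gap_label]
            if j - i - 1 != expected_gap:
                raise ValidationError(
                    f"positions {self.positions} span {j - i - 1} letters "
                    f"but label {self.gap_label} requires {expected_gap}"
                )

    @property
    def condition(self) -> str:
        label = self.gap_label or f"{self.positions[1] - self.positions[0] - 1}L"
        return f"rev{label}" if self.reversed else label


def make_identity_prime(word: LetterString) -> str:
    return word.text.lower()


def make_tl_prime(word: LetterString, i: int) -> str:
    """Transpose the adjacent letters at positions ``i`` and ``i + 1``."""
    if not 1 <= i < word.n:
        raise ValidationError(
            f"transposition position {i} out of range 1..{word.n - 1}"
        )
    chars = list(word.text)
    chars[i - 1], chars[i] = chars[i], chars[i - 1]
    return "".join(chars).lower()


def make_sl_prime(
    word: LetterString, positions: Sequence[int], replacements: Sequence[str]
) -> str:
    """Substitute the letters at ``positions`` with ``replacements``, which
    must not already occur in the word."""
    if len(positions) != len(replacements):
        raise ValidationError("positions and replacements must align")
    chars = list(word.text)
    for pos, rep in zip(positions, replacements):
        if not 1 <= pos <= word.n:
            raise ValidationError(f"position {pos} out of range 1..{word.n}")
        rep_u = rep.upper()
        if len(rep_u) != 1 or not rep_u.isalpha():
            raise ValidationError(f"replacement {rep!r} must be a single letter")
        if rep_u in word.text:
            raise ValidationError(
                f"replacement letter {rep_u!r} already occurs in {word.text!r}"
            )
        chars[pos - 1] = rep_u
    return "".join(chars).lower()


def make_bigram_prime(word: LetterString, spec: PrimeSpec) -> str:
    """Two-letter prime from the word-internal positions of ``spec``,
    reversed when flagged."""
    i, j = spec.positions
    if word.n < 4:
        raise ValidationError(
            "bigram primes need words of length >= 4 to have two internal letters"
        )
    for pos in (i, j):
        if pos in (1, word.n):
            raise ValidationError(
                f"position {pos} is an edge position; bigram primes are word-internal"
            )
        if not 1 < pos < word.n:
            raise ValidationError(f"position {pos} out of range 2..{word.n - 1}")
    pair = word.letter(i) + word.letter(j)
    if spec.reversed:
        pair = pair[::-1]
    return pair.lower()


def make_ald_prime(word: LetterString, candidate: str) -> str:
    """Validate that ``candidate`` shares no letters with ``word`` and
    return it lowercase.  The candidate may be an arbitrary letter string
    or a prime donated by another item."""
    cand = normalize_string(candidate)
    overlap = sorted(set(cand.text) & set(word.text))
    if overlap:
        raise ValidationError(
            f"candidate {candidate!r} shares letters {overlap} with {word.text!r}"
        )
    return cand.text.lower()


def build_condition_set(
    word: LetterString,
    conditions: Iterable[str],
    ald_candidate: str | None = None,
    tl_position: int | None = None,
) -> dict[str, str]:
    """Build the primes for the requested condition labels.

    Supported labels: ``identity``, ``TL``, ``ALD``, and bigram labels
    ``0L``/``1L``/``3L`` with optional ``rev`` prefix.  Bigram conditions
    use positions (2, 3), (2, 4) and (2, 6).  The TL transposition defaults
    to the first two letters for words up to three letters, otherwise to
    the word-internal positions (3, 4).
    """
    bigram_positions = {"0L": (2, 3), "1L": (2, 4), "3L": (2, 6)}
    primes: dict[str, str] = {}
    for cond in conditions:
        if cond == "identity":
            primes[cond] = make_identity_prime(word)
        elif cond == "TL":
            i = tl_position if tl_position is not None else (1 if word.n <= 3 else 3)
            primes[cond] = make_tl_prime(word, i)
        elif cond == "ALD":
            if ald_candidate is None:
                raise ValidationError("ALD condition needs a candidate prime")
            primes[cond] = make_ald_prime(word, ald_candidate)
        else:
            rev = cond.startswith("rev")
            label = cond[3:] if rev else cond
            if label not in bigram_positions:
                raise ValidationError(f"unknown condition {cond!r}")
            spec = PrimeSpec(
                positions=bigram_positions[label], reversed=rev, gap_label=label
            )
            primes[cond] = make_bigram_prime(word, spec)
    return primes
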