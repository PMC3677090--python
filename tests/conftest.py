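import itertools
import random

import pytest
from hypothesis import HealthCheck, settings

from orthosim.orthography import CodingPolicy, LetterString

settings.register_profile(
    "default", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")

ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def random_no_repeat_word(rng: random.Random, length: int) -> LetterString:
    return LetterString("".join(rng.sample(ALPHABET, length)))


def brute_force_pairs(text: str, max_gap: int | None) -> set[tuple[str, str]]:
    """Independent oracle: enumerate all ordered letter pairs (i < j) whose
    gap is allowed, as a plain set of tuples."""
    pairs = set()
    for i, j in itertools.combinations(range(len(text)), 2):
        gap = j - i - 1
        if max_gap is None or gap <= max_gap:
            pairs.add((text[i], text[j]))
    return pairs


@pytest.fixture
def unbounded() -> CodingPolicy:
    return CodingPolicy.binary()


@pytest.fixture
def span2() -> CodingPolicy:
    return CodingPolicy.binary(max_gap=2)


@pytest.fixture
def seriol() -> CodingPolicy:
    return CodingPolicy.seriol()


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20130803)
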