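"""Prime-target match scores under competing letter-order coding schemes.

Every scorer returns a :class:`MatchResult` with a similarity score in
[0, 1].  Scores are normalized by the *target's* code (count or weight
sum), so a prime whose code contains the full target code scores exactly
1.0 even when the prime is longer.

Models
------
``binary_ob_match``
    Shared open bigrams divided by the target's bigram count.
``weighted_ob_match``
    Distance-weighted overlap (e.g. 1.0 / 0.8 / 0.4 gap weights).
``noisy_ob_match``
    Letter positions carry Gaussian noise; reversed pairs gain a little
    activation, so strict order is no longer all-or-none.
``slot_coding_match``
    Left-aligned per-position letter identity.
``gradient_match``
    Simplified spatial-gradient coder: geometric activation decay over
    positions, overlap of shared letters' activations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .orthography import (
    EDGE_MARKER,
    BigramCode,
    CodingPolicy,
    LetterString,
    OpenBigram,
    ValidationError,
    extract_open_bigrams,
)

__all__ = [
    "MatchResult",
    "UndefinedScoreError",
    "binary_ob_match",
    "weighted_ob_match",
    "noisy_ob_match",
    "noisy_bigram_code",
    "slot_coding_match",
    "gradient_match",
    "calibrate_noise",
    "CalibrationResult",
    "DEFAULT_NOISE_SD",
    "DEFAULT_GRADIENT_DECAY",
    "MODEL_NAMES",
]

DEFAULT_NOISE_SD = 0.5
DEFAULT_GRADIENT_DECAY = 0.7

MODEL_NAMES = ("binary", "weighted", "noisy", "slot", "gradient")


class UndefinedScoreError(ValidationError):
    """The target's code is empty, so no normalized score exists."""


@dataclass(frozen=True)
class MatchResult:
    """Outcome of scoring one prime against one target."""

    shared: frozenset[OpenBigram]
    score: float
    model: str
    policy: CodingPolicy | None = None

    def __post_init__(self) -> None:
        if not -1e-12 <= self.score <= 1.0 + 1e-12:
            raise ValidationError(f"score {self.score} outside [0, 1]")
        object.__setattr__(self, "score", min(1.0, max(0.0, self.score)))


def binary_ob_match(
    prime: LetterString, target: LetterString, policy: CodingPolicy
) -> MatchResult:
    """Shared open bigrams over the target's bigram count."""
    prime_code = extract_open_bigrams(prime, policy)
    target_code = extract_open_bigrams(target, policy)
    if len(target_code) == 0:
        raise UndefinedScoreError(
            f"target {target.text!r} has no open bigrams under this policy"
        )
    shared = prime_code.pairs() & target_code.pairs()
    return MatchResult(
        shared=frozenset(shared),
        score=len(shared) / len(target_code),
        model="binary",
        policy=policy,
    )


def weighted_ob_match(
    prime: LetterString, target: LetterString, policy: CodingPolicy | None = None
) -> MatchResult:
    """Weighted overlap: sum over shared pairs of min(prime weight, target
    weight), over the target's total weight.  Defaults to the SERIOL gap
    weights when no policy is given.

    The min combination (rather than crediting the full target weight)
    keeps this the exact noiseless limit of :func:`noisy_ob_match`; the two
    rules only differ when a pair occurs at a more favorable gap in the
    target than in the prime.
    """
    if policy is None:
        policy = CodingPolicy.seriol()
    prime_code = extract_open_bigrams(prime, policy)
    target_code = extract_open_bigrams(target, policy)
    denom = target_code.total_weight
    if denom == 0.0:
        raise UndefinedScoreError(
            f"target {target.text!r} has zero total bigram weight"
        )
    shared = prime_code.pairs() & target_code.pairs()
    num = sum(min(prime_code.weight_of(b), target_code.weight_of(b)) for b in shared)
    return MatchResult(
        shared=frozenset(shared), score=num / denom, model="weighted", policy=policy
    )


def _pair_activations(s: LetterString, policy: CodingPolicy) -> dict[OpenBigram, float]:
    """Activation of every ordered letter pair under positional noise.

    Each letter's perceived position is Gaussian with mean at its index and
    SD ``policy.noise_sd``; the activation of the ordered pair (a, b) taken
    from positions i < j is P(perceived a < perceived b) x gap weight, and
    the reversed pair (b, a) gets the complementary probability times the
    same gap weight.  Repeated pairs keep their maximum activation.
    Boundary markers, when enabled, sit at positions 0 and n + 1.
    """
    sd = policy.noise_sd
    entries: dict[OpenBigram, float] = {}

    def add(bigram: OpenBigram, activation: float) -> None:
        if activation <= 0.0:
            return
        prev = entries.get(bigram)
        if prev is None or activation > prev:
            entries[bigram] = activation

    positions = list(enumerate(s.text, start=1))
    if policy.include_edges:
        positions = [(0, EDGE_MARKER)] + positions + [(s.n + 1, EDGE_MARKER)]
    for a_idx in range(len(positions) - 1):
        for b_idx in range(a_idx + 1, len(positions)):
            i, a = positions[a_idx]
            j, b = positions[b_idx]
            if a == EDGE_MARKER and b == EDGE_MARKER:
                continue
            gap = j - i - 1
            edge = a == EDGE_MARKER or b == EDGE_MARKER
            w = 1.0 if edge else policy.weight(gap)
            if w == 0.0:
                continue
            # P(pos_a < pos_b) for independent Gaussians centered i < j
            p_forward = norm.cdf((j - i) / (sd * math.sqrt(2.0))) if sd > 0 else 1.0
            add(OpenBigram(a, b, gap=gap, edge=edge), w * p_forward)
            add(OpenBigram(b, a, gap=gap, edge=edge), w * (1.0 - p_forward))
    return entries


def noisy_bigram_code(s: LetterString, policy: CodingPolicy) -> BigramCode:
    """Open-bigram code under Gaussian positional noise (see
    :func:`noisy_ob_match`)."""
    return BigramCode(source=s, policy=policy, entries=_pair_activations(s, policy))


def noisy_ob_match(
    prime: LetterString, target: LetterString, policy: CodingPolicy
) -> MatchResult:
    """Weighted overlap of noisy bigram activations.

    Match = sum over shared pairs of min(prime activation, target
    activation), divided by the target's total activation.  With
    ``noise_sd = 0`` this reduces exactly to :func:`weighted_ob_match`.
    """
    prime_entries = _pair_activations(prime, policy)
    target_entries = _pair_activations(target, policy)
    denom = sum(target_entries.values())
    if denom == 0.0:
        raise UndefinedScoreError(
            f"target {target.text!r} has zero total bigram activation"
        )
    shared = set(prime_entries) & set(target_entries)
    num = sum(min(prime_entries[b], target_entries[b]) for b in shared)
    return MatchResult(
        shared=frozenset(shared), score=num / denom, model="noisy", policy=policy
    )


def slot_coding_match(prime: LetterString, target: LetterString) -> MatchResult:
    """Absolute-position coding: identical letters in identical slots,
    strings compared left-aligned, normalized by target length."""
    same = sum(
        1 for p, t in zip(prime.text, target.text) if p == t
    )
    return MatchResult(
        shared=frozenset(), score=same / target.n, model="slot", policy=None
    )


def _gradient_activations(s: LetterString, decay: float) -> dict[str, float]:
    """Per-letter activation decaying geometrically with position; a
    repeated letter keeps its earliest (strongest) activation."""
    acts: dict[str, float] = {}
    for pos, ch in enumerate(s.text):
        acts.setdefault(ch, decay**pos)
    return acts


def gradient_match(
    prime: LetterString,
    target: LetterString,
    decay: float = DEFAULT_GRADIENT_DECAY,
) -> MatchResult:
    """Simplified spatial-gradient similarity.

    Both strings map to per-letter activations decreasing geometrically
    with position.  Each target position whose letter also appears in the
    prime contributes min(prime activation, target activation); letters
    absent from the prime contribute 0.  Normalized by the target's total
    activation, so identity scores 1 and letter-disjoint pairs score 0.
    """
    if not 0.0 < decay < 1.0:
        raise ValidationError("decay must lie in (0, 1)")
    prime_acts = _gradient_activations(prime, decay)
    num = 0.0
    denom = 0.0
    for pos, ch in enumerate(target.text):
        t_act = decay**pos
        denom += t_act
        p_act = prime_acts.get(ch)
        if p_act is not None:
            num += min(p_act, t_act)
    return MatchResult(
        shared=frozenset(), score=num / denom, model="gradient", policy=None
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Least-squares noise-width estimate against published match scores."""

    noise_sd: float
    residuals: tuple[float, ...]
    sse: float
    converged: bool
    message: str = ""


def calibrate_noise(
    target_scores: Sequence[tuple[LetterString, LetterString, float]],
    policy: CodingPolicy,
    bounds: tuple[float, float] = (1e-3, 3.0),
) -> CalibrationResult:
    """Fit the positional-noise SD to published match scores.

    One-dimensional bounded least squares of :func:`noisy_ob_match` scores
    against the published values.  Residuals (model minus published) are
    reported rather than asserting exact reproduction, because published
    values may come from parameterizations that are not recoverable from
    the noise width alone.
    """
    if not target_scores:
        raise ValidationError("at least one published score is required")

    def sse(sigma: float) -> float:
        pol = policy.with_noise(sigma)
        return sum(
            (noisy_ob_match(p, t, pol).score - published) ** 2
            for p, t, published in target_scores
        )

    res = minimize_scalar(sse, bounds=bounds, method="bounded")
    sigma = float(res.x)
    pol = policy.with_noise(sigma)
    residuals = tuple(
        noisy_ob_match(p, t, pol).score - published
        for p, t, published in target_scores
    )
    return CalibrationResult(
        noise_sd=sigma,
        residuals=residuals,
        sse=float(res.fun),
        converged=bool(res.success),
        message=str(getattr(res, "message", "")),
    )


def score_pair(
    prime: LetterString,
    target: LetterString,
    model: str,
    policy: CodingPolicy | None = None,
    decay: float = DEFAULT_GRADIENT_DECAY,
) -> MatchResult:
    """Dispatch to a scorer by model name (see :data:`MODEL_NAMES`)."""
    if model == "binary":
        return binary_ob_match(prime, target, policy or CodingPolicy.binary())
    if model == "weighted":
        return weighted_ob_match(prime, target, policy)
    if model == "noisy":
        pol = policy or CodingPolicy.seriol(noise_sd=DEFAULT_NOISE_SD)
        if pol.noise_sd == 0.0:
            pol = pol.with_noise(DEFAULT_NOISE_SD)
        return noisy_ob_match(prime, target, pol)
    if model == "slot":
        return slot_coding_match(prime, target)
    if model == "gradient":
        return gradient_match(prime, target, decay)
    raise ValidationError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
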