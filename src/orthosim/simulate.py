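"""Trial-level same-different RT simulation with crossed random effects.

The generator works on the inverse-RT scale (invRT = -1000/RT, so larger
means slower), where trial noise is Gaussian:

    invRT = baseline + subject effect + item effect + condition shift + noise

Condition shifts apply to Same trials only; Different-trial condition
means are equal by construction.  Requested priming effects are given in
ms as differences of *cell mean RTs*.  Because the RT mean is a convex
function of the invRT mean, a naive 1/RT conversion would inflate the
realized effect; instead each condition's invRT shift is solved
numerically (Gauss-Hermite quadrature over the marginal invRT
distribution) so that the expected cell-mean RT difference equals the
requested value and recovery is unbiased.  Raw output keeps sub-cutoff
RTs; filtering is a separate step (:func:`apply_rt_cutoff`).
"""

from __future__ import annotations

import string as _string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .orthography import ValidationError

__all__ = [
    "DesignSpec",
    "RecoveryResult",
    "simulate_experiment",
    "apply_rt_cutoff",
    "recover_effects",
    "random_lexicon",
    "DEFAULT_CUTOFF_MS",
]

DEFAULT_CUTOFF_MS = 250.0

# RTs are capped here so that extreme invRT draws cannot cross zero and
# flip sign (the task itself times out at 2000 ms).
_MAX_RT_MS = 2500.0

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(151)
_GH_NORM = float(np.sqrt(2.0 * np.pi))


def _expected_rt(mu_inv: float, sd_inv: float) -> float:
    """E[-1000 / min(X, cap)] for X ~ N(mu_inv, sd_inv^2), by Gauss-Hermite
    quadrature with the same cap used when generating trials."""
    x = mu_inv + sd_inv * _GH_NODES
    x = np.minimum(x, -1000.0 / _MAX_RT_MS)
    return float(np.sum(_GH_WEIGHTS * (-1000.0 / x)) / _GH_NORM)


@dataclass(frozen=True)
class DesignSpec:
    """Design of one simulated experiment.

    ``condition_effects`` maps condition label -> priming effect in ms on
    the mean-RT scale, relative to the control; the control's entry must
    be 0.  ``error_rates`` are per-condition Bernoulli error probabilities
    (default 5% everywhere).
    """

    n_subjects: int
    n_items: int
    condition_effects: Mapping[str, float]
    control: str = "ALD"
    baseline_rt_ms: float = 477.0
    reps: int = 1
    p_same: float = 0.5
    subject_sd: float = 0.15
    item_sd: float = 0.05
    residual_sd: float = 0.25
    error_rates: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_items < 1 or self.reps < 1:
            raise ValidationError("n_subjects, n_items and reps must be >= 1")
        if not 0.0 < self.p_same < 1.0:
            raise ValidationError("p_same must lie in (0, 1)")
        effects = dict(self.condition_effects)
        if self.control not in effects:
            raise ValidationError(
                f"control condition {self.control!r} missing from effects"
            )
        if effects[self.control] != 0.0:
            raise ValidationError("control condition must have a 0 ms effect")
        for cond, delta in effects.items():
            if self.baseline_rt_ms - delta <= 0:
                raise ValidationError(
                    f"effect {delta} ms implies nonpositive RT for {cond!r}"
                )
        if self.baseline_rt_ms <= 0:
            raise ValidationError("baseline RT must be positive")
        object.__setattr__(self, "condition_effects", effects)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.condition_effects)

    @property
    def total_inv_sd(self) -> float:
        """Marginal invRT SD across subjects, items and trials."""
        return float(
            np.sqrt(self.subject_sd**2 + self.item_sd**2 + self.residual_sd**2)
        )

    def inv_shift(self, condition: str) -> float:
        """invRT shift whose expected cell-mean RT sits ``delta`` ms below
        the control's, solved numerically against the marginal invRT
        distribution (see module docstring)."""
        delta = self.condition_effects[condition]
        if delta == 0.0:
            return 0.0
        base_inv = -1000.0 / self.baseline_rt_ms
        sd = self.total_inv_sd
        target_rt = _expected_rt(base_inv, sd) - delta
        lo = -1000.0 / max(self.baseline_rt_ms - delta, 1.0) - base_inv
        return float(
            brentq(
                lambda s: _expected_rt(base_inv + s, sd) - target_rt,
                min(2.0 * lo, -1e-9) if lo < 0 else -1e-9,
                max(2.0 * lo, 1e-9) if lo > 0 else 1e-9,
                xtol=1e-12,
            )
        )


def simulate_experiment(design: DesignSpec) -> pd.DataFrame:
    """Generate one trial per subject x item x condition x response type x
    repetition.

    Returns a data frame with columns subject, item, referent, condition,
    response, rt_ms, correct.  Fully deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n_s, n_i, reps = design.n_subjects, design.n_items, design.reps
    conds = design.conditions
    responses = ("Same", "Different")
    err = dict(design.error_rates or {})

    subj_eff = rng.normal(0.0, design.subject_sd, size=n_s)
    item_eff = rng.normal(0.0, design.item_sd, size=n_i)
    base_inv = -1000.0 / design.baseline_rt_ms

    rows = []
    for s in range(n_s):
        for it in range(n_i):
            for cond in conds:
                for resp in responses:
                    shift = design.inv_shift(cond) if resp == "Same" else 0.0
                    for rep in range(reps):
                        inv = (
                            base_inv
                            + subj_eff[s]
                            + item_eff[it]
                            + shift
                            + rng.normal(0.0, design.residual_sd)
                        )
                        inv = min(inv, -1000.0 / _MAX_RT_MS)
                        rt = -1000.0 / inv
                        p_err = err.get(cond, 0.05)
                        correct = rng.random() >= p_err
                        rows.append(
                            (
                                f"s{s + 1:03d}",
                                f"w{it + 1:03d}",
                                f"w{it + 1:03d}" if resp == "Same" else "other",
                                cond,
                                resp,
                                rt,
                                bool(correct),
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "item",
            "referent",
            "condition",
            "response",
            "rt_ms",
            "correct",
        ],
    )


def apply_rt_cutoff(
    trials: pd.DataFrame, cutoff_ms: float = DEFAULT_CUTOFF_MS
) -> tuple[pd.DataFrame, int]:
    """Drop correct Same-trial analysis rows faster than ``cutoff_ms``.

    Rows that are not part of the analysis set (Different trials, errors)
    pass through untouched.  Returns (filtered trials, number removed).
    """
    in_analysis = (
        (trials["response"] == "Same")
        & trials["correct"]
        & (trials["rt_ms"] < cutoff_ms)
    )
    n_removed = int(in_analysis.sum())
    return trials[~in_analysis].reset_index(drop=True), n_removed


@dataclass(frozen=True)
class RecoveryResult:
    """Cell means and bootstrap priming-effect estimates."""

    condition_means: dict[str, float]
    priming: dict[str, float]
    ci: dict[str, tuple[float, float]]
    n_trials: dict[str, int]
    unreliable: bool = False
    missing: tuple[str, ...] = field(default_factory=tuple)


def recover_effects(
    trials: pd.DataFrame,
    control: str = "ALD",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> RecoveryResult:
    """Condition mean RTs over correct Same trials, priming effects vs the
    control, and percentile bootstrap CIs (trials resampled within
    condition)."""
    analysis = trials[(trials["response"] == "Same") & trials["correct"]]
    conds = list(dict.fromkeys(trials["condition"]))
    if control not in conds:
        raise ValidationError(f"control condition {control!r} absent from data")
    if len(conds) < 2:
        raise ValidationError("need at least two conditions including the control")

    rng = np.random.default_rng(seed)
    missing = tuple(
        c for c in conds if analysis[analysis["condition"] == c].empty
    )
    by_cond = {
        c: analysis.loc[analysis["condition"] == c, "rt_ms"].to_numpy()
        for c in conds
        if c not in missing
    }
    means = {c: float(v.mean()) for c, v in by_cond.items()}
    n_trials = {c: int(v.size) for c, v in by_cond.items()}

    boot_means: dict[str, np.ndarray] = {}
    for c, v in by_cond.items():
        idx = rng.integers(0, v.size, size=(n_boot, v.size))
        boot_means[c] = v[idx].mean(axis=1)

    alpha = (1.0 - ci_level) / 2.0
    priming: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    if control in by_cond:
        for c in by_cond:
            if c == control:
                continue
            priming[c] = means[control] - means[c]
            boot_delta = boot_means[control] - boot_means[c]
            lo, hi = np.quantile(boot_delta, [alpha, 1.0 - alpha])
            ci[c] = (float(lo), float(hi))

    unreliable = trials["subject"].nunique() < 2
    return RecoveryResult(
        condition_means=means,
        priming=priming,
        ci=ci,
        n_trials=n_trials,
        unreliable=unreliable,
        missing=missing,
    )


def random_lexicon(
    n_words: int,
    length: int,
    no_repeats: bool = True,
    seed: int = 0,
) -> list[str]:
    """Uniformly sampled uppercase letter strings, reproducible by seed.

    With ``no_repeats`` each word's letters are distinct (length <= 26).
    Words may repeat across the list; pass a larger alphabet-use budget by
    sampling more words and deduplicating if distinct words are needed.
    """
    if n_words < 0 or length < 1:
        raise ValidationError("need n_words >= 0 and length >= 1")
    if no_repeats and length > 26:
        raise ValidationError("cannot draw more than 26 distinct letters")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(_string.ascii_uppercase))
    words = []
    for _ in range(n_words):
        if no_repeats:
            letters = rng.choice(alphabet, size=length, replace=False)
        else:
            letters = rng.choice(alphabet, size=length, replace=True)
        words.append("".join(letters))
    return words
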