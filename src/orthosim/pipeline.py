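"""Condition-level priming tables, model predictions, and falsification.

The packaged fixtures transcribe the condition-level mean RTs (ms) and
percent error rates of three masked-priming same-different experiments:

* ``exp1`` — 2- and 3-letter targets; identity / TL / ALD primes.
* ``exp2`` — 7-letter targets; 0L / 1L / 3L bigram primes and ALD control.
* ``exp3`` — 7-letter targets; 0L / 3L bigram primes, canonical and
  reversed, plus ALD control.

Priming effects are computed on Same-response cells only (Different
trials are stored but carry no priming), as control RT minus condition
RT.  ``evaluate_models`` flags every (model, condition) where the
predicted match score is exactly zero yet the observed priming effect is
positive (and, by default, reported significant): a single such cell is
enough to rule the model out, since a zero match score means the prime
and target have nothing in common at the level of the model's input
representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .models import (
    DEFAULT_NOISE_SD,
    MODEL_NAMES,
    score_pair,
)
from .orthography import CodingPolicy, ValidationError, normalize_string

__all__ = [
    "EXPERIMENTS",
    "PrimingTable",
    "PredictionTable",
    "FalsificationFlag",
    "FalsificationReport",
    "default_model_policies",
    "load_priming_table",
    "compute_priming_effects",
    "predict_experiment",
    "evaluate_models",
]

EXPERIMENTS = ("exp1", "exp2", "exp3")

_COLUMNS = [
    "experiment",
    "response",
    "target_class",
    "condition",
    "prime_example",
    "target_example",
    "rt_ms",
    "pct_error",
    "sig_flag",
]

CONTROL_CONDITION = "ALD"


class SchemaError(ValidationError):
    """A fixture or table does not conform to the expected layout."""


@dataclass(frozen=True)
class PrimingTable:
    """Condition-level cells of one experiment.

    ``cells`` has one row per (response, target_class, condition) with the
    mean RT in ms, the percent error rate, the example prime-target pair,
    and a significance flag for the condition-vs-control contrast.
    """

    experiment: str
    cells: pd.DataFrame
    control: str = CONTROL_CONDITION

    def __post_init__(self) -> None:
        df = self.cells
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"fixture missing columns: {missing}")
        if (df["rt_ms"] <= 0).any():
            raise SchemaError("all mean RTs must be positive")
        if ((df["pct_error"] < 0) | (df["pct_error"] > 100)).any():
            raise SchemaError("error rates must lie in [0, 100]")
        same = df[df["response"] == "Same"]
        for tclass, grp in same.groupby("target_class"):
            if self.control not in set(grp["condition"]):
                raise SchemaError(
                    f"no {self.control} cell for Same-response "
                    f"target class {tclass!r}"
                )

    def same_cells(self) -> pd.DataFrame:
        return self.cells[self.cells["response"] == "Same"]

    def cell(self, response: str, target_class: str, condition: str) -> pd.Series:
        df = self.cells
        sel = df[
            (df["response"] == response)
            & (df["target_class"] == target_class)
            & (df["condition"] == condition)
        ]
        if len(sel) != 1:
            raise SchemaError(
                f"expected one cell for ({response}, {target_class}, "
                f"{condition}), found {len(sel)}"
            )
        return sel.iloc[0]


@dataclass(frozen=True)
class PredictionTable:
    """Per-model match scores and observed priming for one experiment.

    ``scores`` rows: model, target_class, condition, prime, target, score.
    ``priming`` rows: target_class, condition, delta_ms, significant.
    """

    experiment: str
    scores: pd.DataFrame
    priming: pd.DataFrame


@dataclass(frozen=True)
class FalsificationFlag:
    model: str
    target_class: str
    condition: str
    score: float
    delta_ms: float
    significant: bool


@dataclass(frozen=True)
class FalsificationReport:
    experiment: str
    flags: tuple[FalsificationFlag, ...] = field(default_factory=tuple)
    models: tuple[str, ...] = ()

    def flags_for(self, model: str) -> list[FalsificationFlag]:
        return [f for f in self.flags if f.model == model]

    def verdict(self, model: str) -> str:
        return "inconsistent" if self.flags_for(model) else "consistent"

    def summary(self) -> str:
        lines = [f"Falsification report - {self.experiment}"]
        for model in self.models:
            lines.append(f"  {model}: {self.verdict(model)}")
            for f in self.flags_for(model):
                lines.append(
                    f"    {f.target_class}/{f.condition}: score = {f.score:g}, "
                    f"observed priming = {f.delta_ms:g} ms"
                    + (" (significant)" if f.significant else "")
                )
        return "\n".join(lines)


def _fixture_path(experiment: str) -> Path:
    if experiment not in EXPERIMENTS:
        raise SchemaError(
            f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}"
        )
    return Path(str(resources.files("orthosim").joinpath(f"data/{experiment}.csv")))


def load_priming_table(experiment: str, path: str | Path | None = None) -> PrimingTable:
    """Load a packaged fixture (``exp1``/``exp2``/``exp3``) or an external
    CSV with the same schema."""
    src = Path(path) if path is not None else _fixture_path(experiment)
    try:
        df = pd.read_csv(src)
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot read fixture {src}: {exc}") from exc
    df["sig_flag"] = df["sig_flag"].fillna(0).astype(int) if "sig_flag" in df else 0
    return PrimingTable(experiment=experiment, cells=df)


def compute_priming_effects(
    table: PrimingTable, control: str | None = None
) -> dict[tuple[str, str], float]:
    """Priming effect per (target_class, condition) on Same-response cells:
    control mean RT minus condition mean RT, in ms."""
    control = control or table.control
    same = table.same_cells()
    effects: dict[tuple[str, str], float] = {}
    for tclass, grp in same.groupby("target_class"):
        ctrl_rows = grp[grp["condition"] == control]
        if ctrl_rows.empty:
            raise SchemaError(f"missing {control} cell for class {tclass!r}")
        ctrl_rt = float(ctrl_rows["rt_ms"].iloc[0])
        for _, row in grp.iterrows():
            if row["condition"] == control:
                continue
            effects[(str(tclass), str(row["condition"]))] = ctrl_rt - float(
                row["rt_ms"]
            )
    return effects


def default_model_policies() -> dict[str, CodingPolicy | None]:
    """Policy per model name as used for the experiments' predictions.

    Binary coding uses the span-two constraint shared by the bigram
    models; the noisy variant adds Gaussian positional noise on top of the
    distance weights.
    """
    return {
        "binary": CodingPolicy.binary(max_gap=2),
        "weighted": CodingPolicy.seriol(),
        "noisy": CodingPolicy.seriol(noise_sd=DEFAULT_NOISE_SD),
        "slot": None,
        "gradient": None,
    }


def predict_experiment(
    table: PrimingTable,
    models: Sequence[str] = MODEL_NAMES,
    policies: Mapping[str, CodingPolicy | None] | None = None,
) -> PredictionTable:
    """Score each Same-trial condition's example prime-target pair under
    each model, and attach the observed priming effects."""
    pols = dict(default_model_policies())
    if policies:
        pols.update(policies)
    effects = compute_priming_effects(table)
    same = table.same_cells()

    score_rows = []
    for _, row in same.iterrows():
        prime = normalize_string(str(row["prime_example"]))
        target = normalize_string(str(row["target_example"]))
        for model in models:
            result = score_pair(prime, target, model, pols.get(model))
            score_rows.append(
                {
                    "model": model,
                    "target_class": row["target_class"],
                    "condition": row["condition"],
                    "prime": str(row["prime_example"]),
                    "target": str(row["target_example"]),
                    "score": result.score,
                }
            )
    priming_rows = [
        {
            "target_class": tclass,
            "condition": cond,
            "delta_ms": delta,
            "significant": bool(
                int(table.cell("Same", tclass, cond)["sig_flag"])
            ),
        }
        for (tclass, cond), delta in effects.items()
    ]
    return PredictionTable(
        experiment=table.experiment,
        scores=pd.DataFrame(score_rows),
        priming=pd.DataFrame(priming_rows),
    )


def evaluate_models(
    predictions: PredictionTable,
    observed: PrimingTable,
    min_effect: float = 0.0,
    require_significance: bool = True,
) -> FalsificationReport:
    """Flag every (model, condition) whose predicted match score is exactly
    zero while the observed priming effect exceeds ``min_effect`` (and is
    reported significant, unless ``require_significance`` is False)."""
    if predictions.experiment != observed.experiment:
        raise SchemaError(
            f"prediction table is for {predictions.experiment!r} but "
            f"observations are for {observed.experiment!r}"
        )
    effects = compute_priming_effects(observed)
    pred_keys = {
        (r["target_class"], r["condition"])
        for _, r in predictions.scores.iterrows()
        if r["condition"] != observed.control
    }
    missing = set(effects) - pred_keys
    if missing:
        raise SchemaError(f"conditions without predictions: {sorted(missing)}")

    flags: list[FalsificationFlag] = []
    models = tuple(dict.fromkeys(predictions.scores["model"]))
    for _, row in predictions.scores.iterrows():
        key = (str(row["target_class"]), str(row["condition"]))
        if key not in effects:
            continue  # control condition
        delta = effects[key]
        sig = bool(int(observed.cell("Same", key[0], key[1])["sig_flag"]))
        if row["score"] == 0.0 and delta > min_effect and (sig or not require_significance):
            flags.append(
                FalsificationFlag(
                    model=str(row["model"]),
                    target_class=key[0],
                    condition=key[1],
                    score=float(row["score"]),
                    delta_ms=delta,
                    significant=sig,
                )
            )
    return FalsificationReport(
        experiment=observed.experiment, flags=tuple(flags), models=models
    )
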