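# orthosim

Letter-order coding models for visual word recognition: open-bigram
extraction and match scores under competing coding schemes (binary
open bigrams, distance-weighted bigrams, noisy-position bigrams, slot
coding, and a simplified spatial-gradient coder), together with
masked-priming stimulus construction, packaged condition-level results
from three same-different priming experiments, a zero-overlap
falsification check, and a trial-level RT simulator with crossed subject
and item effects.

## Quick tour

```python
from orthosim import (
    CodingPolicy, normalize_string, extract_open_bigrams,
    binary_ob_match, weighted_ob_match, noisy_ob_match,
    load_priming_table, compute_priming_effects,
    predict_experiment, evaluate_models,
)

judge = normalize_string("JUDGE")
policy = CodingPolicy.binary()                       # unbounded gap, no edges
len(extract_open_bigrams(judge, policy))             # 10
binary_ob_match(normalize_string("jugde"), judge, policy).score   # 0.9

# distance-weighted (1.0 / 0.8 / 0.4 per gap, zero beyond two letters)
weighted_ob_match(normalize_string("bo"), normalize_string("ABOLISH")).score

# positional noise lets reversed pairs score above zero
noisy = CodingPolicy.seriol(noise_sd=0.5)
noisy_ob_match(normalize_string("fo"), normalize_string("OF"), noisy).score

# packaged results tables and the falsification verdict
table = load_priming_table("exp3")
compute_priming_effects(table)       # {('7letter', '0L'): 29.0, ...}
report = evaluate_models(predict_experiment(table), table)
print(report.summary())
```

Synthetic trial-level data (inverse-RT scale, condition effects on Same
trials only, 250 ms cutoff as a separate step):

```python
from orthosim import DesignSpec, simulate_experiment, apply_rt_cutoff, recover_effects

design = DesignSpec(n_subjects=12, n_items=20,
                    condition_effects={"TL": 57.0, "ALD": 0.0}, seed=1)
trials = simulate_experiment(design)
filtered, n_removed = apply_rt_cutoff(trials)
recover_effects(filtered, seed=1).priming            # {'TL': ~57}
```

## CLI

The `orthosim` entry point exposes six subcommands:

```sh
orthosim score --input pairs.tsv --out scores.tsv --model binary --model weighted
orthosim primes --words words.txt --out stimuli.tsv --condition 0L --condition rev3L
orthosim predict --experiment exp2
orthosim evaluate --experiment exp3
orthosim simulate --config sim.yaml --out trials.csv
orthosim reproduce            # recompute printed reference values; exit 2 on mismatch
```

`score` reads a TSV with `prime` and `target` columns; policies come from
flags (`--max-gap`, `--edges`, `--sigma`) or a YAML config with a
`policy:` section (keys: `preset`, `max_gap`, `include_edges`,
`gap_weights`, `noise_sd`). `simulate` takes a `design:` section
(`n_subjects`, `n_items`, `condition_effects`, `seed`, ...). Exit codes:
0 success, 1 validation error, 2 reproduction mismatch.

## Tests and acceptance report

```sh
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the reference quantities (bigram
counts and shares for the worked examples, the degenerate repeated-pair
match, and the priming effects from the packaged tables) from scratch
and writes them as JSON.

## Layout

- `src/orthosim/orthography.py` — letter strings, coding policies, open-bigram extraction and counting
- `src/orthosim/models.py` — the five match-score models plus noise calibration
- `src/orthosim/stimuli.py` — TL / SL / bigram / ALD prime construction
- `src/orthosim/pipeline.py` — priming tables, predictions, falsification (`data/exp{1,2,3}.csv` fixtures)
- `src/orthosim/simulate.py` — trial-level RT generator, cutoff, effect recovery
- `src/orthosim/cli.py`, `src/orthosim/config.py` — command line and YAML config
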