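# dyadbargain

Analysis pipeline for dyadic face-to-face bargaining experiments in which
pairs of children jointly choose between an *equal* reward tray (E gummy
bears each) and an *unequal* one (L to one child, S to the other, L > S).
Because both children must pull the tray together, every reward is the
outcome of a negotiation; the scientific questions are whether dyads
develop strategies at all, whether those strategies point the same way,
and whether the resulting reward division is fairer or less fair than
chance.

The package provides, for researchers analysing such choice/negotiation
data at small sample sizes:

* **Domain model and I/O** — validated trial records (agreement, tray,
  large-reward recipient, protest, change-of-tray) with a canonical CSV
  interchange format (`dyadbargain.core`).
* **Per-dyad and group measures** — reward totals, inequality measures,
  unequal-tray share, highest-earner share, negotiation descriptives
  (`dyadbargain.metrics`).
* **Monte Carlo strategy tests** — a *pure-strategy* test (mean |p_i − ½|:
  individual dyads depart from 50/50) and a *common-strategy* test
  (mean p_i: dyads lean the same way) against a random-choice null matched
  on per-dyad success counts (`dyadbargain.resampling`).
* **Exact small-sample tests** — two-sided exact binomial by tail
  doubling; an exact Wilcoxon signed-rank test (all 2^m sign assignments,
  midranks, zero-ties dropped); and the closed-form expected absolute
  reward difference E|Δ| = δ·k·C(k−1,⌊(k−1)/2⌋)/2^(k−1) under random role
  assignment, used to test observed inequality against chance
  (`dyadbargain.exact_tests`).
* **Theoretical curves and classification** — monopoly and alternation
  predictions for the highest earner's share, and the
  inequality/equality/reciprocal/mixed dyad classification at the 66%
  threshold (`dyadbargain.strategy`).
* **A synthetic-data generator** — dyad strategy archetypes (random,
  monopolist, equal-preferrer, alternator, mixtures) with the study's
  failure processes, plus calibration and strategy-recovery harnesses
  (`dyadbargain.simulate`).

## Worked example

```python
from dyadbargain import (
    EXP1_DESIGN, AnalysisConfig, binom_two_sided,
    common_strategy_test, expected_abs_diff, generate_dataset,
    pure_strategy_test,
)
from dyadbargain.simulate import study_config

# a study-shaped synthetic sample: 12 dyads per age group, 4 trials each
dataset = generate_dataset(study_config(experiment=1, seed=2027))
young = type(dataset)(
    design=dataset.design,
    dyads=tuple(d for d in dataset.dyads if d.age_group == "3.5"),
)

cfg = AnalysisConfig(seed=7)          # 10,000 Monte Carlo reps
pure = pure_strategy_test(young, cfg)
common = common_strategy_test(young, cfg)
print(f"pure:   stat={pure.observed_statistic:.3f} p={pure.p_value:.4f}")
print(f"common: stat={common.observed_statistic:.3f} p={common.p_value:.4f}")
print(f"first-choice 2/12 binomial p = {binom_two_sided(2, 12).p_value:.4f}")
print(f"expected |diff| after 4 random unequal splits = {expected_abs_diff(4, 2)}")
```

prints

```
pure:   stat=0.229 p=0.4224
common: stat=0.701 p=0.0095
first-choice 2/12 binomial p = 0.0386
expected |diff| after 4 random unequal splits = 3
```

— the two tests dissociate: no individual dyad in this simulated younger
group is deterministic enough to beat chance (pure p ≈ 0.42), yet the
group as a whole leans toward the unequal tray (common p ≈ 0.01). A dyad
splitting the unequal tray 4 times at random would end up 3 gummy bears
apart on average — the baseline the observed-vs-expected inequality test
compares against.

## Analysis scripts

`analysis/01_simulate.py` … `06_calibration.py` run the full narrative:
simulate both experiments, descriptives and curves, exact tests, Monte
Carlo strategy tests, pattern classification with recovery validation, and
type-I-error/power calibration. Each writes its tables under `results/`.

## Command line

```sh
dyadbargain simulate --config sim.json --out trials.csv --seed 11
dyadbargain analyze --trials trials.csv --config analysis.json --out report.json
dyadbargain classify --trials trials.csv --threshold 0.66
dyadbargain curves --design exp2
dyadbargain test binom --k 2 --n 12
dyadbargain test wilcoxon --diffs 1,2,-3
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch: it simulates both study-shaped
experiments from the given seed, executes every analysis stage (group
summaries, both Monte Carlo tests, exact tests, classification,
negotiation), writes the per-experiment reports to
`results/report_exp{1,2}.json`, prints their summaries, and writes the
results map to `--out`.

See `docs/methods.md` for the statistical model, the generator's
assumptions and the package's design choices.
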