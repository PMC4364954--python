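"""Monte Carlo strategy tests against a random-choice null.

Both tests simulate dyads choosing between the two trays by fair coin,
with each simulated dyad making exactly as many decisions as that dyad's
observed number of successful trials.  Two statistics distinguish two
questions:

* **pure strategy** — mean over dyads of |prop_unequal - 0.5|: do
  individual dyads deviate from 50/50, in either direction?
* **common strategy** — mean over dyads of prop_unequal: do dyads lean the
  same way?

Significance is the proportion of simulations whose statistic lies at
least as far from its random expectation as the observed one (non-strict
comparison).  The observed and simulated statistics go through the same
arithmetic, so the non-strict comparison is exact in floating point.

Dyads with zero successful trials carry no choice information and are
excluded (and reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import AnalysisConfig, Dataset
from .metrics import summarize_dataset

__all__ = [
    "MonteCarloTestResult",
    "simulate_null_choices",
    "mc_p_value",
    "pure_strategy_test",
    "common_strategy_test",
]


@dataclass(frozen=True)
class MonteCarloTestResult:
    """A Monte Carlo test outcome, carrying everything needed to replay it."""

    test_name: str
    observed_statistic: float
    n_reps: int
    p_value: float
    seed: int
    convention: str
    n_dyads_included: int
    excluded_dyads: tuple = ()
    null_summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "observed_statistic": self.observed_statistic,
            "n_reps": self.n_reps,
            "p_value": self.p_value,
            "seed": self.seed,
            "convention": self.convention,
            "n_dyads_included": self.n_dyads_included,
            "excluded_dyads": list(self.excluded_dyads),
            "null_summary": self.null_summary,
        }


def simulate_null_choices(
    success_counts: Sequence[int],
    rng: np.random.Generator,
    n_reps: int = 1,
) -> np.ndarray:
    """Simulate per-dyad unequal-choice counts under fair-coin choices.

    Returns an ``(n_reps, n_dyads)`` array; dyad *i* of each replicate is a
    Binomial(k_i, 1/2) draw, where ``k_i`` is that dyad's observed number of
    successful trials.  Fully determined by the generator state.
    """
    k = np.asarray(success_counts, dtype=int)
    if k.size == 0:
        raise ValueError("success_counts is empty")
    if (k < 1).any():
        raise ValueError("every success count must be >= 1 (exclude zero-success dyads)")
    return rng.binomial(k, 0.5, size=(n_reps, k.size))


def mc_p_value(
    observed: float,
    null_draws: Sequence[float],
    reference: float,
    convention: str = "plain",
) -> float:
    """Proportion of null draws at least as far from *reference* as *observed*.

    ``plain``: b/m, the verbatim reading of "proportion of simulations at
    least as far away"; ``plus_one``: (b+1)/(m+1), which cannot return an
    exact zero.
    """
    draws = np.asarray(null_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("null_draws is empty")
    d_obs = abs(observed - reference)
    b = int(np.count_nonzero(np.abs(draws - reference) >= d_obs))
    m = draws.size
    if convention == "plain":
        return b / m
    if convention == "plus_one":
        return (b + 1) / (m + 1)
    raise ValueError(f"unknown convention {convention!r}")


def _strategy_test(
    dataset: Dataset,
    config: AnalysisConfig,
    test_name: str,
) -> MonteCarloTestResult:
    summaries = summarize_dataset(dataset)
    included = [s for s in summaries if s.n_success >= 1]
    excluded = tuple(s.dyad_id for s in summaries if s.n_success == 0)
    if not included:
        raise ValueError("no dyad with at least one successful trial")

    k = np.array([s.n_success for s in included], dtype=int)
    observed_counts = np.array([s.n_unequal for s in included], dtype=float)

    if test_name == "pure_strategy":
        reference = 0.0

        def statistic(counts: np.ndarray) -> np.ndarray:
            return np.abs(counts / k - 0.5).mean(axis=-1)

    elif test_name == "common_strategy":
        reference = 0.5

        def statistic(counts: np.ndarray) -> np.ndarray:
            return (counts / k).mean(axis=-1)

    else:  # pragma: no cover - internal
        raise ValueError(test_name)

    observed_stat = float(statistic(observed_counts))

    rng = np.random.default_rng(config.seed)
    draws = simulate_null_choices(k, rng, n_reps=config.n_reps)
    null_stats = statistic(draws.astype(float))

    p = mc_p_value(observed_stat, null_stats, reference, convention=config.p_convention)
    q = np.quantile(null_stats, [0.025, 0.5, 0.975])
    return MonteCarloTestResult(
        test_name=test_name,
        observed_statistic=observed_stat,
        n_reps=config.n_reps,
        p_value=float(p),
        seed=config.seed,
        convention=config.p_convention,
        n_dyads_included=len(included),
        excluded_dyads=excluded,
        null_summary={
            "mean": float(null_stats.mean()),
            "q025": float(q[0]),
            "median": float(q[1]),
            "q975": float(q[2]),
        },
    )


def pure_strategy_test(dataset: Dataset, config: AnalysisConfig) -> MonteCarloTestResult:
    """Do individual dyads deviate from 50/50 tray choice, in any direction?

    Statistic: mean over included dyads of |prop_unequal - 0.5| (random
    expectation 0).  Larger = more deterministic dyads.
    """
    return _strategy_test(dataset, config, "pure_strategy")


def common_strategy_test(dataset: Dataset, config: AnalysisConfig) -> MonteCarloTestResult:
    """Do dyads share a directional bias toward one tray?

    Statistic: mean over included dyads of prop_unequal (random expectation
    0.5, two-sided distance).
    """
    return _strategy_test(dataset, config, "common_strategy")
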