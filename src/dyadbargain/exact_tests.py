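"""Exact small-sample tests and the combinatorial expected-inequality value.

Three pieces:

* a two-sided exact binomial test by tail doubling (used for first-choice
  counts across dyads);
* an exact Wilcoxon signed-rank test whose null distribution is built over
  *all* sign assignments of the nonzero differences (zero differences are
  "ties" and are dropped; tied magnitudes receive midranks);
* the expected absolute reward difference for a dyad that split ``k``
  unequal-tray trials at random: the mean of ``|sum of k independent
  +/-delta steps|`` over all ``2^k`` equally likely role sequences, where
  ``delta = L - S``.  Equal-tray trials are symmetric and contribute zero.

The Wilcoxon null is computed by dynamic programming over the rank
multiset (a subset-sum polynomial), not by explicit enumeration, so the
test-suite brute-force oracle is an independent route to the same law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import Dataset
from .metrics import summarize_dataset

__all__ = [
    "ExactTestResult",
    "binom_two_sided",
    "wilcoxon_exact",
    "expected_abs_diff",
    "observed_vs_expected_test",
]

#: Full enumeration is exact but exponential; the study's n <= 15 is far below this.
MAX_WILCOXON_N = 20


@dataclass(frozen=True)
class ExactTestResult:
    """Outcome of one exact test.

    ``statistic`` is k for the binomial test and T = min(T+, T-) for the
    Wilcoxon test (``t_plus`` then also carries T+).  ``n_effective`` is the
    number of observations entering the null; for the Wilcoxon test
    ``n_effective + ties_dropped`` equals the input size.
    """

    method: str
    statistic: float
    n_effective: int
    p_value: float
    sidedness: str
    ties_dropped: int = 0
    t_plus: Optional[float] = None
    degenerate: bool = False
    detail: Optional[pd.DataFrame] = field(default=None, compare=False)


def binom_two_sided(k: int, n: int, p0: float = 0.5) -> ExactTestResult:
    """Two-sided exact binomial test by tail doubling.

    p = min(1, 2 * min(P(X <= k), P(X >= k))) for X ~ Binomial(n, p0).
    Reproduces the printed first-choice p-values at p0 = 0.5 and stays
    well-defined for asymmetric nulls.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"null probability must be in (0, 1), got {p0}")
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    p = min(1.0, 2.0 * min(lower, upper))
    return ExactTestResult(
        method="binomial_two_sided",
        statistic=float(k),
        n_effective=int(n),
        p_value=float(p),
        sidedness="two_sided",
    )


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Counts of each value of 2*T+ over all sign assignments.

    ``double_ranks`` are the (mid)ranks doubled so they are integers.
    Returns an integer-valued float array ``c`` with ``c[s]`` = number of
    the 2^m assignments whose doubled positive-rank sum equals ``s``.
    Exact in float64 for m <= 20 (counts < 2^53).
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_exact(
    differences: Sequence[float],
    sidedness: str = "two_sided",
) -> ExactTestResult:
    """Exact Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped and reported as ``ties_dropped``; tied
    magnitudes receive midranks.  The null law of T+ is exact over all
    ``2^m`` sign assignments of the m nonzero differences.  Two-sided
    p = min(1, 2*min(P(T+ <= t+), P(T+ >= t+))); one_sided_greater
    p = P(T+ >= t+).  If every difference is zero the result is degenerate
    with p = 1.
    """
    if sidedness not in ("two_sided", "one_sided_greater"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    diffs = np.asarray(list(differences), dtype=float)
    if diffs.size == 0:
        raise ValueError("need at least one difference")
    nonzero = diffs[diffs != 0.0]
    ties = int(diffs.size - nonzero.size)
    m = int(nonzero.size)
    if m == 0:
        return ExactTestResult(
            method="wilcoxon_exact",
            statistic=0.0,
            t_plus=0.0,
            n_effective=0,
            ties_dropped=ties,
            p_value=1.0,
            sidedness=sidedness,
            degenerate=True,
        )
    if m > MAX_WILCOXON_N:
        raise ValueError(
            f"exact enumeration limited to {MAX_WILCOXON_N} nonzero differences, got {m}"
        )

    ranks = stats.rankdata(np.abs(nonzero))  # midranks for tied magnitudes
    double_ranks = np.rint(2.0 * ranks).astype(int)
    t_plus2 = int(double_ranks[nonzero > 0].sum())
    t_minus2 = int(double_ranks.sum()) - t_plus2

    counts = _signed_rank_distribution(double_ranks)
    n_assignments = 2.0**m
    p_le = counts[: t_plus2 + 1].sum() / n_assignments
    p_ge = counts[t_plus2:].sum() / n_assignments
    if sidedness == "two_sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        p = p_ge

    return ExactTestResult(
        method="wilcoxon_exact",
        statistic=min(t_plus2, t_minus2) / 2.0,
        t_plus=t_plus2 / 2.0,
        n_effective=m,
        ties_dropped=ties,
        p_value=float(p),
        sidedness=sidedness,
    )


def expected_abs_diff(k_unequal: int, delta: int) -> Fraction:
    """Expected |reward difference| after ``k`` random unequal-tray splits.

    Each of the ``2^k`` role sequences is equally likely; each unequal
    trial moves the running difference by +/-delta.  Closed form
    ``delta * k * C(k-1, floor((k-1)/2)) / 2^(k-1)`` (the mean absolute
    displacement of a simple random walk), verified against brute-force
    enumeration in the test suite.  Exact rational arithmetic.
    """
    if k_unequal < 0 or delta < 0:
        raise ValueError(
            f"k_unequal and delta must be non-negative, got {k_unequal}, {delta}"
        )
    if k_unequal == 0:
        return Fraction(0)
    k = k_unequal
    return Fraction(delta * k * math.comb(k - 1, (k - 1) // 2), 2 ** (k - 1))


def observed_vs_expected_test(
    dataset: Dataset,
    sidedness: str = "two_sided",
) -> ExactTestResult:
    """Observed vs chance-expected within-dyad inequality, exact Wilcoxon.

    For each dyad with at least one success, pairs the observed absolute
    reward difference with the random-role expectation
    ``expected_abs_diff(n_unequal, L - S)`` and feeds the per-dyad
    (observed - expected) differences to :func:`wilcoxon_exact`.  The
    per-dyad table rides on ``detail``.
    """
    delta = dataset.design.delta
    rows = []
    for s in summarize_dataset(dataset):
        if s.n_success < 1:
            continue
        expected = float(expected_abs_diff(s.n_unequal, delta))
        rows.append(
            {
                "dyad_id": s.dyad_id,
                "n_success": s.n_success,
                "n_unequal": s.n_unequal,
                "observed_abs_diff": s.abs_diff,
                "expected_abs_diff": expected,
                "difference": s.abs_diff - expected,
            }
        )
    if not rows:
        raise ValueError("no dyad with at least one successful trial")
    table = pd.DataFrame(rows)
    result = wilcoxon_exact(table["difference"].to_numpy(), sidedness=sidedness)
    return ExactTestResult(
        method="observed_vs_expected",
        statistic=result.statistic,
        t_plus=result.t_plus,
        n_effective=result.n_effective,
        ties_dropped=result.ties_dropped,
        p_value=result.p_value,
        sidedness=result.sidedness,
        degenerate=result.degenerate,
        detail=table,
    )
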