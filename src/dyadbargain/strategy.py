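"""Theoretical outcome curves, dyad pattern classification, negotiation table.

The two curves predict the highest earner's reward share as a function of
how often a dyad took the unequal tray (u of n successes):

* **monopoly**: the same child takes the large plate on every unequal
  success — share = (u*L + (n-u)*E) / (u*(L+S) + (n-u)*2E);
* **alternation**: the large plate alternates — the highest earner gets
  ceil(u/2)*L + floor(u/2)*S + (n-u)*E over the same total.

Both equal 1/2 at u=0; monopoly rises to L/(L+S) at u=n; alternation never
exceeds monopoly.

Pattern classification assigns each dyad one of five labels from its
successful trials, evaluated in this order (first match wins):

1. *undetermined* — no successful trial;
2. *equality* — equal tray on >= tau of successes (tau default 0.66, so
   2 of 3 qualifies);
3. *reciprocal* — at least two unequal successes with the large reward
   split exactly evenly;
4. *inequality* — one child took the large reward on >= tau of successes;
5. *mixed* — anything else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .core import Dataset, TrayDesign
from .exact_tests import ExactTestResult, wilcoxon_exact
from .metrics import DyadSummary, _mean_sd, summarize_dataset

__all__ = [
    "PATTERN_LABELS",
    "CurvePoint",
    "NegotiationSummary",
    "monopoly_curve",
    "alternation_curve",
    "curve_table",
    "classify_dyad",
    "classify_dataset",
    "negotiation_summary",
]

PATTERN_LABELS = ("inequality", "equality", "reciprocal", "mixed", "undetermined")


@dataclass(frozen=True)
class CurvePoint:
    u: int
    n: int
    monopoly_prop: float
    alternation_prop: float


def _total_rewards(u: int, n: int, design: TrayDesign) -> int:
    return u * (design.unequal_large + design.unequal_small) + (
        n - u
    ) * 2 * design.equal_per_child


def monopoly_curve(u: int, n: int, design: TrayDesign) -> float:
    """Highest earner's share when one child monopolises the large plate."""
    if n < 1:
        raise ValueError("need n >= 1 successful trials")
    if not 0 <= u <= n:
        raise ValueError(f"need 0 <= u <= n, got u={u}, n={n}")
    top = u * design.unequal_large + (n - u) * design.equal_per_child
    return top / _total_rewards(u, n, design)


def alternation_curve(u: int, n: int, design: TrayDesign) -> float:
    """Highest earner's share under strict large-plate turn-taking."""
    if n < 1:
        raise ValueError("need n >= 1 successful trials")
    if not 0 <= u <= n:
        raise ValueError(f"need 0 <= u <= n, got u={u}, n={n}")
    top = (
        math.ceil(u / 2) * design.unequal_large
        + math.floor(u / 2) * design.unequal_small
        + (n - u) * design.equal_per_child
    )
    return top / _total_rewards(u, n, design)


def curve_table(design: TrayDesign, n: Optional[int] = None) -> pd.DataFrame:
    """Both theoretical curves for u = 0..n, as a plottable table."""
    if n is None:
        n = design.n_test_trials
    rows = [
        CurvePoint(
            u=u,
            n=n,
            monopoly_prop=monopoly_curve(u, n, design),
            alternation_prop=alternation_curve(u, n, design),
        )
        for u in range(n + 1)
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def classify_dyad(summary: DyadSummary, threshold: float = 0.66) -> str:
    """Assign one pattern label from a dyad's successful trials."""
    n = summary.n_success
    if n == 0:
        return "undetermined"
    if summary.n_equal / n >= threshold:
        return "equality"
    if summary.n_unequal >= 2 and summary.big_count_A == summary.big_count_B:
        return "reciprocal"
    if max(summary.big_count_A, summary.big_count_B) / n >= threshold:
        return "inequality"
    return "mixed"


def classify_dataset(dataset: Dataset, threshold: float = 0.66) -> pd.DataFrame:
    """Label counts per (experiment, age_group), dyad labels attached.

    Returns a DataFrame with one row per group and one column per label;
    per-dyad labels ride on ``.attrs["dyad_labels"]``.
    """
    covs = {d.dyad_id: d for d in dataset.dyads}
    labels = {}
    for s in summarize_dataset(dataset):
        labels[s.dyad_id] = classify_dyad(s, threshold)

    rows: dict[tuple, dict] = {}
    for did, label in labels.items():
        d = covs[did]
        key = (d.experiment, d.age_group)
        row = rows.setdefault(key, {lab: 0 for lab in PATTERN_LABELS})
        row[label] += 1
    table = pd.DataFrame(
        [
            {"experiment": k[0], "age_group": k[1], **v}
            for k, v in sorted(rows.items())
        ]
    )
    table.attrs["dyad_labels"] = labels
    table.attrs["threshold"] = threshold
    return table


@dataclass(frozen=True)
class NegotiationSummary:
    """Negotiation descriptives plus the paired change-of-tray comparison.

    ``dyad_table`` holds per-dyad proportions; ``means`` the across-dyad
    means/SDs of the defined values; ``change_test`` the exact Wilcoxon on
    per-dyad (equal-outcome change proportion - unequal-outcome change
    proportion), over the ``n_paired`` dyads having both outcome types
    (``n_unpaired`` lacked one and are excluded from the test).
    """

    dyad_table: pd.DataFrame
    means: dict
    change_test: Optional[ExactTestResult]
    n_paired: int
    n_unpaired: int


def negotiation_summary(dataset: Dataset, sidedness: str = "two_sided") -> NegotiationSummary:
    """Protest/immediate-acceptance/change-of-tray descriptives per dyad.

    Per dyad: the protest proportion over all trials, the split of protests
    by target (small amount vs equal tray), and — separately for successful
    equal and unequal outcomes — the proportion immediately accepted (no
    protest, no change of tray) and the proportion resulting from a change
    of tray.
    """
    rows = []
    for dyad in dataset.dyads:
        trials = dyad.trials
        n_trials = len(trials)
        protests = [t for t in trials if t.protest != "none"]
        n_protest = len(protests)
        row = {
            "dyad_id": dyad.dyad_id,
            "protest_prop": n_protest / n_trials,
            "protest_against_small_share": (
                sum(t.protest == "against_small" for t in protests) / n_protest
                if n_protest
                else None
            ),
            "protest_against_equal_share": (
                sum(t.protest == "against_equal" for t in protests) / n_protest
                if n_protest
                else None
            ),
        }
        for tray in ("equal", "unequal"):
            outcomes = [t for t in trials if t.outcome == "success" and t.tray == tray]
            if outcomes:
                row[f"{tray}_immediate_prop"] = sum(
                    t.protest == "none" and not t.change_of_tray for t in outcomes
                ) / len(outcomes)
                row[f"{tray}_change_prop"] = sum(t.change_of_tray for t in outcomes) / len(
                    outcomes
                )
            else:
                row[f"{tray}_immediate_prop"] = None
                row[f"{tray}_change_prop"] = None
        rows.append(row)
    table = pd.DataFrame(rows)

    means = {}
    for col in table.columns:
        if col == "dyad_id":
            continue
        defined = [r[col] for r in rows if r[col] is not None]
        mean, sd = _mean_sd(defined)
        means[col] = {"n_used": len(defined), "mean": mean, "sd": sd}

    paired = [
        r["equal_change_prop"] - r["unequal_change_prop"]
        for r in rows
        if r["equal_change_prop"] is not None and r["unequal_change_prop"] is not None
    ]
    n_paired = len(paired)
    n_unpaired = len(rows) - n_paired
    change_test = wilcoxon_exact(paired, sidedness=sidedness) if paired else None

    return NegotiationSummary(
        dyad_table=table,
        means=means,
        change_test=change_test,
        n_paired=n_paired,
        n_unpaired=n_unpaired,
    )
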