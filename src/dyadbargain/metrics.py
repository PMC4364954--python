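"""Per-dyad and per-group summary measures.

Every downstream test consumes these: success and agreement counts, reward
totals per child, the absolute and proportional within-dyad reward
difference, the proportion of successful trials on the unequal tray, the
highest earner's reward share, and negotiation descriptives (protest and
change-of-tray proportions).

Proportions whose denominator is zero are *undefined* and carried as
``None`` — never silently zero.  Group statistics average per-dyad values
(percentages are computed per dyad first, then averaged across dyads) and
report the sample (n-1) standard deviation.

Denominator conventions, per field:

==================  ==========================================
prop_unequal        successful trials
prop_diff           total rewards delivered (successes only)
highest_earner_prop total rewards delivered (successes only)
protest_prop        all trials (protests are coded from room entry)
change_prop         successful trials (an outcome exists only there)
==================  ==========================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .core import Dataset, DyadRecord, TrayDesign, rewards_for_trial

__all__ = [
    "DyadSummary",
    "MeasureStat",
    "GroupSummary",
    "PROPORTION_MEASURES",
    "summarize_dyad",
    "summarize_dataset",
    "summarize_groups",
    "highest_earner_points",
    "dyad_summaries_frame",
    "group_summaries_frame",
]

#: DyadSummary proportion fields that group summaries aggregate.
PROPORTION_MEASURES = (
    "prop_agreed",
    "prop_success_of_agreed",
    "prop_unequal",
    "prop_diff",
    "highest_earner_prop",
    "protest_prop",
    "change_prop",
)


@dataclass(frozen=True)
class DyadSummary:
    """Derived per-dyad counts, reward totals and proportions."""

    dyad_id: str
    n_trials: int
    n_agreed: int
    n_success: int
    n_equal: int
    n_unequal: int
    big_count_A: int
    big_count_B: int
    rewards_A: int
    rewards_B: int
    abs_diff: int
    prop_diff: Optional[float]
    prop_unequal: Optional[float]
    highest_earner_prop: Optional[float]
    prop_agreed: float
    prop_success_of_agreed: Optional[float]
    protest_prop: float
    change_prop: Optional[float]


@dataclass(frozen=True)
class MeasureStat:
    """Mean and sample SD of one proportion across a group's dyads."""

    n_used: int
    n_excluded: int
    mean: Optional[float]
    sd: Optional[float]


@dataclass(frozen=True)
class GroupSummary:
    """Aggregated proportions for one covariate combination."""

    key: dict
    n_dyads: int
    n_excluded: int  # dyads undefined on at least one measure
    measures: dict = field(default_factory=dict)  # name -> MeasureStat


def summarize_dyad(dyad: DyadRecord, design: TrayDesign) -> DyadSummary:
    """Compute every per-dyad measure from its coded trials."""
    n_trials = len(dyad.trials)
    n_agreed = sum(t.outcome != "no_agreement" for t in dyad.trials)
    successes = [t for t in dyad.trials if t.outcome == "success"]
    n_success = len(successes)
    n_equal = sum(t.tray == "equal" for t in successes)
    n_unequal = n_success - n_equal
    big_a = sum(t.large_recipient == "A" for t in successes)
    big_b = sum(t.large_recipient == "B" for t in successes)

    rewards_a = rewards_b = 0
    for t in dyad.trials:
        ra, rb = rewards_for_trial(t, design)
        rewards_a += ra
        rewards_b += rb
    abs_diff = abs(rewards_a - rewards_b)
    total = rewards_a + rewards_b

    if n_success > 0:
        prop_diff = abs_diff / total
        prop_unequal = n_unequal / n_success
        highest = max(rewards_a, rewards_b) / total
        change = sum(t.change_of_tray for t in successes) / n_success
    else:
        prop_diff = prop_unequal = highest = change = None

    return DyadSummary(
        dyad_id=dyad.dyad_id,
        n_trials=n_trials,
        n_agreed=n_agreed,
        n_success=n_success,
        n_equal=n_equal,
        n_unequal=n_unequal,
        big_count_A=big_a,
        big_count_B=big_b,
        rewards_A=rewards_a,
        rewards_B=rewards_b,
        abs_diff=abs_diff,
        prop_diff=prop_diff,
        prop_unequal=prop_unequal,
        highest_earner_prop=highest,
        prop_agreed=n_agreed / n_trials,
        prop_success_of_agreed=(n_success / n_agreed) if n_agreed else None,
        protest_prop=sum(t.protest != "none" for t in dyad.trials) / n_trials,
        change_prop=change,
    )


def summarize_dataset(dataset: Dataset) -> list[DyadSummary]:
    return [summarize_dyad(d, dataset.design) for d in dataset.dyads]


def _mean_sd(values: Sequence[float]) -> tuple[Optional[float], Optional[float]]:
    n = len(values)
    if n == 0:
        return None, None
    mean = sum(values) / n
    if n < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def summarize_groups(dataset: Dataset, grouping: Sequence[str]) -> list[GroupSummary]:
    """One :class:`GroupSummary` per observed covariate combination.

    *grouping* names DyadRecord covariates (``experiment``, ``age_group``,
    ``gender``, ``familiarity``).  Dyads with an undefined measure are
    excluded from that measure's mean/SD and counted in ``n_excluded``.
    """
    valid = {"experiment", "age_group", "gender", "familiarity"}
    unknown = set(grouping) - valid
    if unknown:
        raise KeyError(f"unknown covariate(s) {sorted(unknown)}; valid: {sorted(valid)}")

    groups: dict[tuple, list[DyadSummary]] = {}
    order: list[tuple] = []
    for dyad in dataset.dyads:
        key = tuple(getattr(dyad, g) for g in grouping)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(summarize_dyad(dyad, dataset.design))

    out = []
    for key in order:
        summaries = groups[key]
        measures = {}
        for name in PROPORTION_MEASURES:
            vals = [getattr(s, name) for s in summaries]
            defined = [v for v in vals if v is not None]
            mean, sd = _mean_sd(defined)
            measures[name] = MeasureStat(
                n_used=len(defined),
                n_excluded=len(vals) - len(defined),
                mean=mean,
                sd=sd,
            )
        n_excluded = sum(
            any(getattr(s, name) is None for name in PROPORTION_MEASURES)
            for s in summaries
        )
        out.append(
            GroupSummary(
                key=dict(zip(grouping, key)),
                n_dyads=len(summaries),
                n_excluded=n_excluded,
                measures=measures,
            )
        )
    return out


def highest_earner_points(dataset: Dataset) -> pd.DataFrame:
    """Per-dyad (prop_unequal, highest_earner_prop) points.

    One row per dyad with at least one success — the scatter the theoretical
    monopoly/alternation curves are drawn against.
    """
    rows = [
        {
            "dyad_id": s.dyad_id,
            "prop_unequal": s.prop_unequal,
            "highest_earner_prop": s.highest_earner_prop,
        }
        for s in summarize_dataset(dataset)
        if s.n_success >= 1
    ]
    return pd.DataFrame(rows, columns=["dyad_id", "prop_unequal", "highest_earner_prop"])


def dyad_summaries_frame(dataset: Dataset) -> pd.DataFrame:
    """All per-dyad summaries as a DataFrame (one row per dyad)."""
    covs = {d.dyad_id: d for d in dataset.dyads}
    rows = []
    for s in summarize_dataset(dataset):
        d = covs[s.dyad_id]
        row = {
            "dyad_id": s.dyad_id,
            "experiment": d.experiment,
            "age_group": d.age_group,
            "gender": d.gender,
            "familiarity": d.familiarity,
        }
        row.update({k: getattr(s, k) for k in DyadSummary.__dataclass_fields__ if k != "dyad_id"})
        rows.append(row)
    return pd.DataFrame(rows)


def group_summaries_frame(dataset: Dataset, grouping: Sequence[str]) -> pd.DataFrame:
    """Group summaries as a long DataFrame (one row per group x measure)."""
    rows = []
    for g in summarize_groups(dataset, grouping):
        for name, stat in g.measures.items():
            rows.append(
                {
                    **g.key,
                    "n_dyads": g.n_dyads,
                    "measure": name,
                    "n_used": stat.n_used,
                    "n_excluded": stat.n_excluded,
                    "mean": stat.mean,
                    "sd": stat.sd,
                }
            )
    return pd.DataFrame(rows)
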