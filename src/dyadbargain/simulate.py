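"""Synthetic trial-level data with the structure the analyses assume.

No trial-level data were published for the study this pipeline targets, so
every stage is exercised on simulated dyads.  A :class:`StrategySpec`
states how a dyad behaves; a :class:`SimulationConfig` states the design
(tray payoffs, trials per dyad) and the group layout (covariate
combination, dyad count, strategy per group).  Generation per trial:

1. no agreement with probability ``p_no_agreement``;
2. otherwise a tray is agreed: unequal with probability ``p_unequal``
   (the alternator always wants the unequal tray by default);
3. coordination failure with probability ``p_coordination_failure``
   (agreed tray recorded, no rewards);
4. on an unequal success the large plate goes to the dyad's dominant
   child with probability ``p_dominant_large`` — except the alternator,
   whose large plate alternates deterministically across its unequal
   successes (failed trials do not advance the turn);
5. protest and change-of-tray indicators are drawn independently given
   the tray context (protests on unequal trials target the small amount,
   on equal trials the equal split).

Default nuisance rates mirror the study's descriptives (agreement in
~90% of trials, success in ~95% of agreed trials, protests in ~40% of
trials and mostly against the small amount).  Everything is reproducible
bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import AnalysisConfig, Dataset, DyadRecord, TrayDesign, TrialRecord
from .metrics import summarize_dyad
from .resampling import common_strategy_test, pure_strategy_test
from .strategy import classify_dyad

__all__ = [
    "StrategySpec",
    "GroupSpec",
    "SimulationConfig",
    "generate_dataset",
    "generate_tagged_dataset",
    "experiment_config",
    "study_population",
    "study_config",
    "calibration_experiment",
    "recovery_experiment",
]

Kind = Literal["random", "monopolist", "equal_preferrer", "alternator", "mixture"]

# Nuisance-process defaults, from the study's descriptive rates.
DEFAULT_P_NO_AGREEMENT = 0.06
DEFAULT_P_COORDINATION_FAILURE = 0.06
DEFAULT_PROTEST_RATE_UNEQUAL = 0.45  # protests against the small amount
DEFAULT_PROTEST_RATE_EQUAL = 0.10  # protests against the equal tray
DEFAULT_P_CHANGE_OF_TRAY = 0.20


class StrategySpec(BaseModel):
    """How one dyad behaves, as per-trial probabilities."""

    model_config = ConfigDict(frozen=True)

    kind: Kind
    p_unequal: float = Field(default=0.5, ge=0.0, le=1.0)
    p_dominant_large: float = Field(default=0.5, ge=0.0, le=1.0)
    p_no_agreement: float = Field(default=DEFAULT_P_NO_AGREEMENT, ge=0.0, le=1.0)
    p_coordination_failure: float = Field(
        default=DEFAULT_P_COORDINATION_FAILURE, ge=0.0, le=1.0
    )
    protest_rate_unequal: float = Field(default=DEFAULT_PROTEST_RATE_UNEQUAL, ge=0.0, le=1.0)
    protest_rate_equal: float = Field(default=DEFAULT_PROTEST_RATE_EQUAL, ge=0.0, le=1.0)
    p_change_of_tray: float = Field(default=DEFAULT_P_CHANGE_OF_TRAY, ge=0.0, le=1.0)
    components: Optional[tuple["StrategySpec", ...]] = None
    weights: Optional[tuple[float, ...]] = None

    @model_validator(mode="after")
    def _check_mixture(self) -> "StrategySpec":
        if self.kind == "mixture":
            if not self.components or not self.weights:
                raise ValueError("mixture requires components and weights")
            if len(self.components) != len(self.weights):
                raise ValueError("components and weights differ in length")
            if any(c.kind == "mixture" for c in self.components):
                raise ValueError("nested mixtures are not supported")
            if abs(sum(self.weights) - 1.0) > 1e-9:
                raise ValueError(f"weights must sum to 1, got {sum(self.weights)}")
        elif self.components is not None or self.weights is not None:
            raise ValueError("components/weights only valid for kind='mixture'")
        return self

    # -- canonical archetypes ------------------------------------------------

    @classmethod
    def random(cls, **overrides) -> "StrategySpec":
        """Fair-coin tray choice, fair-coin large plate."""
        return cls(kind="random", p_unequal=0.5, p_dominant_large=0.5, **overrides)

    @classmethod
    def monopolist(cls, p_unequal: float = 1.0, **overrides) -> "StrategySpec":
        """Unequal tray, one child always at the large plate."""
        return cls(kind="monopolist", p_unequal=p_unequal, p_dominant_large=1.0, **overrides)

    @classmethod
    def equal_preferrer(cls, p_unequal: float = 0.0, **overrides) -> "StrategySpec":
        """Equal tray (p_unequal is the residual unequal rate)."""
        return cls(kind="equal_preferrer", p_unequal=p_unequal, **overrides)

    @classmethod
    def alternator(cls, p_unequal: float = 1.0, **overrides) -> "StrategySpec":
        """Unequal tray with deterministic large-plate turn-taking."""
        return cls(kind="alternator", p_unequal=p_unequal, **overrides)

    def no_failures(self) -> "StrategySpec":
        """Copy with agreement/coordination failure switched off."""
        return self.model_copy(update={"p_no_agreement": 0.0, "p_coordination_failure": 0.0})


class GroupSpec(BaseModel):
    """One block of dyads sharing covariates and a strategy."""

    model_config = ConfigDict(frozen=True)

    experiment: Literal[1, 2]
    age_group: Literal["3.5", "5"]
    gender: Literal["F", "M"] = "F"
    familiarity: Literal["familiar", "unfamiliar"] = "familiar"
    n_dyads: int = Field(ge=1)
    strategy: StrategySpec


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    design: TrayDesign
    groups: tuple[GroupSpec, ...]
    seed: int

    @model_validator(mode="after")
    def _nonempty(self) -> "SimulationConfig":
        if not self.groups:
            raise ValueError("at least one group required")
        return self


def _simulate_dyad(
    dyad_id: str,
    group: GroupSpec,
    spec: StrategySpec,
    design: TrayDesign,
    rng: np.random.Generator,
) -> DyadRecord:
    trials = []
    next_large = "A"  # alternator turn state, resets per dyad
    for idx in range(1, design.n_test_trials + 1):
        if rng.random() < spec.p_no_agreement:
            outcome, tray, large = "no_agreement", "none", "none"
        else:
            tray = "unequal" if rng.random() < spec.p_unequal else "equal"
            if rng.random() < spec.p_coordination_failure:
                outcome, large = "unsuccessful_agreement", "none"
            else:
                outcome = "success"
                if tray == "unequal":
                    if spec.kind == "alternator":
                        large = next_large
                        next_large = "B" if next_large == "A" else "A"
                    else:
                        large = "A" if rng.random() < spec.p_dominant_large else "B"
                else:
                    large = "none"
        if tray == "unequal":
            protest = "against_small" if rng.random() < spec.protest_rate_unequal else "none"
        elif tray == "equal":
            protest = "against_equal" if rng.random() < spec.protest_rate_equal else "none"
        else:
            protest = "none"
        change = tray != "none" and rng.random() < spec.p_change_of_tray
        trials.append(
            TrialRecord(
                dyad_id=dyad_id,
                trial_index=idx,
                outcome=outcome,
                tray=tray,
                large_recipient=large,
                protest=protest,
                change_of_tray=bool(change),
            )
        )
    return DyadRecord(
        dyad_id=dyad_id,
        experiment=group.experiment,
        age_group=group.age_group,
        gender=group.gender,
        familiarity=group.familiarity,
        trials=tuple(trials),
    )


def generate_tagged_dataset(config: SimulationConfig) -> tuple[Dataset, dict[str, str]]:
    """Generate a dataset plus each dyad's generating-strategy tag.

    For mixture strategies the tag is the sampled component's kind.
    """
    rng = np.random.default_rng(config.seed)
    dyads = []
    tags: dict[str, str] = {}
    counter = 0
    for group in config.groups:
        for _ in range(group.n_dyads):
            counter += 1
            dyad_id = f"dyad{counter:03d}"
            spec = group.strategy
            if spec.kind == "mixture":
                idx = rng.choice(len(spec.components), p=spec.weights)
                spec = spec.components[idx]
            tags[dyad_id] = spec.kind
            dyads.append(_simulate_dyad(dyad_id, group, spec, config.design, rng))
    return Dataset(design=config.design, dyads=tuple(dyads)), tags


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Generate a fully validated dataset, reproducible from the seed."""
    return generate_tagged_dataset(config)[0]


def experiment_config(
    design: TrayDesign,
    experiment: Literal[1, 2],
    strategies: dict[str, StrategySpec],
    seed: int,
    n_dyads_per_group: int = 12,
) -> SimulationConfig:
    """Study-shaped layout: *n* dyads per age group, balanced covariates.

    ``strategies`` maps age group ("3.5", "5") to a StrategySpec.  Within
    each age group, genders and familiarity are balanced the way the study
    recruited (same-sex dyads, half familiar).
    """
    groups = []
    for age_group, spec in strategies.items():
        quarter, rem = divmod(n_dyads_per_group, 4)
        sizes = [quarter + (1 if i < rem else 0) for i in range(4)]
        cells = [("F", "familiar"), ("F", "unfamiliar"), ("M", "familiar"), ("M", "unfamiliar")]
        for (gender, familiarity), n in zip(cells, sizes):
            if n:
                groups.append(
                    GroupSpec(
                        experiment=experiment,
                        age_group=age_group,
                        gender=gender,
                        familiarity=familiarity,
                        n_dyads=n,
                        strategy=spec,
                    )
                )
    return SimulationConfig(design=design, groups=tuple(groups), seed=seed)


#: Group-level strategy mixtures emulating the reported behaviour of each
#: age group: in the low-stakes game the younger children leaned unequal
#: without strict monopolies while the older split into equal-preferring and
#: unequal-preferring dyads; in the high-stakes game both ages went mostly
#: unequal with a minority of turn-takers.  Weights follow the reported
#: per-group pattern counts (out of 12 dyads).
STUDY_MIXTURES: dict[tuple[int, str], dict] = {
    (1, "3.5"): {
        "components": (
            StrategySpec.monopolist(p_unequal=0.75),
            StrategySpec.random(),
        ),
        "weights": (0.75, 0.25),
    },
    (1, "5"): {
        "components": (
            StrategySpec.equal_preferrer(),
            StrategySpec.monopolist(),
            StrategySpec.random(),
        ),
        "weights": (0.5, 0.42, 0.08),
    },
    (2, "3.5"): {
        "components": (
            StrategySpec.monopolist(p_unequal=0.85),
            StrategySpec.alternator(),
            StrategySpec.equal_preferrer(),
        ),
        "weights": (0.67, 0.25, 0.08),
    },
    (2, "5"): {
        "components": (
            StrategySpec.monopolist(p_unequal=0.85),
            StrategySpec.alternator(),
            StrategySpec.equal_preferrer(),
        ),
        "weights": (0.75, 0.17, 0.08),
    },
}


def study_population(experiment: Literal[1, 2], age_group: str) -> StrategySpec:
    """Mixture strategy emulating one age group of one experiment."""
    entry = STUDY_MIXTURES[(experiment, age_group)]
    return StrategySpec(kind="mixture", **entry)


def study_config(experiment: Literal[1, 2], seed: int) -> SimulationConfig:
    """Full study-shaped simulation: 12 dyads per age group, both ages."""
    from .core import EXP1_DESIGN, EXP2_DESIGN

    design = EXP1_DESIGN if experiment == 1 else EXP2_DESIGN
    return experiment_config(
        design,
        experiment,
        {age: study_population(experiment, age) for age in ("3.5", "5")},
        seed=seed,
    )


def calibration_experiment(
    n_replicates: int,
    config: SimulationConfig,
    analysis: AnalysisConfig,
    alphas: Sequence[float] = (0.05,),
) -> pd.DataFrame:
    """Rejection rates of both Monte Carlo tests over replicate datasets.

    Under a random (null-true) strategy this measures type-I error; under
    any other strategy, power.  Per-replicate seeds derive deterministically
    from ``analysis.seed``.  Monte Carlo standard errors accompany each
    rate.
    """
    ss = np.random.SeedSequence(analysis.seed)
    seeds = ss.generate_state(2 * n_replicates).astype(np.int64) % (2**31)
    p_values: dict[str, list[float]] = {"pure_strategy": [], "common_strategy": []}
    for i in range(n_replicates):
        rep_config = config.model_copy(update={"seed": int(seeds[2 * i])})
        dataset = generate_dataset(rep_config)
        rep_analysis = analysis.model_copy(update={"seed": int(seeds[2 * i + 1])})
        p_values["pure_strategy"].append(pure_strategy_test(dataset, rep_analysis).p_value)
        p_values["common_strategy"].append(common_strategy_test(dataset, rep_analysis).p_value)

    rows = []
    for test_name, ps in p_values.items():
        ps_arr = np.asarray(ps)
        for alpha in alphas:
            rate = float((ps_arr <= alpha).mean())
            rows.append(
                {
                    "test_name": test_name,
                    "alpha": alpha,
                    "n_replicates": n_replicates,
                    "rejection_rate": rate,
                    "mc_se": float(np.sqrt(rate * (1 - rate) / n_replicates)),
                }
            )
    return pd.DataFrame(rows)


def recovery_experiment(
    config: SimulationConfig,
    threshold: float = 0.66,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Confusion table: generating strategy kind vs assigned pattern label.

    Aggregated over *n_replicates* datasets (per-replicate seeds derived
    from ``config.seed``); ``recovery`` rates ride on ``.attrs``.  The
    random kind has no target label, so its recovery is not defined.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(n_replicates).astype(np.int64) % (2**31)
    counts: dict[str, dict[str, int]] = {}
    for i in range(n_replicates):
        rep_config = config.model_copy(update={"seed": int(seeds[i])})
        dataset, tags = generate_tagged_dataset(rep_config)
        for dyad in dataset.dyads:
            label = classify_dyad(summarize_dyad(dyad, dataset.design), threshold)
            row = counts.setdefault(tags[dyad.dyad_id], {})
            row[label] = row.get(label, 0) + 1

    from .strategy import PATTERN_LABELS

    table = pd.DataFrame(
        [
            {"strategy": kind, **{lab: row.get(lab, 0) for lab in PATTERN_LABELS}}
            for kind, row in sorted(counts.items())
        ]
    ).set_index("strategy")

    target = {"monopolist": "inequality", "equal_preferrer": "equality", "alternator": "reciprocal"}
    recovery = {}
    for kind, lab in target.items():
        if kind in table.index:
            total = int(table.loc[kind].sum())
            recovery[kind] = float(table.loc[kind, lab] / total) if total else None
    table.attrs["recovery"] = recovery
    table.attrs["threshold"] = threshold
    return table
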