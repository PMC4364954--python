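"""Domain types and trial-level I/O for dyadic tray-choice bargaining data.

The experimental unit is a *dyad*: two children who must jointly pull one of
two baited trays.  The equal tray pays ``E`` rewards to each child; the
unequal tray pays ``L`` to whichever child sits at the large plate and ``S``
to the other (``L > S``).  A trial can end without agreement, with an agreed
tray that the pair failed to retrieve (coordination failure), or with a
successful retrieval.  Only successful trials deliver rewards.

Data interchange is a flat trials CSV (one row per trial) plus a JSON
configuration carrying the tray design and analysis settings.  All records
are validated on construction; malformed input raises
:class:`DataValidationError` naming the offending row and field.
"""

from __future__ import annotations

import csv
import io
import json
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "TrayDesign",
    "TrialRecord",
    "DyadRecord",
    "Dataset",
    "AnalysisConfig",
    "DataValidationError",
    "EXP1_DESIGN",
    "EXP2_DESIGN",
    "TRIALS_COLUMNS",
    "read_trials",
    "write_trials",
    "trials_to_csv_string",
    "rewards_for_trial",
    "load_config",
    "dump_config",
]

Outcome = Literal["no_agreement", "unsuccessful_agreement", "success"]
Tray = Literal["equal", "unequal", "none"]
Recipient = Literal["A", "B", "none"]
Protest = Literal["none", "against_small", "against_equal"]

#: Canonical column order of the trials CSV.
TRIALS_COLUMNS = (
    "dyad_id",
    "experiment",
    "age_group",
    "gender",
    "familiarity",
    "trial_index",
    "outcome",
    "tray",
    "large_recipient",
    "protest",
    "change_of_tray",
)


class DataValidationError(ValueError):
    """Raised when trial-level input violates the schema or an invariant."""


class TrayDesign(BaseModel):
    """Payoff structure of the two trays and the number of test trials.

    ``equal_per_child`` (E) is what each child gets on an equal-tray success;
    ``unequal_large`` (L) and ``unequal_small`` (S) are the two plates of the
    unequal tray, with L > S.
    """

    model_config = ConfigDict(frozen=True)

    equal_per_child: int = Field(ge=0)
    unequal_large: int = Field(ge=0)
    unequal_small: int = Field(ge=0)
    n_test_trials: int = Field(ge=1)

    @model_validator(mode="after")
    def _check_order(self) -> "TrayDesign":
        if self.unequal_large <= self.unequal_small:
            raise ValueError(
                "unequal_large must exceed unequal_small "
                f"(got L={self.unequal_large}, S={self.unequal_small})"
            )
        return self

    @property
    def delta(self) -> int:
        """Per-trial reward gap L - S on the unequal tray."""
        return self.unequal_large - self.unequal_small


#: Experiment 1: equal (2,2) vs unequal (3,1), four test trials per dyad.
EXP1_DESIGN = TrayDesign(equal_per_child=2, unequal_large=3, unequal_small=1, n_test_trials=4)
#: Experiment 2: equal (2,2) vs unequal (6,1), four test trials per dyad.
EXP2_DESIGN = TrayDesign(equal_per_child=2, unequal_large=6, unequal_small=1, n_test_trials=4)

DESIGN_BY_EXPERIMENT = {1: EXP1_DESIGN, 2: EXP2_DESIGN}


class TrialRecord(BaseModel):
    """One coded trial of one dyad."""

    model_config = ConfigDict(frozen=True)

    dyad_id: str
    trial_index: int = Field(ge=1)
    outcome: Outcome
    tray: Tray
    large_recipient: Recipient
    protest: Protest
    change_of_tray: bool

    @model_validator(mode="after")
    def _check_invariants(self) -> "TrialRecord":
        # tray is absent exactly when no agreement was reached
        if (self.tray == "none") != (self.outcome == "no_agreement"):
            raise ValueError(
                f"tray={self.tray!r} inconsistent with outcome={self.outcome!r}: "
                "tray must be 'none' if and only if outcome is 'no_agreement'"
            )
        got_large = self.large_recipient != "none"
        should_have_large = self.tray == "unequal" and self.outcome == "success"
        if got_large != should_have_large:
            raise ValueError(
                f"large_recipient={self.large_recipient!r} inconsistent with "
                f"tray={self.tray!r}, outcome={self.outcome!r}: a large-reward "
                "recipient exists if and only if the trial is a successful "
                "unequal-tray trial"
            )
        return self


class DyadRecord(BaseModel):
    """A dyad's covariates with its ordered trials."""

    model_config = ConfigDict(frozen=True)

    dyad_id: str
    experiment: Literal[1, 2]
    age_group: Literal["3.5", "5"]
    gender: Literal["F", "M"]
    familiarity: Literal["familiar", "unfamiliar"]
    trials: tuple[TrialRecord, ...]

    @model_validator(mode="after")
    def _check_trials(self) -> "DyadRecord":
        indices = [t.trial_index for t in self.trials]
        if indices != list(range(1, len(self.trials) + 1)):
            raise ValueError(
                f"dyad {self.dyad_id!r}: trial indices must be 1..n in order "
                f"with no gaps or duplicates, got {indices}"
            )
        for t in self.trials:
            if t.dyad_id != self.dyad_id:
                raise ValueError(
                    f"trial {t.trial_index} carries dyad_id {t.dyad_id!r}, "
                    f"expected {self.dyad_id!r}"
                )
        return self


class Dataset(BaseModel):
    """A tray design plus the dyads measured under it."""

    model_config = ConfigDict(frozen=True)

    design: TrayDesign
    dyads: tuple[DyadRecord, ...]

    @model_validator(mode="after")
    def _check_dyads(self) -> "Dataset":
        seen: set[str] = set()
        for d in self.dyads:
            if d.dyad_id in seen:
                raise ValueError(f"duplicate dyad_id {d.dyad_id!r}")
            seen.add(d.dyad_id)
            if len(d.trials) != self.design.n_test_trials:
                raise ValueError(
                    f"dyad {d.dyad_id!r} has {len(d.trials)} trials, design "
                    f"requires {self.design.n_test_trials}"
                )
        return self


class AnalysisConfig(BaseModel):
    """Settings shared by every stochastic and threshold-bearing analysis."""

    model_config = ConfigDict(frozen=True)

    seed: int
    n_reps: int = Field(default=10_000, ge=1)
    threshold: float = Field(default=0.66, gt=0.5, le=1.0)
    p_convention: Literal["plain", "plus_one"] = "plain"


def rewards_for_trial(trial: TrialRecord, design: TrayDesign) -> tuple[int, int]:
    """Reward counts (child A, child B) delivered by one trial.

    Zero for anything short of a successful agreement; ``(E, E)`` for an
    equal-tray success; ``(L, S)`` or ``(S, L)`` for an unequal-tray success
    depending on who sat at the large plate.
    """
    if trial.outcome != "success":
        return (0, 0)
    if trial.tray == "equal":
        e = design.equal_per_child
        return (e, e)
    large, small = design.unequal_large, design.unequal_small
    return (large, small) if trial.large_recipient == "A" else (small, large)


# ---------------------------------------------------------------------------
# CSV interchange


def _parse_bool(value: str, row: int) -> bool:
    if value == "true":
        return True
    if value == "false":
        return False
    raise DataValidationError(
        f"row {row}: field 'change_of_tray' must be 'true' or 'false', got {value!r}"
    )


def read_trials(
    path: Union[str, Path, io.TextIOBase],
    design: Optional[TrayDesign] = None,
) -> Dataset:
    """Read and validate a trials CSV into a :class:`Dataset`.

    Rows are grouped by ``dyad_id`` in order of first appearance, preserving
    trial order within each dyad.  When *design* is omitted it is inferred
    from the file's (then necessarily unique) ``experiment`` column using the
    two published designs; pass an explicit design for custom payoffs.
    """
    if isinstance(path, io.TextIOBase):
        rows = list(csv.DictReader(path))
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        with p.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise DataValidationError(f"{p}: empty file, header required")
            missing = set(TRIALS_COLUMNS) - set(reader.fieldnames)
            if missing:
                raise DataValidationError(
                    f"{p}: missing column(s) {sorted(missing)}"
                )
            rows = list(reader)

    by_dyad: dict[str, dict] = {}
    experiments: set[int] = set()
    for i, row in enumerate(rows, start=2):  # data rows start at line 2
        try:
            trial = TrialRecord(
                dyad_id=row["dyad_id"],
                trial_index=int(row["trial_index"]),
                outcome=row["outcome"],
                tray=row["tray"],
                large_recipient=row["large_recipient"],
                protest=row["protest"],
                change_of_tray=_parse_bool(row["change_of_tray"], i),
            )
        except KeyError as exc:
            raise DataValidationError(f"row {i}: missing column {exc}") from exc
        except (ValidationError, ValueError) as exc:
            raise DataValidationError(f"row {i}: {exc}") from exc

        did = row["dyad_id"]
        entry = by_dyad.setdefault(
            did,
            {
                "experiment": row["experiment"],
                "age_group": row["age_group"],
                "gender": row["gender"],
                "familiarity": row["familiarity"],
                "trials": [],
            },
        )
        for field in ("experiment", "age_group", "gender", "familiarity"):
            if row[field] != entry[field]:
                raise DataValidationError(
                    f"row {i}: dyad {did!r} has inconsistent {field!r} "
                    f"({row[field]!r} vs {entry[field]!r})"
                )
        entry["trials"].append(trial)

    dyads = []
    for did, entry in by_dyad.items():
        try:
            exp = int(entry["experiment"])
            experiments.add(exp)
            dyads.append(
                DyadRecord(
                    dyad_id=did,
                    experiment=exp,
                    age_group=entry["age_group"],
                    gender=entry["gender"],
                    familiarity=entry["familiarity"],
                    trials=tuple(entry["trials"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise DataValidationError(f"dyad {did!r}: {exc}") from exc

    if design is None:
        if len(experiments) > 1:
            raise DataValidationError(
                f"file mixes experiments {sorted(experiments)}; pass an "
                "explicit TrayDesign"
            )
        design = DESIGN_BY_EXPERIMENT[next(iter(experiments))] if experiments else EXP1_DESIGN

    try:
        return Dataset(design=design, dyads=tuple(dyads))
    except ValidationError as exc:
        raise DataValidationError(str(exc)) from exc


def trials_to_csv_string(dataset: Dataset) -> str:
    """Render a dataset as the canonical trials CSV (``\\n`` newlines)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(TRIALS_COLUMNS)
    for dyad in dataset.dyads:
        for t in dyad.trials:
            writer.writerow(
                [
                    dyad.dyad_id,
                    dyad.experiment,
                    dyad.age_group,
                    dyad.gender,
                    dyad.familiarity,
                    t.trial_index,
                    t.outcome,
                    t.tray,
                    t.large_recipient,
                    t.protest,
                    "true" if t.change_of_tray else "false",
                ]
            )
    return buf.getvalue()


def write_trials(dataset: Dataset, path: Union[str, Path]) -> None:
    """Write the canonical trials CSV so that :func:`read_trials` inverts it."""
    Path(path).write_text(trials_to_csv_string(dataset), encoding="utf-8", newline="")


# ---------------------------------------------------------------------------
# Configuration JSON


def load_config(path: Union[str, Path]) -> tuple[TrayDesign, AnalysisConfig]:
    """Load the design + analysis configuration JSON.

    Schema: ``{"design": {"E", "L", "S", "n_test_trials"},
    "analysis": {"seed", "n_reps", "threshold", "p_convention"}}``.
    """
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        d = doc["design"]
        design = TrayDesign(
            equal_per_child=d["E"],
            unequal_large=d["L"],
            unequal_small=d["S"],
            n_test_trials=d["n_test_trials"],
        )
        analysis = AnalysisConfig(**doc["analysis"])
    except (KeyError, ValidationError) as exc:
        raise DataValidationError(f"{path}: {exc}") from exc
    return design, analysis


def dump_config(design: TrayDesign, analysis: AnalysisConfig, path: Union[str, Path]) -> None:
    doc = {
        "design": {
            "E": design.equal_per_child,
            "L": design.unequal_large,
            "S": design.unequal_small,
            "n_test_trials": design.n_test_trials,
        },
        "analysis": analysis.model_dump(),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
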