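"""Shared fixtures: compact builders for dyads and datasets.

Trial shorthand used throughout the suite:

* ``"E"``  — equal-tray success
* ``"UA"`` / ``"UB"`` — unequal-tray success, child A / B at the large plate
* ``"N"``  — no agreement
* ``"FE"`` / ``"FU"`` — unsuccessful agreement on the equal / unequal tray
"""

from __future__ import annotations

from typing import Sequence

import pytest

from dyadbargain.core import (
    EXP1_DESIGN,
    EXP2_DESIGN,
    Dataset,
    DyadRecord,
    TrayDesign,
    TrialRecord,
)

_SHORTHAND = {
    "E": ("success", "equal", "none"),
    "UA": ("success", "unequal", "A"),
    "UB": ("success", "unequal", "B"),
    "N": ("no_agreement", "none", "none"),
    "FE": ("unsuccessful_agreement", "equal", "none"),
    "FU": ("unsuccessful_agreement", "unequal", "none"),
}


def build_dyad(
    dyad_id: str,
    codes: Sequence[str],
    experiment: int = 1,
    age_group: str = "3.5",
    gender: str = "F",
    familiarity: str = "familiar",
    protests: Sequence[str] | None = None,
    changes: Sequence[bool] | None = None,
) -> DyadRecord:
    protests = protests or ["none"] * len(codes)
    changes = changes or [False] * len(codes)
    trials = []
    for i, (code, protest, change) in enumerate(zip(codes, protests, changes), start=1):
        outcome, tray, large = _SHORTHAND[code]
        trials.append(
            TrialRecord(
                dyad_id=dyad_id,
                trial_index=i,
                outcome=outcome,
                tray=tray,
                large_recipient=large,
                protest=protest,
                change_of_tray=change,
            )
        )
    return DyadRecord(
        dyad_id=dyad_id,
        experiment=experiment,
        age_group=age_group,
        gender=gender,
        familiarity=familiarity,
        trials=tuple(trials),
    )


def build_dataset(
    dyad_codes: Sequence[Sequence[str]],
    design: TrayDesign = EXP1_DESIGN,
    **dyad_kwargs,
) -> Dataset:
    dyads = tuple(
        build_dyad(f"d{i:03d}", codes, **dyad_kwargs)
        for i, codes in enumerate(dyad_codes, start=1)
    )
    return Dataset(design=design, dyads=dyads)


@pytest.fixture
def exp1() -> TrayDesign:
    return EXP1_DESIGN


@pytest.fixture
def exp2() -> TrayDesign:
    return EXP2_DESIGN
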