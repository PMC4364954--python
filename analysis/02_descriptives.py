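#!/usr/bin/env python
"""Per-dyad and per-group descriptives plus the theoretical outcome curves.

Reads results/trials_exp{1,2}.csv (from 01_simulate.py) and writes:

* results/dyad_summaries_exp{1,2}.csv — every per-dyad measure;
* results/group_summaries_exp{1,2}.csv — means +- SD per age group;
* results/highest_earner_exp{1,2}.csv — the (unequal share, highest-earner
  share) scatter the curves are drawn against;
* results/curves_exp{1,2}.csv — monopoly and alternation predictions.
"""

from pathlib import Path

from dyadbargain.core import read_trials
from dyadbargain.metrics import (
    dyad_summaries_frame,
    group_summaries_frame,
    highest_earner_points,
)
from dyadbargain.strategy import curve_table

RESULTS = Path("results")


def main() -> None:
    for experiment in (1, 2):
        dataset = read_trials(RESULTS / f"trials_exp{experiment}.csv")
        dyad_summaries_frame(dataset).to_csv(
            RESULTS / f"dyad_summaries_exp{experiment}.csv", index=False
        )
        groups = group_summaries_frame(dataset, ["age_group"])
        groups.to_csv(RESULTS / f"group_summaries_exp{experiment}.csv", index=False)
        highest_earner_points(dataset).to_csv(
            RESULTS / f"highest_earner_exp{experiment}.csv", index=False
        )
        curve_table(dataset.design).to_csv(
            RESULTS / f"curves_exp{experiment}.csv", index=False
        )

        print(f"experiment {experiment}:")
        for _, row in groups[groups["measure"] == "prop_unequal"].iterrows():
            sd = f"{row['sd']:.2f}" if row["sd"] == row["sd"] else "NA"
            print(
                f"  age {row['age_group']}: unequal-tray share "
                f"{row['mean']:.2f} +- {sd} "
                f"({row['n_used']} dyads, {row['n_excluded']} excluded)"
            )


if __name__ == "__main__":
    main()
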