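#!/usr/bin/env python
"""Generate the study-shaped synthetic datasets both experiments analyse.

Writes results/trials_exp{1,2}.csv (12 dyads per age group, 4 test trials,
low-stakes 2-2 vs 3-1 and high-stakes 2-2 vs 6-1 designs) and the matching
analysis configuration JSONs.  Strategy mixtures per age group emulate the
reported group-level behaviour; the trial-level data are synthetic.
"""

from pathlib import Path

from dyadbargain.core import AnalysisConfig, dump_config, write_trials
from dyadbargain.metrics import dyad_summaries_frame
from dyadbargain.simulate import generate_dataset, study_config

SEED = 2026
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for experiment in (1, 2):
        config = study_config(experiment, seed=SEED + experiment)
        dataset = generate_dataset(config)
        trials_path = RESULTS / f"trials_exp{experiment}.csv"
        write_trials(dataset, trials_path)
        dump_config(
            dataset.design,
            AnalysisConfig(seed=SEED + 100 * experiment),
            RESULTS / f"config_exp{experiment}.json",
        )
        frame = dyad_summaries_frame(dataset)
        n_success = frame["n_success"].sum()
        print(
            f"experiment {experiment}: {len(dataset.dyads)} dyads, "
            f"{n_success} successful trials of {4 * len(dataset.dyads)}, "
            f"mean unequal share {frame['prop_unequal'].mean():.2f} "
            f"-> {trials_path}"
        )


if __name__ == "__main__":
    main()
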