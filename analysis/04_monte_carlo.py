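#!/usr/bin/env python
"""Monte Carlo strategy tests per experiment and age group.

For each age group: the pure-strategy test (do individual dyads depart
from 50/50 tray choice, in either direction?) and the common-strategy test
(do dyads lean the same way?), each against 10,000 simulated random-choice
datasets matched on per-dyad success counts.

Writes results/monte_carlo.json.
"""

import json
from pathlib import Path

from dyadbargain.core import AnalysisConfig, Dataset, load_config, read_trials
from dyadbargain.resampling import common_strategy_test, pure_strategy_test

RESULTS = Path("results")


def main() -> None:
    out = []
    for experiment in (1, 2):
        dataset = read_trials(RESULTS / f"trials_exp{experiment}.csv")
        _, analysis = load_config(RESULTS / f"config_exp{experiment}.json")
        by_age = {}
        for dyad in dataset.dyads:
            by_age.setdefault(dyad.age_group, []).append(dyad)
        for i, (age, dyads) in enumerate(sorted(by_age.items())):
            sub = Dataset(design=dataset.design, dyads=tuple(dyads))
            for j, test in enumerate((pure_strategy_test, common_strategy_test)):
                cfg = analysis.model_copy(update={"seed": analysis.seed + 10 * i + j})
                r = test(sub, cfg)
                out.append({"experiment": experiment, "age_group": age, **r.to_dict()})
                print(
                    f"experiment {experiment}, age {age}, {r.test_name}: "
                    f"statistic {r.observed_statistic:.3f}, p = {r.p_value:.4f} "
                    f"({r.n_dyads_included} dyads, seed {r.seed})"
                )
    (RESULTS / "monte_carlo.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
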