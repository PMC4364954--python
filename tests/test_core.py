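"""Domain types, validation totality, and CSV round-tripping."""

import io

import pytest
from pydantic import ValidationError

from dyadbargain.core import (
    EXP1_DESIGN,
    EXP2_DESIGN,
    AnalysisConfig,
    Dataset,
    DataValidationError,
    TrayDesign,
    TrialRecord,
    dump_config,
    load_config,
    read_trials,
    rewards_for_trial,
    trials_to_csv_string,
    write_trials,
)
from dyadbargain.simulate import SimulationConfig, GroupSpec, StrategySpec, generate_dataset

from conftest import build_dataset, build_dyad


class TestTrayDesign:
    def test_published_designs(self):
        assert (EXP1_DESIGN.equal_per_child, EXP1_DESIGN.unequal_large,
                EXP1_DESIGN.unequal_small, EXP1_DESIGN.n_test_trials) == (2, 3, 1, 4)
        assert EXP2_DESIGN.unequal_large == 6
        assert EXP1_DESIGN.delta == 2 and EXP2_DESIGN.delta == 5

    def test_large_must_exceed_small(self):
        with pytest.raises(ValidationError):
            TrayDesign(equal_per_child=2, unequal_large=1, unequal_small=3, n_test_trials=4)


class TestTrialInvariants:
    def test_large_recipient_on_equal_tray_rejected(self):
        with pytest.raises(ValidationError, match="large_recipient"):
            TrialRecord(
                dyad_id="d", trial_index=1, outcome="success", tray="equal",
                large_recipient="A", protest="none", change_of_tray=False,
            )

    def test_tray_none_requires_no_agreement(self):
        with pytest.raises(ValidationError, match="tray"):
            TrialRecord(
                dyad_id="d", trial_index=1, outcome="success", tray="none",
                large_recipient="none", protest="none", change_of_tray=False,
            )

    def test_unsuccessful_agreement_keeps_its_tray(self):
        t = TrialRecord(
            dyad_id="d", trial_index=1, outcome="unsuccessful_agreement", tray="unequal",
            large_recipient="none", protest="against_small", change_of_tray=False,
        )
        assert t.tray == "unequal"

    def test_trial_index_gaps_rejected(self):
        from dyadbargain.core import DyadRecord

        t1 = build_dyad("d1", ["E"]).trials[0]
        t3 = TrialRecord(
            dyad_id="d1", trial_index=3, outcome="success", tray="equal",
            large_recipient="none", protest="none", change_of_tray=False,
        )
        with pytest.raises(ValidationError, match="no gaps"):
            DyadRecord(
                dyad_id="d1", experiment=1, age_group="3.5", gender="F",
                familiarity="familiar", trials=(t1, t3),
            )

    def test_duplicate_dyad_ids_rejected(self):
        d = build_dyad("same", ["E"] * 4)
        design = TrayDesign(equal_per_child=2, unequal_large=3, unequal_small=1, n_test_trials=4)
        with pytest.raises(ValidationError, match="duplicate"):
            Dataset(design=design, dyads=(d, d))


@pytest.mark.parametrize(
    "code, design, expected",
    [
        ("E", EXP1_DESIGN, (2, 2)),       # equal split of 2 per plate
        ("UB", EXP2_DESIGN, (1, 6)),      # 1 vs 6, large plate at B
        ("UA", EXP1_DESIGN, (3, 1)),
        ("N", EXP1_DESIGN, (0, 0)),
        ("FU", EXP1_DESIGN, (0, 0)),      # no rewards without success
    ],
)
def test_rewards_for_trial(code, design, expected):
    dyad = build_dyad("d1", [code])
    assert rewards_for_trial(dyad.trials[0], design) == expected


def test_reward_conservation_on_success(exp1, exp2):
    for design in (exp1, exp2):
        for code in ("E", "UA", "UB"):
            ra, rb = rewards_for_trial(build_dyad("d", [code]).trials[0], design)
            total = 2 * design.equal_per_child if code == "E" else (
                design.unequal_large + design.unequal_small
            )
            assert ra + rb == total


class TestCsvRoundTrip:
    def test_identity_one_dyad(self, tmp_path):
        ds = build_dataset([["E", "UA", "N", "UB"]])
        path = tmp_path / "trials.csv"
        write_trials(ds, path)
        back = read_trials(path)
        assert back == ds

    def test_write_read_write_is_bitstable(self, tmp_path):
        ds = build_dataset([["E", "UA", "UB", "E"], ["N", "FU", "E", "UA"]])
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_trials(ds, p1)
        write_trials(read_trials(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_dataset_is_header_only(self, tmp_path):
        ds = Dataset(design=EXP1_DESIGN, dyads=())
        path = tmp_path / "empty.csv"
        write_trials(ds, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("dyad_id,experiment")

    def test_two_dyads_eight_rows_in_order(self):
        ds = build_dataset([["E"] * 4, ["UA"] * 4])
        lines = trials_to_csv_string(ds).splitlines()
        assert len(lines) == 9
        assert [ln.split(",")[0] for ln in lines[1:]] == ["d001"] * 4 + ["d002"] * 4

    def test_round_trip_on_simulated_datasets(self, tmp_path):
        """write o read is the identity across 100 generated datasets."""
        for seed in range(100):
            config = SimulationConfig(
                design=EXP1_DESIGN if seed % 2 else EXP2_DESIGN,
                groups=(
                    GroupSpec(
                        experiment=1 if seed % 2 else 2, age_group="3.5",
                        n_dyads=3, strategy=StrategySpec.random(),
                    ),
                ),
                seed=seed,
            )
            ds = generate_dataset(config)
            path = tmp_path / "t.csv"
            write_trials(ds, path)
            assert read_trials(path, design=config.design) == ds


class TestReadValidation:
    def _rows(self, **overrides):
        base = {
            "dyad_id": "d1", "experiment": "1", "age_group": "3.5", "gender": "F",
            "familiarity": "familiar", "trial_index": "1", "outcome": "success",
            "tray": "equal", "large_recipient": "none", "protest": "none",
            "change_of_tray": "false",
        }
        base.update(overrides)
        return base

    def _write(self, tmp_path, row):
        cols = list(row)
        text = ",".join(cols) + "\n" + ",".join(row[c] for c in cols) + "\n"
        path = tmp_path / "bad.csv"
        path.write_text(text)
        return path

    def test_invariant_violation_names_row(self, tmp_path):
        path = self._write(tmp_path, self._rows(large_recipient="A"))
        with pytest.raises(DataValidationError, match="row 2"):
            read_trials(path, design=TrayDesign(
                equal_per_child=2, unequal_large=3, unequal_small=1, n_test_trials=1))

    def test_unknown_enum_value(self, tmp_path):
        path = self._write(tmp_path, self._rows(outcome="victory"))
        with pytest.raises(DataValidationError, match="row 2"):
            read_trials(path)

    def test_missing_column(self, tmp_path):
        row = self._rows()
        del row["outcome"]
        path = self._write(tmp_path, row)
        with pytest.raises(DataValidationError, match="outcome"):
            read_trials(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_trials(tmp_path / "nope.csv")

    def test_mixed_experiments_need_explicit_design(self, tmp_path):
        d1 = build_dyad("a", ["E"] * 4, experiment=1)
        d2 = build_dyad("b", ["E"] * 4, experiment=2)
        ds = Dataset(design=EXP1_DESIGN, dyads=(d1, d2))
        path = tmp_path / "mixed.csv"
        write_trials(ds, path)
        with pytest.raises(DataValidationError, match="mixes experiments"):
            read_trials(path)
        assert read_trials(path, design=EXP1_DESIGN) == ds


class TestConfigJson:
    def test_round_trip(self, tmp_path):
        analysis = AnalysisConfig(seed=11, n_reps=500, threshold=0.7, p_convention="plus_one")
        path = tmp_path / "config.json"
        dump_config(EXP2_DESIGN, analysis, path)
        design2, analysis2 = load_config(path)
        assert design2 == EXP2_DESIGN and analysis2 == analysis

    def test_defaults(self):
        cfg = AnalysisConfig(seed=1)
        assert cfg.n_reps == 10_000
        assert cfg.threshold == 0.66
        assert cfg.p_convention == "plain"

    def test_threshold_must_exceed_half(self):
        with pytest.raises(ValidationError):
            AnalysisConfig(seed=1, threshold=0.5)
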