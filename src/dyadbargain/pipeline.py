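"""End-to-end analysis: metrics -> Monte Carlo -> exact tests -> patterns.

:func:`run_analyze` executes every stage on a trials CSV and returns an
:class:`AnalysisReport` whose ``to_dict()`` is the JSON the CLI writes; the
human-readable summary is rendered *from* that JSON, never computed
separately.  All stochastic results carry their seed; per-group seeds are
derived deterministically from the configured base seed.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import __version__
from .core import AnalysisConfig, Dataset, TrayDesign, load_config, read_trials
from .exact_tests import ExactTestResult, binom_two_sided, observed_vs_expected_test
from .metrics import group_summaries_frame, highest_earner_points
from .resampling import common_strategy_test, pure_strategy_test
from .strategy import classify_dataset, curve_table, negotiation_summary

__all__ = ["AnalysisReport", "run_analyze", "analyze_dataset", "render_summary"]


@dataclass
class AnalysisReport:
    provenance: dict
    group_summaries: list
    monte_carlo: list
    exact_tests: list
    classification: dict
    curves: list
    negotiation: dict
    highest_earner: list
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "group_summaries": self.group_summaries,
            "monte_carlo": self.monte_carlo,
            "exact_tests": self.exact_tests,
            "classification": self.classification,
            "curves": self.curves,
            "negotiation": self.negotiation,
            "highest_earner": self.highest_earner,
            "warnings": self.warnings,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, default=_jsonify) + "\n",
            encoding="utf-8",
        )


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _exact_to_dict(result: ExactTestResult, **extra) -> dict:
    d = {
        "method": result.method,
        "statistic": result.statistic,
        "t_plus": result.t_plus,
        "n_effective": result.n_effective,
        "ties_dropped": result.ties_dropped,
        "p_value": result.p_value,
        "sidedness": result.sidedness,
        "degenerate": result.degenerate,
    }
    d.update(extra)
    return d


def _first_choice_counts(dataset: Dataset) -> tuple[int, int]:
    """(# dyads choosing the equal tray at trial 1, # dyads with a coded trial-1 tray)."""
    k = n = 0
    for dyad in dataset.dyads:
        tray = dyad.trials[0].tray
        if tray != "none":
            n += 1
            k += tray == "equal"
    return k, n


def analyze_dataset(dataset: Dataset, analysis: AnalysisConfig) -> AnalysisReport:
    """Run every stage on an in-memory dataset (see :func:`run_analyze`)."""
    warnings: list[str] = []
    groups: dict[tuple, list] = {}
    for dyad in dataset.dyads:
        groups.setdefault((dyad.experiment, dyad.age_group), []).append(dyad)

    seed_pool = np.random.SeedSequence(analysis.seed).generate_state(
        2 * max(1, len(groups))
    ).astype(np.int64) % (2**31)

    monte_carlo = []
    exact = []
    for i, (key, dyads) in enumerate(sorted(groups.items())):
        sub = Dataset(design=dataset.design, dyads=tuple(dyads))
        label = {"experiment": key[0], "age_group": key[1]}

        for j, test in enumerate((pure_strategy_test, common_strategy_test)):
            cfg = analysis.model_copy(update={"seed": int(seed_pool[2 * i + j] )})
            result = test(sub, cfg)
            monte_carlo.append({**label, **result.to_dict()})
            for did in result.excluded_dyads:
                warnings.append(
                    f"{result.test_name} {label}: dyad {did} excluded (no successful trial)"
                )

        try:
            ove = observed_vs_expected_test(sub)
            exact.append(
                _exact_to_dict(
                    ove,
                    **label,
                    per_dyad=ove.detail.to_dict(orient="records"),
                )
            )
            if ove.degenerate:
                warnings.append(f"observed_vs_expected {label}: degenerate (all differences zero)")
        except ValueError as err:
            warnings.append(f"observed_vs_expected {label}: skipped ({err})")

        k, n = _first_choice_counts(sub)
        if n:
            fc = binom_two_sided(k, n, 0.5)
            exact.append(
                _exact_to_dict(fc, **label, description="first choice equal tray at trial 1")
            )
        else:
            warnings.append(f"first_choice {label}: no dyad with a coded trial-1 tray")

    class_table = classify_dataset(dataset, analysis.threshold)
    classification = {
        "threshold": analysis.threshold,
        "counts": class_table.to_dict(orient="records"),
        "dyad_labels": class_table.attrs["dyad_labels"],
    }

    neg = negotiation_summary(dataset)
    negotiation = {
        "means": neg.means,
        "n_paired": neg.n_paired,
        "n_unpaired": neg.n_unpaired,
        "change_of_tray_test": _exact_to_dict(neg.change_test) if neg.change_test else None,
        "denominator_note": (
            "protest_prop uses all trials; change proportions use successful "
            "trials of the given outcome type"
        ),
    }
    if neg.change_test is not None and neg.change_test.degenerate:
        warnings.append("negotiation change-of-tray test degenerate (all differences zero)")

    return AnalysisReport(
        provenance={
            "version": __version__,
            "seed": analysis.seed,
            "n_reps": analysis.n_reps,
            "threshold": analysis.threshold,
            "p_convention": analysis.p_convention,
            "design": {
                "E": dataset.design.equal_per_child,
                "L": dataset.design.unequal_large,
                "S": dataset.design.unequal_small,
                "n_test_trials": dataset.design.n_test_trials,
            },
            "n_dyads": len(dataset.dyads),
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
        group_summaries=group_summaries_frame(dataset, ["experiment", "age_group"]).to_dict(
            orient="records"
        ),
        monte_carlo=monte_carlo,
        exact_tests=exact,
        classification=classification,
        curves=curve_table(dataset.design).to_dict(orient="records"),
        negotiation=negotiation,
        highest_earner=highest_earner_points(dataset).to_dict(orient="records"),
        warnings=warnings,
    )


def run_analyze(
    trials_path: Union[str, Path],
    config_path: Union[str, Path],
    design: Optional[TrayDesign] = None,
) -> AnalysisReport:
    """Read trials + configuration, run every stage, return the report.

    The configuration JSON's design must match the data; its analysis block
    supplies seed, rep count, classification threshold and p-value
    convention.
    """
    cfg_design, analysis = load_config(config_path)
    dataset = read_trials(trials_path, design=design or cfg_design)
    report = analyze_dataset(dataset, analysis)
    data = Path(trials_path).read_bytes()
    report.provenance["input_path"] = str(trials_path)
    report.provenance["input_sha256"] = hashlib.sha256(data).hexdigest()
    return report


def render_summary(report: dict) -> str:
    """Human-readable summary derived from the report JSON."""
    lines = []
    prov = report["provenance"]
    lines.append(
        f"dyadbargain {prov['version']} | seed {prov['seed']} | "
        f"{prov['n_dyads']} dyads | design E={prov['design']['E']} "
        f"L={prov['design']['L']} S={prov['design']['S']}"
    )
    lines.append("")
    lines.append("Monte Carlo strategy tests (random-choice null):")
    for mc in report["monte_carlo"]:
        lines.append(
            f"  exp {mc['experiment']} age {mc['age_group']:>3} "
            f"{mc['test_name']:<15} stat={mc['observed_statistic']:.4f} "
            f"p={mc['p_value']:.4f} (n_reps={mc['n_reps']}, seed={mc['seed']})"
        )
    lines.append("Exact tests:")
    for ex in report["exact_tests"]:
        stat = (
            f"T={ex['statistic']:.1f} T+={ex['t_plus']:.1f}"
            if ex["method"] in ("wilcoxon_exact", "observed_vs_expected")
            else f"k={ex['statistic']:.0f}"
        )
        lines.append(
            f"  exp {ex['experiment']} age {ex['age_group']:>3} "
            f"{ex['method']:<21} {stat} n={ex['n_effective']} p={ex['p_value']:.4f}"
        )
    lines.append("Pattern classification (threshold "
                 f"{report['classification']['threshold']}):")
    for row in report["classification"]["counts"]:
        counts = ", ".join(
            f"{lab}={row[lab]}"
            for lab in ("inequality", "equality", "reciprocal", "mixed", "undetermined")
        )
        lines.append(f"  exp {row['experiment']} age {row['age_group']:>3}: {counts}")
    if report["warnings"]:
        lines.append("Warnings:")
        lines.extend(f"  - {w}" for w in report["warnings"])
    return "\n".join(lines) + "\n"
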