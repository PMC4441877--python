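"""One-way sensitivity scenarios and the horizon sweep.

A :class:`Scenario` is a named set of dotted-path parameter overrides.
Overrides act on the cost side and the clinical attack model only; the
QALY stream is deliberately left at its trial-derived calibration even
when effectiveness parameters change — the published analysis holds the
utility gains fixed across its scenario table, and rescaling them would
change the science, not just the arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from .model import ArmResult, CEResult, ModelOutput, run_model
from .params import ModelParams, apply_overrides


@dataclass(frozen=True)
class Scenario:
    """Named parameter overrides, e.g. ``{"clinical.pain_relief_prob": 0.502}``."""

    name: str
    overrides: Mapping[str, Any]

    def apply(self, base: ModelParams) -> ModelParams:
        return apply_overrides(base, self.overrides)


@dataclass(frozen=True)
class ScenarioResult:
    scenario: Scenario
    spg: ArmResult
    control: ArmResult
    ce: CEResult


def run_scenario(base: ModelParams, scenario: Scenario) -> ScenarioResult:
    """Apply the overrides to a copy of ``base`` and run the cohort model."""
    out: ModelOutput = run_model(scenario.apply(base))
    return ScenarioResult(scenario=scenario, spg=out.spg, control=out.control, ce=out.ce)


def table4_scenarios(base: ModelParams) -> list[Scenario]:
    """The published sensitivity table, in printed order.

    Relative scenarios (attack-rate halving/doubling, medication-cost
    ±25 %) are expressed against ``base`` so the list composes with any
    starting parameter set.
    """
    attacks = base.clinical.baseline_attacks_per_day
    med = base.costs.med_cost_per_attack
    return [
        Scenario("Base case", {}),
        Scenario("Base case (undiscounted)", {"discount.annual_rate": 0.0}),
        Scenario("Pain relief 50.2 % (lower bound of 95 % CI)",
                 {"clinical.pain_relief_prob": 0.502}),
        Scenario("Pain relief 80.5 % (upper bound of 95 % CI)",
                 {"clinical.pain_relief_prob": 0.805}),
        Scenario("1.37 CH attacks per day (50 % of baseline)",
                 {"clinical.baseline_attacks_per_day": attacks * 0.5}),
        Scenario("4.11 CH attacks per day (150 % of baseline)",
                 {"clinical.baseline_attacks_per_day": attacks * 1.5}),
        Scenario("Utilization (cost) of attack-ending meds +25 %",
                 {"costs.med_cost_per_attack": med * 1.25}),
        Scenario("Utilization (cost) of attack-ending meds -25 %",
                 {"costs.med_cost_per_attack": med * 0.75}),
        Scenario("No frequency response considered for SPG",
                 {"clinical.initial_freq_reduction": 0.0}),
        Scenario("Average frequency reduction low (15 %)",
                 {"clinical.initial_freq_reduction": 0.15}),
        Scenario("Average frequency reduction high (50 %)",
                 {"clinical.initial_freq_reduction": 0.50}),
        Scenario("No annual change in frequency response",
                 {"clinical.annual_decline_fraction": 0.0}),
        Scenario("Double annual decline in frequency response (6.2 % absolute)",
                 {"clinical.annual_decline_fraction": 0.20}),
        Scenario("Sumatriptan s.c. for every attack (EUR 18.81 per attack)",
                 {"costs.med_cost_per_attack": 18.81}),
        Scenario("Maximum guideline medication dosages (EUR 56.66 per attack)",
                 {"costs.med_cost_per_attack": 56.66}),
        Scenario("Stimulator in revisions paid by payer",
                 {"costs.revision_device_paid_by_payer": True}),
        Scenario("Reduced timeframe of analysis 3.5 years", {"horizon_years": 3.5}),
        Scenario("Extended timeframe of analysis 7.0 years", {"horizon_years": 7.0}),
    ]


def run_table4(base: ModelParams) -> list[ScenarioResult]:
    """Run every scenario of the published sensitivity table."""
    return [run_scenario(base, s) for s in table4_scenarios(base)]


def horizon_sweep(base: ModelParams, horizons: Sequence[float]) -> list[ScenarioResult]:
    """Re-run the model over alternative analysis horizons (years)."""
    results = []
    for h in horizons:
        if h <= 0:
            raise ValueError(f"horizons must be > 0, got {h}")
        results.append(run_scenario(base, Scenario(f"{h:g}-year horizon",
                                                   {"horizon_years": float(h)})))
    return results


def results_to_frame(results: Iterable[ScenarioResult]) -> pd.DataFrame:
    """One row per (scenario, arm), euros and QALYs at full precision."""
    rows = []
    for res in results:
        for arm in (res.spg, res.control):
            rows.append({
                "scenario": res.scenario.name,
                "arm": arm.arm,
                "cost_discounted": arm.cost_discounted,
                "cost_undiscounted": arm.cost_undiscounted,
                "qaly_discounted": arm.qaly_discounted,
                "qaly_undiscounted": arm.qaly_undiscounted,
            })
    return pd.DataFrame(rows)


def summary_frame(results: Iterable[ScenarioResult]) -> pd.DataFrame:
    """Sensitivity-table view: scenario, ICER (or dominance) and cost difference.

    Euros are rounded to integers at this reporting boundary only.
    """
    rows = []
    for res in results:
        dominating = res.ce.verdict == "spg_dominating"
        rows.append({
            "scenario": res.scenario.name,
            "icer_eur_per_qaly": ("SPG dominating" if dominating
                                  else None if res.ce.icer is None
                                  else round(res.ce.icer)),
            "delta_cost_eur": round(res.ce.delta_cost),
            "delta_qaly": round(res.ce.delta_qaly, 3),
            "verdict": res.ce.verdict,
        })
    return pd.DataFrame(rows)


def write_results(results: Sequence[ScenarioResult], outdir: str | Path) -> dict[str, Path]:
    """Write the per-arm CSV, the summary CSV and a JSON summary to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "arms": outdir / "arm_results.csv",
        "summary": outdir / "scenario_summary.csv",
        "json": outdir / "scenario_summary.json",
    }
    results_to_frame(results).to_csv(paths["arms"], index=False)
    summary = summary_frame(results)
    summary.to_csv(paths["summary"], index=False)
    payload = [
        {"scenario": r.scenario.name,
         "delta_cost": r.ce.delta_cost,
         "delta_qaly": r.ce.delta_qaly,
         "icer": r.ce.icer,
         "verdict": r.ce.verdict}
        for r in results
    ]
    paths["json"].write_text(json.dumps(payload, indent=2))
    return paths
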