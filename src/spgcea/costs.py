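"""Expected costs per arm: up-front stimulation costs and medication streams.

The control arm pays for abortive medication for every attack at the
constant baseline frequency.  The stimulation arm pays the expected
up-front stack (implantation DRG, device, imaging, titration visits, and
expectation-weighted revision / infection / explant costs) at time zero,
and abortive medication only for the residual attacks — those neither
prevented by the prophylactic effect nor relieved within 15 minutes by
stimulation.  The prophylactic effect is a yearly step function declining
by a fixed relative fraction of the initial effect each year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import DAYS_PER_YEAR, ClinicalParams, CostParams, ModelParams

ARMS = ("spg", "control")


@dataclass(frozen=True)
class AnnualCostStream:
    """Undiscounted medication cost per model year, plus any time-zero cost.

    The final entry is prorated linearly when the horizon is fractional.
    """

    arm: str
    per_year_cost: tuple[float, ...]
    upfront_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.arm == "control" and self.upfront_cost != 0.0:
            raise ValueError("control arm carries no up-front cost")
        if any(c < 0 for c in self.per_year_cost) or self.upfront_cost < 0:
            raise ValueError("cost entries must be >= 0")

    @property
    def total(self) -> float:
        return self.upfront_cost + sum(self.per_year_cost)


def expected_upfront_cost(costs: CostParams) -> float:
    """Expected time-zero cost of adopting stimulation, per patient.

    Complications enter as probability-weighted expectations; the revision
    DRG is always payer-paid, the replacement device only when
    ``revision_device_paid_by_payer`` is set.
    """
    revision = costs.revision_drg
    if costs.revision_device_paid_by_payer:
        revision += costs.device_cost
    return (costs.implant_drg + costs.device_cost + costs.imaging_cost
            + costs.titration_visits_cost
            + costs.revision_prob * revision
            + costs.infection_prob * costs.antibiotics_cost
            + costs.explant_prob * costs.explant_cost)


def freq_reduction_at_year(year_index: int, clinical: ClinicalParams) -> float:
    """Prophylactic attack-frequency reduction in force during model year ``year_index``.

    Year 1 carries the full initial effect; each later year loses
    ``annual_decline_fraction`` of the initial effect (a relative decline,
    so the absolute per-year loss scales with the initial effect), clamped
    at zero for long horizons.
    """
    if year_index < 1:
        raise ValueError(f"year_index must be >= 1, got {year_index}")
    decline = clinical.annual_decline_fraction * (year_index - 1)
    return max(0.0, clinical.initial_freq_reduction * (1.0 - decline))


def annual_medication_cost(year_index: int, arm: str, params: ModelParams) -> float:
    """Undiscounted abortive-medication cost for one full model year."""
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")
    clinical = params.clinical
    base = (clinical.baseline_attacks_per_day * DAYS_PER_YEAR
            * params.costs.med_cost_per_attack)
    if arm == "control":
        return base
    reduction = freq_reduction_at_year(year_index, clinical)
    return base * (1.0 - reduction) * (1.0 - clinical.pain_relief_prob)


def build_cost_streams(params: ModelParams) -> tuple[AnnualCostStream, AnnualCostStream]:
    """Per-year undiscounted cost streams, ``(stimulation, control)``."""
    horizon = params.horizon_years
    n_years = math.ceil(horizon - 1e-12)
    spg, control = [], []
    for year in range(1, n_years + 1):
        length = min(1.0, horizon - (year - 1))
        spg.append(annual_medication_cost(year, "spg", params) * length)
        control.append(annual_medication_cost(year, "control", params) * length)
    return (AnnualCostStream("spg", tuple(spg), expected_upfront_cost(params.costs)),
            AnnualCostStream("control", tuple(control)))
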