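"""Deterministic cohort model: discounted totals per arm and the ICER.

Costs and QALYs accrue as continuous flows on a grid of 4-week cycles
(split at model-year boundaries so the yearly step functions for the
prophylactic effect and the QALY gain apply exactly).  Each interval's
flow is discounted at a single time point per the configured timing; the
stimulation arm's up-front cost sits at time zero, undiscounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import costs as cost_engine
from . import effects as effect_engine
from .params import DAYS_PER_YEAR, DiscountSpec, ModelParams

VERDICTS = ("icer", "spg_dominating", "spg_dominated", "equal")


@dataclass(frozen=True)
class ArmResult:
    """Discounted and undiscounted cost and QALY totals for one arm."""

    arm: str
    cost_discounted: float
    cost_undiscounted: float
    qaly_discounted: float
    qaly_undiscounted: float


@dataclass(frozen=True)
class CEResult:
    """Incremental result, stimulation minus control.

    ``icer`` is the incremental cost per QALY gained; it is ``None`` when a
    dominance verdict applies or when the QALY difference is zero.
    """

    delta_cost: float
    delta_qaly: float
    icer: float | None
    verdict: str


@dataclass(frozen=True)
class ModelOutput:
    spg: ArmResult
    control: ArmResult
    ce: CEResult


def discount_factor(t: float | np.ndarray, spec: DiscountSpec) -> float | np.ndarray:
    """Present-value factor ``(1 + rate)^-t`` for time ``t`` in years."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("discounting requires t >= 0")
    return (1.0 + spec.annual_rate) ** (-np.asarray(t, dtype=float))


def _interval_pv_weights(t0: np.ndarray, t1: np.ndarray, spec: DiscountSpec,
                         timing: str) -> np.ndarray:
    """Discount weight applied to a flow spread uniformly over [t0, t1)."""
    if spec.annual_rate == 0.0:
        return np.ones_like(t0)
    if timing == "start":
        return discount_factor(t0, spec)
    if timing == "midpoint":
        return discount_factor((t0 + t1) / 2.0, spec)
    if timing == "end":
        return discount_factor(t1, spec)
    # exact integral of the discount curve over the interval
    log1p = math.log1p(spec.annual_rate)
    return (discount_factor(t0, spec) - discount_factor(t1, spec)) / (log1p * (t1 - t0))


def _time_grid(horizon_years: float, cycle_length_days: float) -> tuple[np.ndarray, np.ndarray]:
    """Interval edges: 4-week cycles split at year boundaries and the horizon."""
    cycle = cycle_length_days / DAYS_PER_YEAR
    n_cycles = int(math.floor(horizon_years / cycle + 1e-9))
    edges = np.arange(n_cycles + 1) * cycle
    years = np.arange(1.0, horizon_years, 1.0)
    edges = np.unique(np.concatenate((edges, years, [0.0, horizon_years])))
    edges = edges[edges <= horizon_years + 1e-12]
    return edges[:-1], edges[1:]


def run_model(params: ModelParams, mode: str = "calibrated") -> ModelOutput:
    """Run both arms over the horizon and form the incremental result.

    ``mode`` selects the stimulation arm's QALY route (see
    :mod:`spgcea.effects`).
    """
    spec = params.discount
    t0, t1 = _time_grid(params.horizon_years, spec.cycle_length_days)
    dur = t1 - t0
    year = np.minimum(np.floor((t0 + t1) / 2.0).astype(int) + 1,
                      math.ceil(params.horizon_years - 1e-12))

    n_years = int(year.max())
    spg_med = np.array([cost_engine.annual_medication_cost(y, "spg", params)
                        for y in range(1, n_years + 1)])[year - 1]
    ctrl_med = cost_engine.annual_medication_cost(1, "control", params)
    spg_qaly = np.array([effect_engine.annual_qaly("spg", y, params, mode)
                         / min(1.0, params.horizon_years - (y - 1))
                         for y in range(1, n_years + 1)])[year - 1]
    ctrl_qaly = params.utility.baseline_utility

    w_main = _interval_pv_weights(t0, t1, spec, spec.timing)
    w_med = _interval_pv_weights(t0, t1, spec, spec.stim_med_timing)
    upfront = cost_engine.expected_upfront_cost(params.costs)

    # undiscounted totals reuse the identical cycle flows (with unit weights)
    # so a zero discount rate reproduces them bit-for-bit
    ones = np.ones_like(dur)
    spg = ArmResult(
        arm="spg",
        cost_discounted=upfront + float(np.sum(spg_med * dur * w_med)),
        cost_undiscounted=upfront + float(np.sum(spg_med * dur * ones)),
        qaly_discounted=float(np.sum(spg_qaly * dur * w_main)),
        qaly_undiscounted=float(np.sum(spg_qaly * dur * ones)),
    )
    control = ArmResult(
        arm="control",
        cost_discounted=float(np.sum(ctrl_med * dur * w_main)),
        cost_undiscounted=float(np.sum(ctrl_med * dur * ones)),
        qaly_discounted=float(np.sum(ctrl_qaly * dur * w_main)),
        qaly_undiscounted=float(np.sum(ctrl_qaly * dur * ones)),
    )
    return ModelOutput(spg=spg, control=control, ce=icer(spg, control))


def icer(spg: ArmResult, control: ArmResult) -> CEResult:
    """Incremental cost-effectiveness of stimulation vs control (discounted).

    Dominance verdicts follow the usual cost-effectiveness-plane quadrants:
    cheaper and more effective dominates (no ICER is quoted), dearer and
    less effective is dominated.  Zero QALY difference yields a verdict
    without an ICER value.
    """
    delta_cost = spg.cost_discounted - control.cost_discounted
    delta_qaly = spg.qaly_discounted - control.qaly_discounted
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return CEResult(0.0, 0.0, None, "equal")
    if delta_qaly == 0.0:
        verdict = "spg_dominated" if delta_cost > 0 else "spg_dominating"
        return CEResult(delta_cost, 0.0, None, verdict)
    if delta_cost < 0.0 and delta_qaly > 0.0:
        return CEResult(delta_cost, delta_qaly, None, "spg_dominating")
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return CEResult(delta_cost, delta_qaly, delta_cost / delta_qaly, "spg_dominated")
    return CEResult(delta_cost, delta_qaly, delta_cost / delta_qaly, "icer")
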