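"""Cohort model: discounting, arm totals, ICER verdicts."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spgcea import (
    ArmResult,
    apply_overrides,
    discount_factor,
    icer,
    run_model,
)
from spgcea.model import _interval_pv_weights, _time_grid
from spgcea.params import DAYS_PER_YEAR


def _arm(cost, qaly, arm="spg"):
    return ArmResult(arm, cost, cost, qaly, qaly)


class TestDiscountFactor:
    def test_time_zero(self, base_params):
        assert discount_factor(0.0, base_params.discount) == 1.0

    def test_zero_rate(self, base_params):
        spec = dataclasses.replace(base_params.discount, annual_rate=0.0)
        assert discount_factor(7.3, spec) == 1.0

    def test_negative_time_rejected(self, base_params):
        with pytest.raises(ValueError):
            discount_factor(-0.1, base_params.discount)

    def test_five_year_constant_flow_ratio(self, base_params):
        # the published tables imply discounted/undiscounted ~ 41,298/44,475
        t0, t1 = _time_grid(5.0, 28.0)
        w = _interval_pv_weights(t0, t1, base_params.discount, "end")
        ratio = float(np.sum((t1 - t0) * w)) / 5.0
        assert ratio == pytest.approx(41298 / 44475, rel=3e-3)

    def test_annuity_factor_pins_convention(self, base_params):
        t0, t1 = _time_grid(5.0, 28.0)
        w = _interval_pv_weights(t0, t1, base_params.discount, "end")
        assert float(np.sum((t1 - t0) * w)) == pytest.approx(41298 / 8895.08, rel=3e-3)

    def test_timing_ordering(self, base_params):
        t0, t1 = _time_grid(3.0, 28.0)
        spec = base_params.discount
        start = np.sum((t1 - t0) * _interval_pv_weights(t0, t1, spec, "start"))
        mid = np.sum((t1 - t0) * _interval_pv_weights(t0, t1, spec, "midpoint"))
        cont = np.sum((t1 - t0) * _interval_pv_weights(t0, t1, spec, "continuous"))
        end = np.sum((t1 - t0) * _interval_pv_weights(t0, t1, spec, "end"))
        assert start > cont > end
        assert start > mid > end
        assert mid == pytest.approx(cont, rel=1e-5)


class TestRunModel:
    def test_base_case_arm_totals(self, base_params):
        out = run_model(base_params)
        assert out.spg.cost_discounted == pytest.approx(42187, rel=1e-3)
        assert out.control.cost_discounted == pytest.approx(41298, rel=1e-3)
        assert out.ce.delta_cost == pytest.approx(889, rel=0.01)
        assert out.ce.delta_qaly == pytest.approx(0.325, rel=0.01)
        assert out.ce.icer == pytest.approx(2736, rel=0.01)

    def test_zero_rate_reproduces_undiscounted_exactly(self, base_params):
        p = apply_overrides(base_params, {"discount.annual_rate": 0.0})
        out = run_model(p)
        for arm in (out.spg, out.control):
            assert arm.cost_discounted == arm.cost_undiscounted
            assert arm.qaly_discounted == arm.qaly_undiscounted

    def test_discounted_below_undiscounted_at_positive_rate(self, base_params):
        out = run_model(base_params)
        for arm in (out.spg, out.control):
            assert arm.cost_discounted < arm.cost_undiscounted
            assert arm.qaly_discounted < arm.qaly_undiscounted

    def test_totals_additive_against_brute_force_cycle_sum(self, base_params):
        """Oracle: explicit python loop over 28-day cycles, control arm."""
        p = base_params
        rate = (p.clinical.baseline_attacks_per_day * DAYS_PER_YEAR
                * p.costs.med_cost_per_attack)
        cycle = 28.0 / DAYS_PER_YEAR
        boundaries = sorted(
            {k * cycle for k in range(int(p.horizon_years / cycle) + 1)}
            | {float(y) for y in range(1, math.ceil(p.horizon_years))}
            | {0.0, p.horizon_years})
        total = 0.0
        for t, t_next in zip(boundaries, boundaries[1:]):
            total += rate * (t_next - t) * 1.03 ** (-t_next)
        out = run_model(p)
        assert out.control.cost_discounted == pytest.approx(total, rel=1e-9)

    def test_undiscounted_totals_match_annual_streams(self, base_params):
        from spgcea import build_cost_streams, build_qaly_streams
        out = run_model(base_params)
        spg_c, ctrl_c = build_cost_streams(base_params)
        spg_q, ctrl_q = build_qaly_streams(base_params)
        assert out.spg.cost_undiscounted == pytest.approx(spg_c.total, rel=1e-12)
        assert out.control.cost_undiscounted == pytest.approx(ctrl_c.total, rel=1e-12)
        assert out.spg.qaly_undiscounted == pytest.approx(spg_q.total, rel=1e-12)
        assert out.control.qaly_undiscounted == pytest.approx(ctrl_q.total, rel=1e-12)

    def test_interpolated_mode_stays_close_to_calibrated(self, base_params):
        cal = run_model(base_params, mode="calibrated")
        itp = run_model(base_params, mode="interpolated")
        assert itp.ce.delta_qaly == pytest.approx(cal.ce.delta_qaly, abs=0.02)
        assert itp.spg.cost_discounted == cal.spg.cost_discounted

    def test_sub_year_horizon(self, base_params):
        p = apply_overrides(base_params, {"horizon_years": 0.5})
        out = run_model(p)
        assert out.control.cost_undiscounted == pytest.approx(0.5 * 8895.08, abs=0.01)

    @settings(max_examples=20, deadline=None)
    @given(k=st.floats(0.1, 10))
    def test_icer_scale_consistency(self, base_params, k):
        """Multiplying all costs by k multiplies delta_cost and the ICER by k."""
        out = run_model(base_params)
        paths = ("med_cost_per_attack", "implant_drg", "device_cost", "imaging_cost",
                 "titration_visits_cost", "revision_drg", "antibiotics_cost",
                 "explant_cost")
        scaled = apply_overrides(base_params, {
            f"costs.{name}": getattr(base_params.costs, name) * k for name in paths})
        out_k = run_model(scaled)
        assert out_k.ce.delta_cost == pytest.approx(k * out.ce.delta_cost, rel=1e-9)
        assert out_k.ce.icer == pytest.approx(k * out.ce.icer, rel=1e-9)


class TestIcerVerdicts:
    def test_dominating(self):
        ce = icer(_arm(99.0, 2.0), _arm(100.0, 1.9, "control"))
        assert ce.verdict == "spg_dominating"
        assert ce.icer is None

    def test_dominated(self):
        ce = icer(_arm(101.0, 1.0), _arm(100.0, 1.9, "control"))
        assert ce.verdict == "spg_dominated"

    def test_equal(self):
        ce = icer(_arm(100.0, 1.0), _arm(100.0, 1.0, "control"))
        assert ce.verdict == "equal"
        assert ce.icer is None

    def test_zero_qaly_delta_reports_verdict_without_icer(self):
        ce = icer(_arm(101.0, 1.0), _arm(100.0, 1.0, "control"))
        assert ce.icer is None
        assert ce.verdict == "spg_dominated"

    def test_plain_icer_quadrant(self):
        ce = icer(_arm(110.0, 2.0), _arm(100.0, 1.0, "control"))
        assert ce.verdict == "icer"
        assert ce.icer == pytest.approx(10.0)

    def test_dominance_iff_sign_pattern(self):
        ce = icer(_arm(99.0, 0.5), _arm(100.0, 1.0, "control"))  # cheaper, worse
        assert ce.verdict == "icer"
        assert ce.icer == pytest.approx(2.0)  # savings per QALY forgone
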