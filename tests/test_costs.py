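"""Cost streams, net costs, and ICER classification."""

import numpy as np
import pytest

from tfaban.costs import (CE_THRESHOLD_AUD_PER_HALY, build_policy_costs,
                          compute_icer, discount_stream,
                          healthcare_cost_delta)
from tfaban.costs_util import annuity_factor
from tfaban.inputs import AGES, CostInputs
from tfaban.lifetable import LifeTableOutcome


def make_cost_inputs(ihd_unit=5_000.0, other_unit=0.0, **overrides):
    kwargs = dict(
        ihd_cost_per_prevalent_case={s: np.full(AGES.size, float(ihd_unit))
                                     for s in ("male", "female")},
        other_healthcare_cost_per_person={s: np.full(AGES.size, float(other_unit))
                                          for s in ("male", "female")},
        legislation_mean=1_090_000.0, legislation_sd=77_497.0,
        monitoring_annual=1_557_422.0, reformulation_initial=6_010_391.0,
    )
    kwargs.update(overrides)
    return CostInputs(**kwargs)


def make_outcome(person_years, prevalent_py, sex="male", entry_age=60):
    """Minimal hand-built trajectory for cost-delta arithmetic."""
    py = np.asarray(person_years, dtype=float)
    pp = np.asarray(prevalent_py, dtype=float)
    n = py.size
    z = np.zeros(n)
    return LifeTableOutcome(
        sex=sex, subgroup="total", entry_age=entry_age, label="toy",
        ages=np.arange(entry_age, entry_age + n),
        alive_start=py, alive_end=py, prevalent_start=pp, prevalent_end=pp,
        incident_cases=z, ihd_deaths=z, other_deaths=z,
        person_years=py, prevalent_person_years=pp,
        yld_all_cause=z, ihd_disability_weight=0.0,
    )


class TestDiscountStream:
    def test_no_discounting(self):
        assert discount_stream(np.ones(10), 0.0) == pytest.approx(10.0)

    def test_annuity_closed_form(self):
        # ten years of 1.0 from year 1 at 3%: (1 - 1.03^-10) / 0.03
        expected = (1 - 1.03**-10) / 0.03
        assert discount_stream(np.ones(10), 0.03) == pytest.approx(expected)
        assert discount_stream(np.ones(10), 0.03) == pytest.approx(8.5302, abs=1e-4)
        assert annuity_factor(0.03, 10) == pytest.approx(expected)

    def test_year_zero_payment_is_face_value(self):
        for rate in (0.0, 0.03, 0.06):
            assert discount_stream([5.0], rate, first_year=0) == pytest.approx(5.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            discount_stream([1.0], -0.01)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_present_value_non_increasing_in_rate(self, seed):
        values = np.random.default_rng(seed).uniform(0, 100, size=30)
        pvs = [discount_stream(values, r) for r in (0.0, 0.01, 0.03, 0.06, 0.10)]
        assert all(a >= b for a, b in zip(pvs, pvs[1:]))


class TestPolicyCosts:
    def test_one_off_component_arithmetic(self):
        stream = build_policy_costs(make_cost_inputs(), horizon=10, rate=0.03)
        assert stream.repackaging == pytest.approx(0.10 * 6_010_391)
        assert stream.repackaging == pytest.approx(601_039, abs=0.5)
        # annual industry cost: 1% of the initial reformulation, per year
        per_year = stream.annual_industry / annuity_factor(0.03, 10)
        assert per_year == pytest.approx(60_104, abs=0.5)
        assert stream.reformulation_initial == pytest.approx(6_010_391)

    def test_totals_are_sums_of_components(self):
        stream = build_policy_costs(make_cost_inputs(), horizon=10, rate=0.03)
        assert stream.total == pytest.approx(
            stream.legislation + stream.monitoring + stream.reformulation_initial
            + stream.repackaging + stream.annual_industry)
        assert stream.total == pytest.approx(stream.government + stream.industry)

    def test_doubled_products_doubles_industry_components_exactly(self):
        base = build_policy_costs(make_cost_inputs(), 10, 0.03)
        doubled = build_policy_costs(make_cost_inputs(), 10, 0.03,
                                     variant="doubled_products")
        assert doubled.reformulation_initial == 2 * base.reformulation_initial
        assert doubled.repackaging == 2 * base.repackaging
        assert doubled.annual_industry == 2 * base.annual_industry
        assert doubled.government == base.government

    def test_no_industry_costs_variant(self):
        stream = build_policy_costs(make_cost_inputs(), 10, 0.03,
                                    variant="no_industry_costs")
        assert stream.industry == 0.0
        assert stream.government > 0.0

    def test_monitoring_variant(self):
        base = build_policy_costs(make_cost_inputs(), 10, 0.03)
        up = build_policy_costs(make_cost_inputs(), 10, 0.03,
                                variant="monitoring_plus_25pct")
        assert up.monitoring == pytest.approx(1.25 * base.monitoring)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_policy_costs(make_cost_inputs(), 10, 0.03, variant="bogus")

    def test_legislation_draw_injection(self):
        stream = build_policy_costs(make_cost_inputs(), 10, 0.03,
                                    legislation_cost=2e6)
        assert stream.legislation == 2e6


class TestHealthcareCostDelta:
    def test_identical_outcomes_zero_delta(self):
        out = make_outcome([100, 99], [10, 11])
        ihd, total = healthcare_cost_delta(out, out, make_cost_inputs(), 0.03)
        assert ihd == total == 0.0

    def test_prevalent_case_year_arithmetic(self):
        # 10 fewer prevalent case-years for one year at 5,000 AUD, undiscounted
        ref = make_outcome([100.0], [20.0])
        arm = make_outcome([100.0], [10.0])
        ihd, total = healthcare_cost_delta(ref, arm, make_cost_inputs(), 0.0)
        assert ihd == pytest.approx(-50_000.0)
        assert total == pytest.approx(-50_000.0)

    def test_added_life_years_can_cost_more_than_ihd_savings(self):
        ref = make_outcome([100.0], [20.0])
        arm = make_outcome([110.0], [10.0])  # more survivors, fewer cases
        costs = make_cost_inputs(ihd_unit=5_000.0, other_unit=20_000.0)
        ihd, total = healthcare_cost_delta(ref, arm, costs, 0.0)
        assert ihd < 0
        assert total > 0  # unrelated costs of added person-years dominate


class TestComputeIcer:
    def test_cost_effective_arithmetic(self):
        res = compute_icer(10_000_000.0, 5_000.0)
        assert res.icer == pytest.approx(2_000.0)
        assert res.classification == "cost_effective"
        assert not res.dominant

    def test_negative_net_cost_is_dominant(self):
        res = compute_icer(-1.0, 100.0)
        assert res.dominant
        assert res.classification == "cost_saving"

    def test_threshold_boundary_is_strict(self):
        halys = 100.0
        res = compute_icer(CE_THRESHOLD_AUD_PER_HALY * halys, halys)
        assert res.classification == "not_cost_effective"
        res = compute_icer(CE_THRESHOLD_AUD_PER_HALY * halys - 1.0, halys)
        assert res.classification == "cost_effective"

    def test_nonpositive_halys_flagged_not_raised(self):
        res = compute_icer(1000.0, 0.0)
        assert res.classification == "undefined"
        assert np.isnan(res.icer)


def test_net_cost_identity_on_full_pipeline(bundle):
    """Net cost decomposes exactly into policy total plus healthcare delta."""
    from tfaban.pipeline import Scenario, evaluate

    res = evaluate(bundle, Scenario())
    for horizon in (10, None):
        hr = res.horizon(horizon)
        assert hr.net_cost == pytest.approx(
            hr.policy.total + hr.total_cost_delta, rel=1e-12)
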