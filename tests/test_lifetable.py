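"""Life-table engine: conservation, closed forms, and a microsimulation oracle."""

import numpy as np
import pytest

from tfaban.lifetable import (LifeTableOutcome, ScenarioSpec, diff_outcomes,
                              run_cohort)
from tests.conftest import make_rates

BAND = (60, 64)
ENTRY = 62
REF = ScenarioSpec(label="reference")


def intervention_spec(pif, sex="male", subgroup="total", rate=0.03):
    return ScenarioSpec(label="intervention",
                        pif_by_stratum={(sex, BAND, subgroup): pif},
                        discount_rate=rate)


def test_zero_rates_conserve_the_cohort():
    rates = make_rates()
    out = run_cohort(ENTRY, "male", "total", rates, 1000.0, REF, band=BAND)
    assert np.all(out.alive_end == 1000.0)
    assert np.all(out.total_deaths == 0.0)
    # 10 undiscounted person-years per survivor over a 10-year horizon
    assert out.life_years(rate=0.0, horizon=10) == pytest.approx(10_000.0)


def test_person_year_conservation_every_cycle(bundle):
    rates = bundle.rates[("female", "total")]
    out = run_cohort(42, "female", "total", rates, 5_000.0, REF, band=(40, 44))
    np.testing.assert_allclose(out.alive_start - out.total_deaths,
                               out.alive_end, rtol=1e-12)
    np.testing.assert_allclose(out.alive_start[1:], out.alive_end[:-1],
                               rtol=1e-12)
    # cumulative form: entrants minus all deaths so far
    np.testing.assert_allclose(
        out.alive_end, out.alive_start[0] - np.cumsum(out.total_deaths),
        rtol=1e-9)


def test_null_intervention_reproduces_reference(bundle):
    rates = bundle.rates[("male", "total")]
    ref = run_cohort(ENTRY, "male", "total", rates, 1000.0, REF, band=BAND)
    null = run_cohort(ENTRY, "male", "total", rates, 1000.0,
                      intervention_spec(0.0), band=BAND)
    np.testing.assert_array_equal(ref.alive_end, null.alive_end)
    delta = diff_outcomes(ref, null, horizon=None)
    assert delta.deaths_averted == delta.events_averted == 0.0
    assert delta.ly_gained == delta.haly_gained == 0.0


def test_constant_mortality_matches_geometric_closed_form():
    """No disease, constant mortality m: survivors decay geometrically, so
    discounted person-years have a closed form (with half-cycle weights)."""
    m, r, n0 = 0.1, 0.03, 1.0
    rates = make_rates(acm=m)
    out = run_cohort(ENTRY, "male", "total", rates, n0, REF, band=BAND)
    T = 100 - ENTRY
    t = np.arange(1, T + 1)
    survivors = (1 - m) ** t
    expected = np.sum(((1 - m) ** (t - 1) + survivors) / 2 / (1 + r) ** t)
    assert out.life_years(rate=r) == pytest.approx(expected, rel=1e-12)


def test_intervention_never_loses_life_years(bundle):
    rates = bundle.rates[("male", "total")]
    ref = run_cohort(ENTRY, "male", "total", rates, 1000.0, REF, band=BAND)
    for pif in (0.05, 0.2, 0.5, 0.9):
        arm = run_cohort(ENTRY, "male", "total", rates, 1000.0,
                         intervention_spec(pif), band=BAND)
        delta = diff_outcomes(ref, arm, horizon=None)
        assert delta.ly_gained >= 0.0
        assert delta.deaths_averted >= 0.0


def test_haly_equals_ly_without_disability():
    rates = make_rates(acm=0.02, incidence=0.01, prevalence=0.05,
                       case_fatality=0.1, yld=0.0, dw=0.0)
    ref = run_cohort(ENTRY, "male", "total", rates, 1000.0, REF, band=BAND)
    arm = run_cohort(ENTRY, "male", "total", rates, 1000.0,
                     intervention_spec(0.3), band=BAND)
    assert ref.halys(rate=0.03) == pytest.approx(ref.life_years(rate=0.03))
    delta = diff_outcomes(ref, arm, horizon=None, discount_rate=0.03)
    assert delta.haly_gained == pytest.approx(delta.ly_gained, rel=1e-12)


def test_discount_monotonicity_of_haly_gains(bundle):
    rates = bundle.rates[("male", "total")]
    ref = run_cohort(ENTRY, "male", "total", rates, 1000.0, REF, band=BAND)
    arm = run_cohort(ENTRY, "male", "total", rates, 1000.0,
                     intervention_spec(0.3), band=BAND)
    gains = [diff_outcomes(ref, arm, None, rate).haly_gained
             for rate in (0.0, 0.03, 0.06)]
    assert gains[0] >= gains[1] >= gains[2]
    assert gains[0] > gains[2]  # strictly, for a real intervention


def test_mismatched_cohorts_rejected(bundle):
    rates = bundle.rates[("male", "total")]
    a = run_cohort(62, "male", "total", rates, 1000.0, REF, band=(60, 64))
    b = run_cohort(67, "male", "total", rates, 1000.0, REF, band=(65, 69))
    with pytest.raises(ValueError, match="different cohorts"):
        diff_outcomes(a, b)


def test_two_year_toy_matches_hand_calculation():
    """A 2-year cohort worked by hand: incidence halved by the intervention.

    Constant rates: incidence 0.10, case fatality 0.20, all-cause mortality
    0.05, prevalence 0.10 (so baseline IHD mortality 0.02, other-cause
    0.03), YLD 0.10, IHD disability weight 0.20, 1,000 entrants, 0%
    discounting over a 2-year horizon.
    """
    rates = make_rates(acm=0.05, incidence=0.10, prevalence=0.10,
                       case_fatality=0.20, yld=0.10, dw=0.20)

    def hand(inc):
        healthy, sick = 900.0, 100.0
        other = 0.05 - 0.10 * 0.20  # 0.03
        events = deaths = ly = prev_py = 0.0
        for _ in range(2):
            h0, s0 = healthy, sick
            new = healthy * inc
            healthy -= new
            sick += new
            d_ihd = sick * 0.20
            sick -= d_ihd
            d_oth = (healthy + sick) * other
            healthy *= 1 - other
            sick *= 1 - other
            events += new
            deaths += d_ihd
            ly += (h0 + s0 + healthy + sick) / 2
            prev_py += (s0 + sick) / 2
        return events, deaths, ly, prev_py

    e_ref, d_ref, ly_ref, pp_ref = hand(0.10)
    e_int, d_int, ly_int, pp_int = hand(0.05)

    ref = run_cohort(ENTRY, "male", "total", rates, 1000.0, REF, band=BAND)
    arm = run_cohort(ENTRY, "male", "total", rates, 1000.0,
                     intervention_spec(0.5, rate=0.0), band=BAND)
    delta = diff_outcomes(ref, arm, horizon=2, discount_rate=0.0)

    assert delta.events_averted == pytest.approx(e_ref - e_int, rel=1e-12)
    assert delta.deaths_averted == pytest.approx(d_ref - d_int, rel=1e-12)
    assert delta.ly_gained == pytest.approx(ly_int - ly_ref, rel=1e-12)
    expected_haly = (ly_int - ly_ref) * 0.9 + (pp_ref - pp_int) * 0.20
    assert delta.haly_gained == pytest.approx(expected_haly, rel=1e-12)


def microsimulate(entry_age, rates, n_persons, pif, rng):
    """Individual-level stochastic oracle with the same annual transitions.

    Returns total deaths, total (half-cycle) person-years, and the
    per-person life-year sample for standard-error estimation.
    """
    from tfaban.inputs import AGE_MIN

    T = 100 - entry_age
    i0 = entry_age - AGE_MIN
    sick = rng.random(n_persons) < rates.ihd_prevalence[i0]
    alive = np.ones(n_persons, dtype=bool)
    person_years = np.zeros(n_persons)
    inc = rates.ihd_incidence * (1 - pif)
    for t in range(T):
        i = i0 + t
        alive0 = alive.copy()
        u = rng.random(n_persons)
        new_cases = alive & ~sick & (u < inc[i])
        sick = sick | new_cases
        u = rng.random(n_persons)
        dies_ihd = alive & sick & (u < rates.ihd_case_fatality[i])
        alive = alive & ~dies_ihd
        other = max(rates.all_cause_mortality[i]
                    - rates.ihd_prevalence[i] * rates.ihd_case_fatality[i], 0.0)
        u = rng.random(n_persons)
        alive = alive & ~(u < other)
        person_years += 0.5 * (alive0.astype(float) + alive.astype(float))
    total_deaths = n_persons - alive.sum()
    return total_deaths, person_years


def test_engine_agrees_with_microsimulation(bundle):
    """Cohort engine vs a 10^5-person stochastic microsimulation."""
    rates = bundle.rates[("male", "total")]
    n = 100_000
    rng = np.random.default_rng(2024)
    deaths_mc, py = microsimulate(72, rates, n, pif=0.0, rng=rng)

    out = run_cohort(72, "male", "total", rates, float(n), REF, band=(70, 74))
    deaths_model = out.total_deaths.sum()
    ly_model = out.life_years(rate=0.0)

    p = deaths_model / n
    se_deaths = np.sqrt(n * p * (1 - p))
    assert abs(deaths_mc - deaths_model) < 3 * se_deaths

    se_ly = py.std(ddof=1) * np.sqrt(n)
    assert abs(py.sum() - ly_model) < 3 * se_ly


def test_invalid_entry_rejected():
    rates = make_rates()
    with pytest.raises(ValueError, match="entry age"):
        run_cohort(15, "male", "total", rates, 100.0, REF)
    with pytest.raises(ValueError, match="population"):
        run_cohort(42, "male", "total", rates, 0.0, REF)
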