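"""Proportional multistate life table (annual-cycle Markov cohort engine).

Each 5-year sex cohort enters at the midpoint age of its band and is
simulated in annual cycles until age 100.  Three states are tracked:
healthy, prevalent ischemic heart disease (IHD), and dead.  Per cycle, in
order: incident cases leave the healthy state at the (PIF-adjusted)
incidence rate; IHD deaths remove prevalent cases at the case-fatality
rate; other-cause mortality — the all-cause rate net of baseline IHD
mortality (prevalence x case fatality, floored at zero) — removes a
proportional share of everyone still alive.  Person-years use a half-cycle
correction (the mean of cycle-start and cycle-end occupancy).

There is no remission from the IHD state and rates carry no calendar-time
trend.  Intervention and reference runs differ only through the incidence
adjustment, so health gains emerge through lower IHD prevalence and
mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inputs import AGE_MIN, AGE_MAX, StratumRates
from .pif import adjust_incidence

#: Simulation years needed for the youngest entrants (age 20) to reach 100.
LIFETIME_YEARS = AGE_MAX - AGE_MIN


@dataclass(frozen=True)
class ScenarioSpec:
    """One model arm: a label, per-stratum PIFs, horizon, and discounting.

    The reference arm has every PIF equal to zero.  ``horizon`` is a year
    count (10 for the short horizon) or ``None`` for the population
    lifetime (all cohorts simulated to age 100).
    """

    label: str = "reference"
    pif_by_stratum: dict = field(default_factory=dict)
    horizon: int | None = None
    discount_rate: float = 0.03

    def pif_for(self, sex: str, band: tuple[int, int], subgroup: str) -> float:
        return float(self.pif_by_stratum.get((sex, band, subgroup), 0.0))


@dataclass
class LifeTableOutcome:
    """Per-year trajectories for one cohort under one scenario.

    Arrays are indexed by simulation year (year 1 is the first annual
    cycle).  ``person_years`` and ``prevalent_person_years`` are
    half-cycle-corrected occupancy; counts (incident cases, deaths) are
    cycle totals.
    """

    sex: str
    subgroup: str
    entry_age: int
    label: str
    ages: np.ndarray                 # age at the start of each cycle
    alive_start: np.ndarray
    alive_end: np.ndarray
    prevalent_start: np.ndarray
    prevalent_end: np.ndarray
    incident_cases: np.ndarray
    ihd_deaths: np.ndarray
    other_deaths: np.ndarray
    person_years: np.ndarray
    prevalent_person_years: np.ndarray
    yld_all_cause: np.ndarray        # per-cycle all-cause YLD fraction
    ihd_disability_weight: float

    @property
    def n_years(self) -> int:
        return self.ages.size

    @property
    def total_deaths(self) -> np.ndarray:
        return self.ihd_deaths + self.other_deaths

    def _slice(self, horizon: int | None) -> slice:
        n = self.n_years if horizon is None else min(horizon, self.n_years)
        return slice(0, n)

    def discount_factors(self, rate: float, horizon: int | None = None) -> np.ndarray:
        """Discount factors (1+r)^-t for simulation years t = 1, 2, ..."""
        s = self._slice(horizon)
        t = np.arange(1, s.stop + 1)
        return (1.0 + rate) ** -t

    def life_years(self, rate: float = 0.0, horizon: int | None = None) -> float:
        s = self._slice(horizon)
        return float(self.person_years[s] @ self.discount_factors(rate, horizon))

    def halys(self, rate: float = 0.0, horizon: int | None = None) -> float:
        """Health-adjusted life years for this arm alone (all-cause YLD
        adjustment only; the IHD disability term applies when differencing)."""
        s = self._slice(horizon)
        adj = self.person_years[s] * (1.0 - self.yld_all_cause[s])
        return float(adj @ self.discount_factors(rate, horizon))


def run_cohort(
    entry_age: int,
    sex: str,
    subgroup: str,
    rates: StratumRates,
    population: float,
    scenario: ScenarioSpec,
    band: tuple[int, int] | None = None,
) -> LifeTableOutcome:
    """Simulate one cohort from its entry age to age 100.

    ``band`` identifies the cohort's 5-year entry band for PIF lookup;
    when omitted the band containing ``entry_age`` is used.  The PIF is
    applied uniformly to incidence at every single year of age the cohort
    passes through.
    """
    if entry_age < AGE_MIN:
        raise ValueError(f"entry age must be >= {AGE_MIN}, got {entry_age}")
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    if band is None:
        from .inputs import band_of_age
        band = band_of_age(entry_age)
    pif = scenario.pif_for(sex, band, subgroup)

    n_years = AGE_MAX - entry_age
    acm = rates.all_cause_mortality
    inc = adjust_incidence(rates.ihd_incidence, pif)
    prev0 = rates.ihd_prevalence
    cf = rates.ihd_case_fatality
    yld = rates.yld_all_cause

    i0 = entry_age - AGE_MIN
    sick = population * float(prev0[i0])
    healthy = population - sick

    ages = np.arange(entry_age, AGE_MAX)
    out = {name: np.zeros(n_years) for name in (
        "alive_start", "alive_end", "prevalent_start", "prevalent_end",
        "incident_cases", "ihd_deaths", "other_deaths",
        "person_years", "prevalent_person_years", "yld_all_cause")}

    for t in range(n_years):
        i = i0 + t
        alive0, sick0 = healthy + sick, sick

        new_cases = healthy * float(inc[i])
        healthy -= new_cases
        sick += new_cases

        deaths_ihd = sick * float(cf[i])
        sick -= deaths_ihd

        # all-cause net of baseline IHD mortality, applied to everyone alive
        other_rate = max(float(acm[i]) - float(prev0[i]) * float(cf[i]), 0.0)
        deaths_other = (healthy + sick) * other_rate
        healthy *= 1.0 - other_rate
        sick *= 1.0 - other_rate

        alive1 = healthy + sick
        out["alive_start"][t] = alive0
        out["alive_end"][t] = alive1
        out["prevalent_start"][t] = sick0
        out["prevalent_end"][t] = sick
        out["incident_cases"][t] = new_cases
        out["ihd_deaths"][t] = deaths_ihd
        out["other_deaths"][t] = deaths_other
        out["person_years"][t] = 0.5 * (alive0 + alive1)
        out["prevalent_person_years"][t] = 0.5 * (sick0 + sick)
        out["yld_all_cause"][t] = float(yld[i])

    return LifeTableOutcome(
        sex=sex, subgroup=subgroup, entry_age=entry_age, label=scenario.label,
        ages=ages, ihd_disability_weight=rates.ihd_disability_weight, **out,
    )


@dataclass(frozen=True)
class OutcomeDelta:
    """Intervention-minus-reference gains for one cohort (or a sum of them).

    Averted deaths and events are undiscounted counts; life years and HALYs
    are discounted at the scenario rate.  The HALY gain combines the
    YLD-adjusted life-year gain with the reduction in prevalent IHD
    person-years weighted by the IHD disability weight.
    """

    deaths_averted: float
    events_averted: float
    ly_gained: float
    haly_gained: float

    def __add__(self, other: "OutcomeDelta") -> "OutcomeDelta":
        return OutcomeDelta(
            self.deaths_averted + other.deaths_averted,
            self.events_averted + other.events_averted,
            self.ly_gained + other.ly_gained,
            self.haly_gained + other.haly_gained,
        )


ZERO_DELTA = OutcomeDelta(0.0, 0.0, 0.0, 0.0)


def diff_outcomes(
    ref: LifeTableOutcome,
    intervention: LifeTableOutcome,
    horizon: int | None = None,
    discount_rate: float = 0.03,
) -> OutcomeDelta:
    """Difference two arms of the same cohort into health gains."""
    same = (
        ref.sex == intervention.sex
        and ref.subgroup == intervention.subgroup
        and ref.entry_age == intervention.entry_age
    )
    if not same:
        raise ValueError(
            f"outcomes are from different cohorts: "
            f"{(ref.sex, ref.subgroup, ref.entry_age)} vs "
            f"{(intervention.sex, intervention.subgroup, intervention.entry_age)}"
        )
    s = ref._slice(horizon)
    disc = ref.discount_factors(discount_rate, horizon)

    deaths = float(np.sum(ref.ihd_deaths[s] - intervention.ihd_deaths[s]))
    events = float(np.sum(ref.incident_cases[s] - intervention.incident_cases[s]))
    d_py = intervention.person_years[s] - ref.person_years[s]
    ly = float(d_py @ disc)
    d_prev = ref.prevalent_person_years[s] - intervention.prevalent_person_years[s]
    haly = float(
        (d_py * (1.0 - ref.yld_all_cause[s])) @ disc
        + (d_prev * ref.ihd_disability_weight) @ disc
    )
    return OutcomeDelta(deaths, events, ly, haly)
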