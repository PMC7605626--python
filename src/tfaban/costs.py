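"""Discounted cost streams, net costs, and cost-effectiveness ratios.

All money is AUD at 2010 prices.  Policy costs take an extended
health-sector perspective: government legislation (one-off, year 0) and
monitoring (annual), plus industry reformulation (one-off), repackaging
(one-off, a fraction of reformulation), and a small ongoing annual industry
cost.  One-off year-0 payments are undiscounted; recurring amounts are
discounted from year 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .costs_util import annuity_factor  # noqa: F401  (re-export convenience)
from .inputs import AGE_MIN, CostInputs
from .lifetable import LIFETIME_YEARS, LifeTableOutcome

#: Value of a statistical life year, AUD 2010; the cost-effectiveness bar.
CE_THRESHOLD_AUD_PER_HALY = 169_361.0

POLICY_VARIANTS = (
    "primary", "doubled_products", "no_industry_costs", "monitoring_plus_25pct",
)


def discount_stream(values, rate: float, first_year: int = 1) -> float:
    """Present value of a per-year stream.

    ``values[i]`` is paid in year ``first_year + i``; year-t amounts are
    discounted by (1+rate)^-t, so with the default ``first_year=1`` a
    recurring stream starts discounting immediately and a single year-0
    payment (``first_year=0``) is taken at face value.
    """
    if rate < 0:
        raise ValueError(f"discount rate must be non-negative, got {rate}")
    values = np.asarray(values, dtype=float)
    t = np.arange(first_year, first_year + values.size)
    return float(np.sum(values / (1.0 + rate) ** t))


@dataclass(frozen=True)
class PolicyCostStream:
    """Discounted policy cost components over a horizon, AUD."""

    horizon: int
    rate: float
    variant: str
    legislation: float
    monitoring: float
    reformulation_initial: float
    repackaging: float
    annual_industry: float

    @property
    def government(self) -> float:
        return self.legislation + self.monitoring

    @property
    def industry(self) -> float:
        return self.reformulation_initial + self.repackaging + self.annual_industry

    @property
    def total(self) -> float:
        return self.government + self.industry


def build_policy_costs(
    costs: CostInputs,
    horizon: int | None,
    rate: float,
    variant: str = "primary",
    legislation_cost: float | None = None,
) -> PolicyCostStream:
    """Assemble the discounted policy cost stream.

    ``legislation_cost`` injects a Monte Carlo gamma draw; when omitted the
    mean is used (deterministic mode).  The ``doubled_products`` variant
    doubles the reformulation base (and with it repackaging and the annual
    industry cost); ``no_industry_costs`` zeroes all industry components;
    ``monitoring_plus_25pct`` raises monitoring by 25%.
    """
    if variant not in POLICY_VARIANTS:
        raise ValueError(f"unknown policy cost variant {variant!r}")
    if horizon is None:
        horizon = LIFETIME_YEARS
    legislation = costs.legislation_mean if legislation_cost is None else legislation_cost

    reform = costs.reformulation_initial
    if variant == "doubled_products":
        reform *= 2.0
    monitoring_annual = costs.monitoring_annual
    if variant == "monitoring_plus_25pct":
        monitoring_annual *= 1.25
    if variant == "no_industry_costs":
        reform = 0.0

    repackaging = costs.repackaging_fraction * reform
    annual_industry = costs.annual_industry_fraction * reform

    recurring = annuity_factor(rate, horizon)
    return PolicyCostStream(
        horizon=horizon, rate=rate, variant=variant,
        legislation=float(legislation),
        monitoring=monitoring_annual * recurring,
        reformulation_initial=reform,
        repackaging=repackaging,
        annual_industry=annual_industry * recurring,
    )


def healthcare_cost_delta(
    ref: LifeTableOutcome,
    intervention: LifeTableOutcome,
    costs: CostInputs,
    rate: float,
    horizon: int | None = None,
) -> tuple[float, float]:
    """(IHD-related, total) healthcare cost change for one cohort, AUD.

    IHD-related costs attach to prevalent IHD case-years; the total adds
    the healthcare cost of all person-years lived (so extra years of life
    gained carry their unrelated healthcare costs).  Savings are negative
    (intervention minus reference).
    """
    if (ref.sex, ref.subgroup, ref.entry_age) != (
        intervention.sex, intervention.subgroup, intervention.entry_age
    ):
        raise ValueError("outcomes are from different cohorts")
    s = ref._slice(horizon)
    disc = ref.discount_factors(rate, horizon)
    idx = ref.ages[s] - AGE_MIN
    ihd_unit = costs.ihd_cost_per_prevalent_case[ref.sex][idx]
    other_unit = costs.other_healthcare_cost_per_person[ref.sex][idx]

    d_prev = intervention.prevalent_person_years[s] - ref.prevalent_person_years[s]
    d_py = intervention.person_years[s] - ref.person_years[s]
    ihd_related = float((d_prev * ihd_unit) @ disc)
    total = ihd_related + float((d_py * other_unit) @ disc)
    return ihd_related, total


@dataclass(frozen=True)
class CEAResult:
    """Net cost, health gain, and the resulting cost-effectiveness verdict."""

    horizon: int | None
    net_cost: float
    halys_gained: float
    icer: float          # AUD/HALY; nan when HALYs <= 0
    dominant: bool       # saves money while gaining health
    classification: str  # cost_saving | cost_effective | not_cost_effective | undefined


def compute_icer(
    net_cost: float,
    halys: float,
    horizon: int | None = None,
    threshold: float = CE_THRESHOLD_AUD_PER_HALY,
) -> CEAResult:
    """ICER = net cost / HALYs gained, classified against the threshold.

    Cost saving means negative net cost (dominant when HALYs are also
    gained); cost-effective means 0 <= ICER strictly below the threshold.
    Non-positive HALY gains yield an undefined ICER rather than an error.
    """
    if halys <= 0:
        return CEAResult(horizon, float(net_cost), float(halys),
                         float("nan"), False, "undefined")
    icer = net_cost / halys
    if net_cost < 0:
        cls = "cost_saving"
    elif icer < threshold:
        cls = "cost_effective"
    else:
        cls = "not_cost_effective"
    return CEAResult(horizon, float(net_cost), float(halys), float(icer),
                     net_cost < 0, cls)
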