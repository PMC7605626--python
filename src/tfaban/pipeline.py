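"""End-to-end evaluation: intake shift -> PIFs -> life tables -> costs -> ICER.

`evaluate` runs the reference arm (current trans-fat intake) and the
intervention arm (intake shifted to the post-ban distribution) over all
cohorts of one subgroup, and reduces the paired trajectories to health
gains, healthcare and policy cost changes, net cost, and the ICER for each
requested horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .costs import (CEAResult, PolicyCostStream, build_policy_costs,
                    compute_icer, healthcare_cost_delta)
from .inputs import AGE_BANDS, SEXES, ExposureDistribution, InputBundle
from .lifetable import (LifeTableOutcome, OutcomeDelta, ScenarioSpec,
                        ZERO_DELTA, diff_outcomes, run_cohort)
from .pif import PifResult, pif_distribution_shift

#: Reporting horizons: first decade and the population lifetime.
DEFAULT_HORIZONS = (10, None)


def horizon_label(horizon: int | None) -> str:
    return "lifetime" if horizon is None else f"{horizon}y"


@dataclass(frozen=True)
class Scenario:
    """An intervention definition (what changes, and how it is valued).

    ``post_mean``/``post_sd`` give the post-ban intake distribution (%E),
    equal to the theoretical-minimum-risk distribution in the primary
    scenario.  ``halve_gap`` moves each stratum's pre-intervention mean
    halfway toward the post mean (spread kept proportional).
    ``cost_variant`` selects the policy-cost variant.
    """

    label: str = "primary"
    post_mean: float = 0.50
    post_sd: float = 0.05
    discount_rate: float = 0.03
    halve_gap: bool = False
    cost_variant: str = "primary"

    def post_distribution(self) -> ExposureDistribution:
        return ExposureDistribution(self.post_mean, self.post_sd, role="post")


@dataclass(frozen=True)
class HorizonResult:
    horizon: int | None
    delta: OutcomeDelta
    ihd_cost_delta: float
    total_cost_delta: float
    policy: PolicyCostStream
    net_cost: float
    cea: CEAResult


@dataclass
class EvalResult:
    scenario: Scenario
    subgroup: str
    pifs: dict[tuple[str, tuple[int, int]], PifResult]
    by_horizon: dict[int | None, HorizonResult]
    outcomes: list[tuple[LifeTableOutcome, LifeTableOutcome]] = field(default_factory=list)

    def horizon(self, horizon: int | None) -> HorizonResult:
        return self.by_horizon[horizon]


def compute_pifs(
    bundle: InputBundle,
    scenario: Scenario,
    subgroup: str = "total",
    rr=None,
    intake_means: Mapping[tuple[str, tuple[int, int], str], float] | None = None,
) -> dict[tuple[str, tuple[int, int]], PifResult]:
    """Per (sex, age band) potential impact fractions for one subgroup.

    ``rr`` and ``intake_means`` override the bundle's point estimates with
    Monte Carlo draws.
    """
    rrf = rr if rr is not None else bundle.rr
    post = scenario.post_distribution()
    pifs = {}
    for sex in SEXES:
        for band in AGE_BANDS:
            pre = bundle.intake(sex, band, subgroup)
            if intake_means is not None:
                key = (sex, band, subgroup)
                if key not in intake_means:
                    key = (sex, band, "total")
                if key in intake_means:
                    pre = pre.with_mean(intake_means[key])
            if scenario.halve_gap:
                pre = pre.with_mean(
                    scenario.post_mean + (pre.mean - scenario.post_mean) / 2.0
                )
            pifs[(sex, band)] = pif_distribution_shift(
                pre, post, rrf, band,
                stratum=f"{sex}/{band[0]}-{band[1]}/{subgroup}",
            )
    return pifs


def evaluate(
    bundle: InputBundle,
    scenario: Scenario,
    subgroup: str = "total",
    horizons: tuple[int | None, ...] = DEFAULT_HORIZONS,
    rr=None,
    intake_means=None,
    legislation_cost: float | None = None,
    keep_outcomes: bool = False,
) -> EvalResult:
    """Run both model arms for one subgroup and reduce to CEA results."""
    pif_results = compute_pifs(bundle, scenario, subgroup, rr=rr,
                               intake_means=intake_means)
    pif_map = {(sex, band, subgroup): res.pif
               for (sex, band), res in pif_results.items()}

    rate = scenario.discount_rate
    ref_spec = ScenarioSpec(label="reference", pif_by_stratum={},
                            horizon=None, discount_rate=rate)
    int_spec = ScenarioSpec(label=scenario.label, pif_by_stratum=pif_map,
                            horizon=None, discount_rate=rate)

    pairs: list[tuple[LifeTableOutcome, LifeTableOutcome]] = []
    for sex, band, entry_age, pop in bundle.cohorts(subgroup):
        if pop <= 0:
            continue
        rates = bundle.rates[(sex, subgroup)]
        ref = run_cohort(entry_age, sex, subgroup, rates, pop, ref_spec, band=band)
        arm = run_cohort(entry_age, sex, subgroup, rates, pop, int_spec, band=band)
        pairs.append((ref, arm))

    by_horizon: dict[int | None, HorizonResult] = {}
    for horizon in horizons:
        delta = ZERO_DELTA
        ihd_cost = total_cost = 0.0
        for ref, arm in pairs:
            delta = delta + diff_outcomes(ref, arm, horizon, rate)
            d_ihd, d_tot = healthcare_cost_delta(ref, arm, bundle.costs, rate, horizon)
            ihd_cost += d_ihd
            total_cost += d_tot
        policy = build_policy_costs(bundle.costs, horizon, rate,
                                    variant=scenario.cost_variant,
                                    legislation_cost=legislation_cost)
        net = policy.total + total_cost
        cea = compute_icer(net, delta.haly_gained, horizon)
        by_horizon[horizon] = HorizonResult(
            horizon=horizon, delta=delta, ihd_cost_delta=ihd_cost,
            total_cost_delta=total_cost, policy=policy, net_cost=net, cea=cea,
        )

    return EvalResult(
        scenario=scenario, subgroup=subgroup, pifs=pif_results,
        by_horizon=by_horizon, outcomes=pairs if keep_outcomes else [],
    )


def outcomes_frame(result: EvalResult) -> pd.DataFrame:
    """Tidy per-cohort, per-year trajectories (one row per cohort x year x arm)."""
    rows = []
    for ref, arm in result.outcomes:
        for out in (ref, arm):
            for t in range(out.n_years):
                rows.append({
                    "sex": out.sex, "subgroup": out.subgroup,
                    "entry_age": out.entry_age, "scenario": out.label,
                    "year": t + 1, "age": int(out.ages[t]),
                    "alive": out.alive_end[t],
                    "prevalent_ihd": out.prevalent_end[t],
                    "incident_ihd": out.incident_cases[t],
                    "ihd_deaths": out.ihd_deaths[t],
                    "total_deaths": out.total_deaths[t],
                    "person_years": out.person_years[t],
                })
    return pd.DataFrame(rows)


def result_record(result: EvalResult) -> dict:
    """Flatten an EvalResult into scalar outputs keyed by horizon label."""
    rec: dict = {"scenario": result.scenario.label, "subgroup": result.subgroup}
    for horizon, hr in result.by_horizon.items():
        lab = horizon_label(horizon)
        rec[lab] = {
            "deaths_averted": hr.delta.deaths_averted,
            "events_averted": hr.delta.events_averted,
            "ly_gained": hr.delta.ly_gained,
            "haly_gained": hr.delta.haly_gained,
            "ihd_healthcare_cost_delta": hr.ihd_cost_delta,
            "total_healthcare_cost_delta": hr.total_cost_delta,
            "policy_cost_total": hr.policy.total,
            "policy_cost_government": hr.policy.government,
            "policy_cost_industry": hr.policy.industry,
            "net_cost": hr.net_cost,
            "icer": hr.cea.icer,
            "classification": hr.cea.classification,
        }
    return rec
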