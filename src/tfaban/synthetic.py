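"""Synthetic input bundles emulating the model's stratified source tables.

No public accession ships the stratified intake, demography, and
epidemiology tables the model consumes, so this module generates complete,
internally consistent stand-ins: right-skewed intake distributions with a
socioeconomic gradient (higher intake in disadvantaged quintiles),
Gompertz all-cause mortality, logistic-in-age IHD incidence / prevalence /
case fatality, and subgroup rate ratios mirroring the construction used
for real data (subgroup rate = total rate x standardised ratio).  All
invariants the loader enforces hold by construction.

`published_scalars` returns the scalar inputs that *are* public — the
age-specific relative risks, the post-intervention / counterfactual intake
distribution, disability weights, and every policy cost parameter — which
the generator uses verbatim.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import inputs as mi
from .inputs import (AGE_BANDS, AGES, SEXES, SEIFA_QUINTILES,
                     REMOTENESS_GROUPS, CostInputs, ExposureDistribution,
                     InputBundle, RelativeRiskFunction, StratumRates,
                     band_midpoint, scale_subgroup_rates, _cap_case_fatality)


class GenerationError(RuntimeError):
    """The synthetic configuration cannot satisfy a model invariant."""


def published_scalars() -> dict:
    """Scalar model inputs from the published Australian analysis.

    Includes the meta-analytic age-specific relative risks per 2%E trans
    fat, the ruminant-only counterfactual intake distribution, sex-specific
    all-cause IHD disability weights, and the policy cost parameters, each
    with a provenance note naming its original source.
    """
    return {
        "pre_intake_mean_total": 0.59,  # national survey mean, %E/day
        "post_intake": {"mean": 0.50, "sd": 0.05},
        "tmred": {"mean": 0.50, "sd": 0.05},
        "tmred_sensitivity": {"mean": 0.40, "sd": 0.04},
        "relative_risk_per_2pctE": {
            "25-34": [1.42, 1.28, 1.57],
            "35-44": [1.40, 1.27, 1.54],
            "45-54": [1.33, 1.22, 1.45],
            "55-64": [1.27, 1.18, 1.36],
            "65-74": [1.22, 1.15, 1.29],
            "75+": [1.16, 1.11, 1.21],
        },
        "ihd_disability_weight": {"male": 0.0767, "female": 0.0763},
        "policy_costs": {
            "legislation_mean": 1_090_000.0,
            "legislation_sd": 77_497.0,
            "monitoring_annual": 1_557_422.0,
            "reformulation_initial": 6_010_391.0,
            "reformulation_initial_doubled": 12_020_783.0,
            "repackaging_fraction": 0.10,
            "annual_industry_fraction": 0.01,
            "n_products": 131,
        },
        "ce_threshold_aud_per_haly": 169_361.0,
        "discount_rate": 0.03,
        "n_iterations": 2000,
        "provenance": {
            "relative_risk_per_2pctE":
                "Meta-analysis of prospective cohorts (Wang et al., JAHA 2017)",
            "post_intake": "Ruminant-source TFA intake (Wu et al., Nutrients 2017)",
            "legislation": "Public-health legislation costing (Lal et al., "
                           "PLoS Med 2017); gamma-distributed",
            "monitoring": "UK estimate scaled by population ratio "
                          "(Allen et al., BMJ 2015)",
            "reformulation": "UK per-product estimate x 131 candidate products "
                             "(Allen et al., BMJ 2015)",
            "ihd_disability_weight": "GBD 2010 weighted average of MI, angina, "
                                     "and heart failure",
            "ce_threshold": "Value of a statistical life year, AUD 2010",
        },
    }


def _logistic(ages: np.ndarray, level: float, slope: float, midpoint: float) -> np.ndarray:
    return level / (1.0 + np.exp(-slope * (ages - midpoint)))


@dataclass
class SynthConfig:
    """Knobs for the synthetic bundle; defaults emulate the Australian setting."""

    seed: int = 20_201_102
    population_total: float = 16_500_000.0   # adults 20+
    female_share: float = 0.51
    #: per-year population is flat to this age then decays exponentially
    population_decay_age: float = 50.0
    population_decay_rate: float = 0.045

    intake_mean_total: float = 0.59          # %E/day, population mean
    intake_cv: float = 0.5                   # SD as a fraction of the mean
    intake_age_slope: float = -0.004         # relative change per year of age
    #: relative intake spread across quintiles, most to least disadvantaged
    quintile_intake_offsets: tuple = (0.15, 0.075, 0.0, -0.075, -0.15)
    remoteness_intake_offsets: tuple = (-0.034, 0.051, 0.102)
    jitter_sd: float = 0.01                  # lognormal table noise

    # Gompertz all-cause mortality: level * exp(slope * (age - 20))
    mortality_level: dict = field(default_factory=lambda: {
        "male": 5.5e-4, "female": 3.5e-4})
    mortality_slope: dict = field(default_factory=lambda: {
        "male": 0.092, "female": 0.095})

    # logistic-in-age IHD curves: (level, slope, midpoint age)
    incidence_params: dict = field(default_factory=lambda: {
        "male": (0.025, 0.09, 78.0), "female": (0.020, 0.09, 82.0)})
    prevalence_params: dict = field(default_factory=lambda: {
        "male": (0.18, 0.08, 72.0), "female": (0.14, 0.08, 76.0)})
    case_fatality_params: dict = field(default_factory=lambda: {
        "male": (0.10, 0.07, 85.0), "female": (0.11, 0.07, 86.0)})
    yld_params: dict = field(default_factory=lambda: {
        "male": (0.20, 0.07, 70.0), "female": (0.20, 0.07, 70.0)})
    yld_floor: float = 0.05

    subgroup_population_shares: dict = field(default_factory=lambda: {
        "seifa_q1": 0.20, "seifa_q2": 0.20, "seifa_q3": 0.20,
        "seifa_q4": 0.20, "seifa_q5": 0.20,
        "major_city": 0.68, "inner_regional": 0.18, "other_regional": 0.11,
    })
    mortality_ratios: dict = field(default_factory=lambda: {
        "seifa_q1": 1.25, "seifa_q2": 1.12, "seifa_q3": 1.00,
        "seifa_q4": 0.92, "seifa_q5": 0.82,
        "major_city": 0.97, "inner_regional": 1.08, "other_regional": 1.15,
    })
    ihd_ratios: dict = field(default_factory=lambda: {
        "seifa_q1": 1.30, "seifa_q2": 1.15, "seifa_q3": 1.00,
        "seifa_q4": 0.90, "seifa_q5": 0.78,
        "major_city": 0.96, "inner_regional": 1.10, "other_regional": 1.20,
    })

    # healthcare unit costs, AUD/year at 2010 prices
    ihd_cost_base: float = 3_500.0           # per prevalent case-year at age 20
    ihd_cost_age_slope: float = 60.0         # + AUD per year of age
    other_cost_base: float = 1_200.0         # per person-year at age 20
    other_cost_growth: float = 0.035         # exponential age growth


def _age_population(cfg: SynthConfig) -> np.ndarray:
    w = np.where(
        AGES <= cfg.population_decay_age, 1.0,
        np.exp(-cfg.population_decay_rate * (AGES - cfg.population_decay_age)),
    )
    return w / w.sum()


def _total_rates(cfg: SynthConfig, sex: str, rng: np.random.Generator,
                 scalars: dict) -> StratumRates:
    jit = lambda n: np.exp(rng.normal(0.0, cfg.jitter_sd, n))  # noqa: E731

    acm = cfg.mortality_level[sex] * np.exp(
        cfg.mortality_slope[sex] * (AGES - mi.AGE_MIN)) * jit(AGES.size)
    acm = np.minimum(np.maximum.accumulate(acm), 0.7)  # increasing, capped

    inc = _logistic(AGES, *cfg.incidence_params[sex]) * jit(AGES.size)
    inc = np.maximum.accumulate(inc)  # rising then plateauing
    prev = np.maximum.accumulate(_logistic(AGES, *cfg.prevalence_params[sex])
                                 * jit(AGES.size))
    cf = np.maximum.accumulate(_logistic(AGES, *cfg.case_fatality_params[sex])
                               * jit(AGES.size))
    level, slope, mid = cfg.yld_params[sex]
    yld = cfg.yld_floor + _logistic(AGES, level, slope, mid)

    # consistency: IHD deaths cannot exceed all-cause deaths
    with np.errstate(divide="ignore"):
        cap = np.where(prev > 0, acm / prev, np.inf)
    if np.any(cf > 2.0 * cap):
        age = int(AGES[np.argmax(cf / cap)])
        raise GenerationError(
            f"case fatality for {sex} at age {age} is inconsistent with "
            f"all-cause mortality (cf x prevalence > mortality by >2x); "
            f"lower case_fatality_params or raise mortality_level"
        )
    cf = np.minimum(cf, cap)

    rates = StratumRates(
        sex=sex, subgroup="total",
        all_cause_mortality=acm, ihd_incidence=inc, ihd_prevalence=prev,
        ihd_case_fatality=cf, yld_all_cause=np.clip(yld, 0.0, 1.0),
        ihd_disability_weight=float(scalars["ihd_disability_weight"][sex]),
    )
    rates.validate()
    return rates


def generate_bundle(config: SynthConfig | None = None) -> InputBundle:
    """Build a complete validated input bundle from a synthetic configuration.

    Deterministic under ``config.seed``.  Quintile intakes are constructed
    multiplicatively around the total-population schedule, so their
    population-weighted mean reproduces the configured total mean exactly
    (up to CSV rounding); the same holds per age-sex stratum.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    scalars = published_scalars()

    # --- intake: base age-sex schedule normalised to the configured mean ---
    age_share = _age_population(cfg)
    band_share = {
        band: float(age_share[(AGES >= band[0]) & (AGES <= band[1])].sum())
        for band in AGE_BANDS
    }
    shape: dict[tuple[str, tuple[int, int]], float] = {}
    for sex in SEXES:
        sex_factor = 1.05 if sex == "male" else 0.95
        for band in AGE_BANDS:
            mid = band_midpoint(band)
            f = sex_factor * (1.0 + cfg.intake_age_slope * (mid - 55.0))
            f *= float(np.exp(rng.normal(0.0, cfg.jitter_sd)))
            shape[(sex, band)] = max(f, 0.05)
    sex_share = {"male": 1.0 - cfg.female_share, "female": cfg.female_share}
    weighted = sum(shape[(sex, band)] * sex_share[sex] * band_share[band]
                   for sex in SEXES for band in AGE_BANDS)
    norm = cfg.intake_mean_total / weighted

    pre_intake = {}
    offsets = {"total": 0.0}
    offsets.update(dict(zip(SEIFA_QUINTILES, cfg.quintile_intake_offsets)))
    offsets.update(dict(zip(REMOTENESS_GROUPS, cfg.remoteness_intake_offsets)))
    for sex in SEXES:
        for band in AGE_BANDS:
            base = shape[(sex, band)] * norm
            for sg, off in offsets.items():
                mean = base * (1.0 + off)
                pre_intake[(sex, band, sg)] = ExposureDistribution(
                    mean=mean, sd=cfg.intake_cv * mean, role="pre")

    # --- population ---
    population = {}
    for sex in SEXES:
        total = cfg.population_total * sex_share[sex] * age_share
        population[(sex, "total")] = total
        for sg, share in cfg.subgroup_population_shares.items():
            population[(sex, sg)] = total * share

    # --- rates: totals, then ratio-derived subgroups ---
    rates = {}
    for sex in SEXES:
        total = _total_rates(cfg, sex, rng, scalars)
        rates[(sex, "total")] = total
        for sg in SEIFA_QUINTILES + REMOTENESS_GROUPS:
            strat = scale_subgroup_rates(total, cfg.mortality_ratios[sg],
                                         fields=("all_cause_mortality",),
                                         subgroup=sg)
            strat = scale_subgroup_rates(strat, cfg.ihd_ratios[sg],
                                         fields=("ihd_incidence",
                                                 "ihd_prevalence"),
                                         subgroup=sg)
            _cap_case_fatality(strat)
            strat.validate()
            rates[(sex, sg)] = strat

    # --- costs ---
    ihd_cost, other_cost = {}, {}
    for sex in SEXES:
        ihd_cost[sex] = (cfg.ihd_cost_base
                         + cfg.ihd_cost_age_slope * (AGES - mi.AGE_MIN))
        other_cost[sex] = cfg.other_cost_base * np.exp(
            cfg.other_cost_growth * (AGES - mi.AGE_MIN))
    pc = scalars["policy_costs"]
    costs = CostInputs(
        ihd_cost_per_prevalent_case=ihd_cost,
        other_healthcare_cost_per_person=other_cost,
        legislation_mean=pc["legislation_mean"],
        legislation_sd=pc["legislation_sd"],
        monitoring_annual=pc["monitoring_annual"],
        reformulation_initial=pc["reformulation_initial"],
        repackaging_fraction=pc["repackaging_fraction"],
        annual_industry_fraction=pc["annual_industry_fraction"],
        n_products=pc["n_products"],
    )

    config_block = {
        "subgroups": list(mi.SUBGROUPS),
        "relative_risk_per_2pctE": scalars["relative_risk_per_2pctE"],
        "ihd_disability_weight": scalars["ihd_disability_weight"],
        "policy_costs": {k: v for k, v in pc.items()
                         if k != "reformulation_initial_doubled"},
        "subgroup_ratios": {
            sg: {"mortality": {s: cfg.mortality_ratios[sg] for s in SEXES},
                 "ihd": {s: cfg.ihd_ratios[sg] for s in SEXES}}
            for sg in SEIFA_QUINTILES + REMOTENESS_GROUPS
        },
        "scenario": {
            "horizon": 10,
            "discount_rate": scalars["discount_rate"],
            "post_mean": scalars["post_intake"]["mean"],
            "post_sd": scalars["post_intake"]["sd"],
            "tmred_mean": scalars["tmred"]["mean"],
            "tmred_sd": scalars["tmred"]["sd"],
            "n_iterations": scalars["n_iterations"],
            "n_effective": 100,
            "seed": cfg.seed,
        },
    }

    bundle = InputBundle(
        pre_intake=pre_intake, population=population, rates=rates,
        costs=costs, rr=RelativeRiskFunction.from_mapping(
            scalars["relative_risk_per_2pctE"]),
        config=config_block,
    )
    bundle.validate()
    return bundle


def write_scalars_yaml(path: str | Path) -> Path:
    """Export the published scalar inputs as YAML."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(published_scalars(), fh, sort_keys=False)
    return path
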