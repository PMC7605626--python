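"""Model inputs: stratified tables, validation, and subgroup rate derivation.

The model is stratified three ways:

* sex — male / female cohorts;
* age — 5-year entry bands from 20-24 to 95-99 (adults only; epidemiological
  rates are carried per single year of age from 20 to 100);
* subgroup — the total population, five area-level socioeconomic (SEIFA)
  quintiles ordered from most disadvantaged (q1) to most advantaged (q5),
  and three remoteness classes.

Subgroup-specific rates are usually not available per year of age, so they
are derived by scaling the total-population rate schedule with a
subgroup-to-total ratio (standardised mortality / hospitalisation ratio),
supplied in the configuration.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

AGE_MIN = 20
AGE_MAX = 100
AGES = np.arange(AGE_MIN, AGE_MAX + 1)

SEXES = ("male", "female")
AGE_BANDS = tuple((lo, lo + 4) for lo in range(20, 100, 5))
SEIFA_QUINTILES = tuple(f"seifa_q{i}" for i in range(1, 6))
REMOTENESS_GROUPS = ("major_city", "inner_regional", "other_regional")
SUBGROUPS = ("total",) + SEIFA_QUINTILES + REMOTENESS_GROUPS

#: Rate fields carried per single year of age in a :class:`StratumRates`.
RATE_FIELDS = (
    "all_cause_mortality",
    "ihd_incidence",
    "ihd_prevalence",
    "ihd_case_fatality",
    "yld_all_cause",
)


class ValidationError(ValueError):
    """An input table or parameter violates a model invariant."""


def band_label(band: tuple[int, int]) -> str:
    return f"{band[0]}-{band[1]}"


def parse_band(label: str) -> tuple[int, int]:
    lo, hi = label.split("-")
    band = (int(lo), int(hi))
    if band not in AGE_BANDS:
        raise ValidationError(f"unknown age band {label!r}")
    return band


def band_of_age(age: int) -> tuple[int, int]:
    if not AGE_MIN <= age < AGE_MIN + 80:
        raise ValueError(f"age {age} outside modelled bands")
    lo = AGE_MIN + 5 * ((age - AGE_MIN) // 5)
    return (lo, lo + 4)


def band_midpoint(band: tuple[int, int]) -> int:
    """Entry age of a 5-year cohort: the midpoint year of its band."""
    return band[0] + 2


@dataclass(frozen=True)
class ExposureDistribution:
    """A stratum's trans-fat intake distribution, in % of daily energy.

    Intake is modelled as lognormal, matched to the arithmetic mean and SD
    by moments: ``sigma^2 = ln(1 + (sd/mean)^2)``, ``mu = ln(mean) -
    sigma^2 / 2``.  A degenerate ``point`` family (all mass at ``mean``) is
    supported for analytical checks.
    """

    mean: float
    sd: float
    family: str = "lognormal"
    role: str = "pre"

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "point"):
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.mean <= 0:
            raise ValidationError(f"intake mean must be positive, got {self.mean}")
        if self.family == "lognormal":
            if self.sd <= 0:
                raise ValidationError(f"intake sd must be positive, got {self.sd}")
            if self.sd >= self.mean:
                raise ValidationError(
                    f"intake sd {self.sd} must be below the mean {self.mean}"
                )
        if self.role not in ("pre", "post", "tmred"):
            raise ValidationError(f"unknown exposure role {self.role!r}")

    @property
    def log_params(self) -> tuple[float, float]:
        """(mu, sigma) of the underlying normal, by moment matching."""
        s2 = math.log1p((self.sd / self.mean) ** 2)
        return math.log(self.mean) - s2 / 2.0, math.sqrt(s2)

    def pdf(self, x: np.ndarray | float) -> np.ndarray | float:
        if self.family == "point":
            raise ValueError("point-mass distribution has no density")
        mu, sigma = self.log_params
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        pos = x > 0
        lx = np.log(x[pos])
        out[pos] = np.exp(-((lx - mu) ** 2) / (2 * sigma**2)) / (
            x[pos] * sigma * math.sqrt(2 * math.pi)
        )
        return out

    def isf(self, q: float) -> float:
        """Upper quantile (inverse survival function)."""
        from scipy import stats

        if self.family == "point":
            return self.mean
        mu, sigma = self.log_params
        return float(stats.lognorm.isf(q, s=sigma, scale=math.exp(mu)))

    def with_mean(self, mean: float) -> "ExposureDistribution":
        """Same relative spread, new mean (used for parameter draws)."""
        sd = self.sd if self.family == "point" else self.sd * mean / self.mean
        return dataclasses.replace(self, mean=mean, sd=sd)


@dataclass(frozen=True)
class RelativeRiskFunction:
    """Age-specific relative risk of ischemic heart disease per 2%E trans fat.

    ``table`` maps (age_lo, age_hi) source bands to (rr, ci_low, ci_high).
    The risk is log-linear in intake and anchored at RR(0) = 1, so
    ``RR(x) = rr ** (x / 2)``.  Model age bands younger than the youngest
    source band use the youngest band's estimate; the open-ended oldest
    band covers all remaining ages.
    """

    table: tuple[tuple[tuple[int, int], tuple[float, float, float]], ...]

    def __post_init__(self) -> None:
        prev_rr = None
        for (lo, hi), (rr, ci_lo, ci_hi) in self.table:
            if rr < 1:
                raise ValidationError(f"relative risk {rr} < 1 for ages {lo}-{hi}")
            if not ci_lo <= rr <= ci_hi:
                raise ValidationError(
                    f"CI ({ci_lo}, {ci_hi}) does not bracket RR {rr} for ages {lo}-{hi}"
                )
            if prev_rr is not None and rr > prev_rr + 1e-12:
                raise ValidationError("relative risk must be non-increasing with age")
            prev_rr = rr

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, tuple[float, float, float]]
    ) -> "RelativeRiskFunction":
        rows = []
        for label, vals in mapping.items():
            if label.endswith("+"):
                lo, hi = int(label[:-1]), 200
            else:
                lo, hi = (int(p) for p in label.split("-"))
            rows.append(((lo, hi), tuple(float(v) for v in vals)))
        rows.sort(key=lambda r: r[0][0])
        return cls(table=tuple(rows))

    def params_for_age(self, age: int) -> tuple[float, float, float]:
        first_lo = self.table[0][0][0]
        if age < first_lo:
            return self.table[0][1]
        for (lo, hi), vals in self.table:
            if lo <= age <= hi:
                return vals
        return self.table[-1][1]

    def rr_per_2pct(self, age_band: tuple[int, int]) -> float:
        return self.params_for_age(band_midpoint(age_band))[0]

    def with_rr_values(self, draws: Mapping[tuple[int, int], float]) -> "RelativeRiskFunction":
        """Replace point estimates (e.g. with Monte Carlo draws), keeping CIs.

        Draws are not required to preserve the age-monotonicity of the point
        estimates, so validation is relaxed by widening each CI to bracket
        the draw.
        """
        rows = []
        for (lo, hi), (rr, ci_lo, ci_hi) in self.table:
            new = float(draws.get((lo, hi), rr))
            rows.append(((lo, hi), (new, min(ci_lo, new), max(ci_hi, new))))
        obj = object.__new__(RelativeRiskFunction)
        object.__setattr__(obj, "table", tuple(rows))
        return obj


@dataclass
class StratumRates:
    """Epidemiological rate schedules per single year of age for one stratum.

    All arrays are indexed by age 20..100.  ``yld_all_cause`` is the
    prevalent all-cause years-lived-with-disability fraction (proportion of
    a life year lost to any condition); ``ihd_disability_weight`` is the
    scalar disability weight applied to the between-scenario change in IHD
    prevalence.
    """

    sex: str
    subgroup: str
    all_cause_mortality: np.ndarray
    ihd_incidence: np.ndarray
    ihd_prevalence: np.ndarray
    ihd_case_fatality: np.ndarray
    yld_all_cause: np.ndarray
    ihd_disability_weight: float

    def validate(self) -> None:
        for name in RATE_FIELDS:
            arr = getattr(self, name)
            if arr.shape != AGES.shape:
                raise ValidationError(
                    f"{name} for {self.sex}/{self.subgroup}: expected "
                    f"{AGES.size} ages, got {arr.size}"
                )
            if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
                bad = int(np.argmax((arr < 0) | (arr > 1) | ~np.isfinite(arr)))
                raise ValidationError(
                    f"{name} for {self.sex}/{self.subgroup} outside [0, 1] "
                    f"at age {AGES[bad]}: {arr[bad]}"
                )
        if np.any(self.ihd_prevalence >= 1):
            raise ValidationError(
                f"ihd_prevalence for {self.sex}/{self.subgroup} must be < 1"
            )
        excess = self.ihd_case_fatality * self.ihd_prevalence - self.all_cause_mortality
        if np.any(excess > 1e-12):
            age = int(AGES[np.argmax(excess)])
            raise ValidationError(
                f"IHD deaths exceed all-cause mortality for {self.sex}/"
                f"{self.subgroup} at age {age} (case fatality x prevalence "
                f"> all-cause rate)"
            )
        if not 0 <= self.ihd_disability_weight < 1:
            raise ValidationError(
                f"disability weight {self.ihd_disability_weight} outside [0, 1)"
            )

    def copy(self) -> "StratumRates":
        return StratumRates(
            sex=self.sex,
            subgroup=self.subgroup,
            ihd_disability_weight=self.ihd_disability_weight,
            **{name: getattr(self, name).copy() for name in RATE_FIELDS},
        )


def scale_subgroup_rates(
    total_rates: StratumRates,
    subgroup_ratio: float,
    fields: tuple[str, ...] = RATE_FIELDS,
    subgroup: str | None = None,
) -> StratumRates:
    """Derive subgroup rates by scaling total-population schedules.

    Each selected age-specific rate is multiplied by ``subgroup_ratio`` (the
    ratio of the subgroup's age-adjusted rate to the total population's) and
    clipped to [0, 1]; clipping events are logged.  In the loader, the
    mortality ratio is applied to all-cause mortality and the
    hospitalisation ratio to IHD incidence and prevalence.
    """
    if not subgroup_ratio > 0:
        raise ValueError(f"subgroup ratio must be positive, got {subgroup_ratio}")
    out = total_rates.copy()
    out.subgroup = subgroup if subgroup is not None else total_rates.subgroup
    for name in fields:
        scaled = getattr(total_rates, name) * subgroup_ratio
        n_clip = int(np.sum(scaled > 1.0))
        if n_clip:
            logger.warning(
                "clipped %d %s values to 1.0 for %s/%s (ratio %.3f)",
                n_clip, name, out.sex, out.subgroup, subgroup_ratio,
            )
        setattr(out, name, np.clip(scaled, 0.0, 1.0))
    return out


def _cap_case_fatality(rates: StratumRates) -> None:
    # After independent scaling of mortality and IHD rates the consistency
    # bound cf * prev <= all-cause mortality can be violated; cap cf.
    prev = rates.ihd_prevalence
    cf = rates.ihd_case_fatality
    with np.errstate(divide="ignore", invalid="ignore"):
        cap = np.where(prev > 0, rates.all_cause_mortality / prev, np.inf)
    if np.any(cf > cap):
        n = int(np.sum(cf > cap))
        logger.warning(
            "capped case fatality at %d ages for %s/%s to respect the "
            "all-cause mortality bound", n, rates.sex, rates.subgroup,
        )
        rates.ihd_case_fatality = np.minimum(cf, cap)


@dataclass
class CostInputs:
    """Healthcare unit costs per sex and year of age, plus policy cost scalars.

    Healthcare costs attach to prevalent IHD case-years
    (``ihd_cost_per_prevalent_case``) and to person-years of life
    (``other_healthcare_cost_per_person``), both AUD/year at 2010 prices.
    Policy costs follow the extended health-sector perspective: one-off
    legislation (gamma-distributed), annual monitoring, one-off industry
    reformulation with a repackaging surcharge, and a small ongoing annual
    industry cost.
    """

    ihd_cost_per_prevalent_case: dict[str, np.ndarray]
    other_healthcare_cost_per_person: dict[str, np.ndarray]
    legislation_mean: float
    legislation_sd: float
    monitoring_annual: float
    reformulation_initial: float
    repackaging_fraction: float = 0.10
    annual_industry_fraction: float = 0.01
    n_products: int = 131

    def validate(self) -> None:
        for sex in SEXES:
            for label, table in (
                ("ihd_cost_per_prevalent_case", self.ihd_cost_per_prevalent_case),
                ("other_healthcare_cost_per_person", self.other_healthcare_cost_per_person),
            ):
                arr = table.get(sex)
                if arr is None or arr.shape != AGES.shape:
                    raise ValidationError(f"{label} missing or misshaped for {sex}")
                if np.any(arr < 0):
                    raise ValidationError(f"{label} contains negative values for {sex}")
        for name in (
            "legislation_mean", "legislation_sd", "monitoring_annual",
            "reformulation_initial",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("repackaging_fraction", "annual_industry_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")


@dataclass
class InputBundle:
    """A validated, fully stratified set of model inputs."""

    pre_intake: dict[tuple[str, tuple[int, int], str], ExposureDistribution]
    population: dict[tuple[str, str], np.ndarray]  # (sex, subgroup) -> per-age counts
    rates: dict[tuple[str, str], StratumRates]
    costs: CostInputs
    rr: RelativeRiskFunction
    config: dict

    @property
    def subgroups(self) -> tuple[str, ...]:
        return tuple(sorted({k[1] for k in self.rates}, key=SUBGROUPS.index))

    def cohorts(self, subgroup: str = "total") -> Iterator[tuple[str, tuple[int, int], int, float]]:
        """Yield (sex, band, entry_age, entry_population) for each cohort."""
        for sex in SEXES:
            pop = self.population[(sex, subgroup)]
            for band in AGE_BANDS:
                lo, hi = band
                n = float(pop[(AGES >= lo) & (AGES <= hi)].sum())
                yield sex, band, band_midpoint(band), n

    def total_population(self, subgroup: str = "total") -> float:
        return float(sum(self.population[(sex, subgroup)].sum() for sex in SEXES))

    def intake(self, sex: str, band: tuple[int, int], subgroup: str) -> ExposureDistribution:
        key = (sex, band, subgroup)
        if key in self.pre_intake:
            return self.pre_intake[key]
        return self.pre_intake[(sex, band, "total")]

    def validate(self) -> None:
        for (sex, subgroup), rates in self.rates.items():
            rates.validate()
            if (sex, subgroup) not in self.population:
                raise ValidationError(f"population missing for {sex}/{subgroup}")
            if np.any(self.population[(sex, subgroup)] < 0):
                raise ValidationError(f"negative population for {sex}/{subgroup}")
        for band in AGE_BANDS:
            for sex in SEXES:
                if (sex, band, "total") not in self.pre_intake:
                    raise ValidationError(
                        f"pre-intervention intake missing for {sex} {band_label(band)}"
                    )
        self.costs.validate()


# ---------------------------------------------------------------------------
# CSV / YAML loading


_RATE_COLUMNS = ("sex", "subgroup", "age") + RATE_FIELDS
_INTAKE_COLUMNS = ("sex", "age_band", "subgroup", "mean", "sd")
_POP_COLUMNS = ("sex", "subgroup", "age", "population")
_COST_COLUMNS = ("sex", "age", "ihd_cost_per_prevalent_case",
                 "other_healthcare_cost_per_person")


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    return df


def _check_rate_bounds(df: pd.DataFrame, path_name: str) -> None:
    for col in RATE_FIELDS:
        bad = df.index[(df[col] < 0) | (df[col] > 1) | df[col].isna()]
        if len(bad):
            row = int(bad[0])
            raise ValidationError(
                f"{path_name}: rate outside [0, 1] at row {row + 2}, "
                f"column {col!r} (value {df.loc[row, col]})"
            )


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return config
    with open(config) as fh:
        return yaml.safe_load(fh)


def load_inputs(paths: Mapping[str, str | Path], config: str | Path | dict) -> InputBundle:
    """Load and validate the full input bundle.

    ``paths`` maps table names (``intake``, ``population``, ``rates``,
    ``costs``) to CSV files; ``config`` is a YAML path or dict carrying the
    scenario block, the relative-risk table, disability weights, policy cost
    scalars, and subgroup scaling ratios.  Subgroups listed in the config
    but absent from a table fall back to total-population values (derived by
    ratio when a ratio is configured, otherwise used verbatim with a logged
    warning).
    """
    cfg = load_config(config)
    wanted_subgroups = tuple(cfg.get("subgroups", SUBGROUPS))
    for sg in wanted_subgroups:
        if sg not in SUBGROUPS:
            raise ValidationError(f"unknown subgroup {sg!r} in config")

    rr = RelativeRiskFunction.from_mapping(cfg["relative_risk_per_2pctE"])
    dw = cfg["ihd_disability_weight"]

    # --- rates ---
    rates_df = _read_csv(paths["rates"], _RATE_COLUMNS)
    _check_rate_bounds(rates_df, Path(paths["rates"]).name)
    rates: dict[tuple[str, str], StratumRates] = {}
    for sex in SEXES:
        sub = rates_df[(rates_df.sex == sex) & (rates_df.subgroup == "total")]
        if len(sub) != AGES.size:
            raise ValidationError(
                f"rates table: expected {AGES.size} rows for {sex}/total, got {len(sub)}"
            )
        sub = sub.sort_values("age")
        if not np.array_equal(sub.age.to_numpy(), AGES):
            raise ValidationError(f"rates table: ages for {sex}/total are not 20..100")
        total = StratumRates(
            sex=sex, subgroup="total",
            ihd_disability_weight=float(dw[sex]),
            **{name: sub[name].to_numpy(dtype=float) for name in RATE_FIELDS},
        )
        total.validate()
        rates[(sex, "total")] = total

    ratios = cfg.get("subgroup_ratios", {})
    for sg in wanted_subgroups:
        if sg == "total":
            continue
        for sex in SEXES:
            sub = rates_df[(rates_df.sex == sex) & (rates_df.subgroup == sg)]
            if len(sub) == AGES.size:
                sub = sub.sort_values("age")
                strat = StratumRates(
                    sex=sex, subgroup=sg,
                    ihd_disability_weight=float(dw[sex]),
                    **{name: sub[name].to_numpy(dtype=float) for name in RATE_FIELDS},
                )
            elif sg in ratios:
                r = ratios[sg]
                strat = scale_subgroup_rates(
                    rates[(sex, "total")], float(r["mortality"][sex]),
                    fields=("all_cause_mortality",), subgroup=sg,
                )
                strat = scale_subgroup_rates(
                    strat, float(r["ihd"][sex]),
                    fields=("ihd_incidence", "ihd_prevalence"), subgroup=sg,
                )
                _cap_case_fatality(strat)
            else:
                logger.warning(
                    "no rates or ratios for subgroup %s; falling back to "
                    "total-population rates", sg,
                )
                strat = rates[(sex, "total")].copy()
                strat.subgroup = sg
            strat.validate()
            rates[(sex, sg)] = strat

    # --- population ---
    pop_df = _read_csv(paths["population"], _POP_COLUMNS)
    population: dict[tuple[str, str], np.ndarray] = {}
    for sg in wanted_subgroups:
        for sex in SEXES:
            sub = pop_df[(pop_df.sex == sex) & (pop_df.subgroup == sg)]
            if len(sub) == 0 and sg != "total":
                logger.warning("population missing for %s/%s; using zero", sex, sg)
                population[(sex, sg)] = np.zeros(AGES.size)
                continue
            if len(sub) != AGES.size:
                raise ValidationError(
                    f"population table: expected {AGES.size} rows for {sex}/{sg}, "
                    f"got {len(sub)}"
                )
            sub = sub.sort_values("age")
            population[(sex, sg)] = sub.population.to_numpy(dtype=float)

    # --- intake ---
    intake_df = _read_csv(paths["intake"], _INTAKE_COLUMNS)
    pre_intake: dict[tuple[str, tuple[int, int], str], ExposureDistribution] = {}
    for _, row in intake_df.iterrows():
        band = parse_band(str(row.age_band))
        try:
            dist = ExposureDistribution(
                mean=float(row["mean"]), sd=float(row.sd), role="pre"
            )
        except ValidationError as exc:
            raise ValidationError(
                f"{Path(paths['intake']).name}: {row.sex} {row.age_band} "
                f"{row.subgroup}: {exc}"
            ) from exc
        pre_intake[(str(row.sex), band, str(row.subgroup))] = dist

    # --- costs ---
    cost_df = _read_csv(paths["costs"], _COST_COLUMNS)
    ihd_cost, other_cost = {}, {}
    for sex in SEXES:
        sub = cost_df[cost_df.sex == sex].sort_values("age")
        if len(sub) != AGES.size:
            raise ValidationError(
                f"cost table: expected {AGES.size} rows for {sex}, got {len(sub)}"
            )
        ihd_cost[sex] = sub.ihd_cost_per_prevalent_case.to_numpy(dtype=float)
        other_cost[sex] = sub.other_healthcare_cost_per_person.to_numpy(dtype=float)

    pc = cfg["policy_costs"]
    costs = CostInputs(
        ihd_cost_per_prevalent_case=ihd_cost,
        other_healthcare_cost_per_person=other_cost,
        legislation_mean=float(pc["legislation_mean"]),
        legislation_sd=float(pc["legislation_sd"]),
        monitoring_annual=float(pc["monitoring_annual"]),
        reformulation_initial=float(pc["reformulation_initial"]),
        repackaging_fraction=float(pc.get("repackaging_fraction", 0.10)),
        annual_industry_fraction=float(pc.get("annual_industry_fraction", 0.01)),
        n_products=int(pc.get("n_products", 131)),
    )

    bundle = InputBundle(
        pre_intake=pre_intake, population=population, rates=rates,
        costs=costs, rr=rr, config=cfg,
    )
    bundle.validate()
    return bundle


def write_bundle(bundle: InputBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle back to the CSV/YAML schemas `load_inputs` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}.csv"
             for name in ("intake", "population", "rates", "costs")}

    rows = []
    for (sex, band, sg), dist in sorted(
        bundle.pre_intake.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        rows.append({"sex": sex, "age_band": band_label(band), "subgroup": sg,
                     "mean": round(dist.mean, 6), "sd": round(dist.sd, 6)})
    pd.DataFrame(rows, columns=list(_INTAKE_COLUMNS)).to_csv(paths["intake"], index=False)

    rows = []
    for (sex, sg), pop in sorted(bundle.population.items()):
        for age, n in zip(AGES, pop):
            rows.append({"sex": sex, "subgroup": sg, "age": int(age),
                         "population": round(float(n), 3)})
    pd.DataFrame(rows, columns=list(_POP_COLUMNS)).to_csv(paths["population"], index=False)

    rows = []
    for (sex, sg), rates in sorted(bundle.rates.items()):
        for i, age in enumerate(AGES):
            row = {"sex": sex, "subgroup": sg, "age": int(age)}
            for name in RATE_FIELDS:
                row[name] = round(float(getattr(rates, name)[i]), 10)
            rows.append(row)
    pd.DataFrame(rows, columns=list(_RATE_COLUMNS)).to_csv(paths["rates"], index=False)

    rows = []
    for sex in SEXES:
        for i, age in enumerate(AGES):
            rows.append({
                "sex": sex, "age": int(age),
                "ihd_cost_per_prevalent_case":
                    round(float(bundle.costs.ihd_cost_per_prevalent_case[sex][i]), 4),
                "other_healthcare_cost_per_person":
                    round(float(bundle.costs.other_healthcare_cost_per_person[sex][i]), 4),
            })
    pd.DataFrame(rows, columns=list(_COST_COLUMNS)).to_csv(paths["costs"], index=False)

    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(bundle.config, fh, sort_keys=True)
    paths["config"] = config_path
    return paths
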