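"""Monte Carlo uncertainty propagation and the deterministic sensitivity suite.

Per iteration, a single parameter set is drawn — age-band relative risks
(lognormal around the published point estimates), stratum intake means
(normal, with a standard error derived from the intake SD), and the
legislation cost (gamma) — and the full pipeline is re-evaluated.  All
other inputs (epidemiological rates, healthcare unit costs, the remaining
policy cost scalars) are held fixed.  Point estimates and 95% uncertainty
intervals are the 50th and 2.5th/97.5th percentiles over iterations.

The intake draw is interpreted as sampling error of the stratum *mean*
(SE = sd / sqrt(n_effective), n_effective configurable, default 100), not
as the population spread itself — the spread stays in the exposure
distribution used by the PIF integral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .inputs import AGE_BANDS, SEXES, InputBundle, RelativeRiskFunction
from .pipeline import (DEFAULT_HORIZONS, Scenario, evaluate, horizon_label,
                       result_record)

DEFAULT_N_ITERATIONS = 2000
DEFAULT_N_EFFECTIVE = 100.0

#: Floor for drawn intake means, %E (a mean at or below zero is meaningless).
_INTAKE_FLOOR = 0.01


@dataclass(frozen=True)
class UncertaintySummary:
    label: str
    median: float
    p2_5: float
    p97_5: float
    n_iterations: int
    seed: int

    def __post_init__(self):
        if not (self.p2_5 <= self.median <= self.p97_5):
            raise ValueError(f"percentiles out of order for {self.label}")


@dataclass(frozen=True)
class ParameterDraw:
    rr: RelativeRiskFunction
    intake_means: dict[tuple[str, tuple[int, int], str], float]
    legislation_cost: float


def _rr_log_se(ci_low: float, ci_high: float) -> float:
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * 1.96)


def draw_parameters(
    bundle: InputBundle,
    rng: np.random.Generator,
    subgroups: Sequence[str] = ("total",),
    n_effective: float | None = None,
) -> ParameterDraw:
    """One joint draw of the uncertain parameters.

    A single relative-risk draw is shared across subgroups (the etiology is
    common); intake means are drawn independently per stratum.  Degenerate
    (zero-variance) configurations return the point estimates exactly.
    """
    if n_effective is None:
        n_effective = float(
            bundle.config.get("scenario", {}).get("n_effective", DEFAULT_N_EFFECTIVE)
        )

    rr_draws = {}
    for (lo, hi), (rr, ci_lo, ci_hi) in bundle.rr.table:
        se = _rr_log_se(ci_lo, ci_hi)
        rr_draws[(lo, hi)] = math.exp(rng.normal(math.log(rr), se)) if se > 0 else rr
    rr = bundle.rr.with_rr_values(rr_draws)

    intake_means = {}
    for sg in subgroups:
        for sex in SEXES:
            for band in AGE_BANDS:
                dist = bundle.intake(sex, band, sg)
                se = dist.sd / math.sqrt(n_effective) if n_effective > 0 else 0.0
                mean = rng.normal(dist.mean, se) if se > 0 else dist.mean
                intake_means[(sex, band, sg)] = max(float(mean), _INTAKE_FLOOR)

    c = bundle.costs
    if c.legislation_sd > 0:
        shape = (c.legislation_mean / c.legislation_sd) ** 2
        scale = c.legislation_sd**2 / c.legislation_mean
        legislation = float(rng.gamma(shape, scale))
    else:
        legislation = c.legislation_mean
    return ParameterDraw(rr=rr, intake_means=intake_means,
                         legislation_cost=legislation)


_MC_QUANTITIES = (
    "deaths_averted", "events_averted", "ly_gained", "haly_gained",
    "ihd_healthcare_cost_delta", "total_healthcare_cost_delta",
    "policy_cost_total", "net_cost", "icer",
)


def run_monte_carlo(
    bundle: InputBundle,
    scenario: Scenario | None = None,
    n: int = DEFAULT_N_ITERATIONS,
    seed: int = 0,
    subgroup: str = "total",
    horizons: tuple[int | None, ...] = DEFAULT_HORIZONS,
    n_effective: float | None = None,
) -> tuple[dict[str, UncertaintySummary], pd.DataFrame]:
    """Monte Carlo over the full pipeline for one subgroup.

    Returns per-quantity summaries (keyed ``"<horizon>.<quantity>"``) and
    the raw iteration-level draws as a DataFrame.  The ICER is summarised
    iteration-wise (one ratio per draw); iterations with negative net cost
    are additionally counted under ``"<horizon>.dominant_fraction"``.
    """
    if n < 2:
        raise ValueError(f"need at least 2 iterations, got {n}")
    scenario = scenario or Scenario()
    rng = np.random.default_rng(seed)
    records = []
    for it in range(n):
        draw = draw_parameters(bundle, rng, subgroups=(subgroup,),
                               n_effective=n_effective)
        try:
            res = evaluate(bundle, scenario, subgroup=subgroup, horizons=horizons,
                           rr=draw.rr, intake_means=draw.intake_means,
                           legislation_cost=draw.legislation_cost)
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"Monte Carlo iteration {it} failed with draw "
                f"legislation={draw.legislation_cost:.0f}: {exc}"
            ) from exc
        row = {"iteration": it}
        rec = result_record(res)
        for horizon in horizons:
            lab = horizon_label(horizon)
            for q in _MC_QUANTITIES:
                row[f"{lab}.{q}"] = rec[lab][q]
            row[f"{lab}.dominant"] = rec[lab]["net_cost"] < 0
        records.append(row)
    frame = pd.DataFrame(records)

    summaries: dict[str, UncertaintySummary] = {}
    for col in frame.columns:
        if col == "iteration":
            continue
        vals = frame[col].to_numpy(dtype=float)
        if col.endswith(".dominant"):
            frac = float(np.mean(vals))
            summaries[col.replace(".dominant", ".dominant_fraction")] = (
                UncertaintySummary(col, frac, frac, frac, n, seed)
            )
            continue
        lo, med, hi = np.percentile(vals, [2.5, 50.0, 97.5])
        summaries[col] = UncertaintySummary(col, float(med), float(lo),
                                            float(hi), n, seed)
    return summaries, frame


def sensitivity_variants() -> dict[str, Scenario]:
    """The univariate sensitivity suite, keyed by variant name.

    Discount rates of 0% and 6%; a lower counterfactual intake
    (0.4 +/- 0.04 %E); less effective elimination (post means 0.52-0.60 %E
    with SD at 10% or 50% of the mean); a halved pre-post intake gap;
    doubled product count; no industry costs; and 25% higher monitoring.
    """
    variants = {
        "primary": Scenario(label="primary"),
        "discount_0pct": Scenario(label="discount_0pct", discount_rate=0.0),
        "discount_6pct": Scenario(label="discount_6pct", discount_rate=0.06),
        "tmred_0.4": Scenario(label="tmred_0.4", post_mean=0.40, post_sd=0.04),
        "halved_gap": Scenario(label="halved_gap", halve_gap=True),
        "doubled_products": Scenario(label="doubled_products",
                                     cost_variant="doubled_products"),
        "no_industry_costs": Scenario(label="no_industry_costs",
                                      cost_variant="no_industry_costs"),
        "monitoring_plus_25pct": Scenario(label="monitoring_plus_25pct",
                                          cost_variant="monitoring_plus_25pct"),
    }
    for mean in (0.52, 0.56, 0.60):
        for sd_pct in (10, 50):
            name = f"post_{mean:.2f}_sd{sd_pct}"
            variants[name] = Scenario(label=name, post_mean=mean,
                                      post_sd=mean * sd_pct / 100.0)
    return variants


def run_sensitivity_suite(
    bundle: InputBundle,
    variants: Iterable[str] | None = None,
    horizons: tuple[int | None, ...] = DEFAULT_HORIZONS,
    subgroup: str = "total",
) -> pd.DataFrame:
    """Deterministic (point-estimate) evaluation of each sensitivity variant.

    Returns one row per variant x horizon with net cost, HALYs gained, and
    the ICER; the primary scenario is always included for reference.
    """
    catalogue = sensitivity_variants()
    if variants is None:
        names = list(catalogue)
    else:
        names = list(variants)
        unknown = [v for v in names if v not in catalogue]
        if unknown:
            raise ValueError(f"unknown sensitivity variant(s): {unknown}")
        if "primary" not in names:
            names.insert(0, "primary")

    rows = []
    for name in names:
        res = evaluate(bundle, catalogue[name], subgroup=subgroup, horizons=horizons)
        for horizon in horizons:
            hr = res.horizon(horizon)
            rows.append({
                "variant": name,
                "horizon": horizon_label(horizon),
                "haly_gained": hr.delta.haly_gained,
                "policy_cost_total": hr.policy.total,
                "total_healthcare_cost_delta": hr.total_cost_delta,
                "net_cost": hr.net_cost,
                "icer": hr.cea.icer,
                "classification": hr.cea.classification,
            })
    return pd.DataFrame(rows)
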