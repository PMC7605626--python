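# Methods

## Model structure

The model is a multiple-cohort proportional multistate life table. Adults
enter in 5-year age bands (20–24 … 95–99) by sex, each cohort anchored at
the midpoint year of its band (22, 27, …, 97), and are simulated in annual
cycles until age 100. Epidemiological rates are carried per single year of
age, so a cohort entering at 47 uses the age-47 rates in its first cycle,
age-48 rates in its second, and so on. Three states are tracked per
cohort: healthy, prevalent ischemic heart disease (IHD), and dead.

Within a cycle, transitions apply in a fixed order:

1. **Incidence** — healthy × I′, where I′ = I (1 − PIF) in the
   intervention arm and I in the reference arm;
2. **IHD case fatality** — prevalent cases × case-fatality rate;
3. **Other-cause mortality** — the all-cause rate net of baseline IHD
   mortality (prevalence × case fatality, floored at zero), applied
   proportionally to everyone still alive.

Person-years use a half-cycle correction (mean of cycle-start and
cycle-end occupancy), standard life-table practice for annual cycles.
There is no remission from the IHD state, and no calendar-time trend in
rates; both would require inputs the model does not take. The exact
transition ordering and half-cycle convention are modelling choices — the
alternatives differ by well under the model's parameter uncertainty — and
are localised in `lifetable.run_cohort`.

State counts are conserved exactly each cycle
(alive<sub>t</sub> = alive<sub>t+1</sub> + deaths<sub>t</sub>), which the
test suite checks at every cycle, alongside agreement with an
individual-level stochastic microsimulation (10⁵ persons, same rates,
within 3 Monte Carlo SE on deaths and life years).

## Exposure and the potential impact fraction

Intake distributions are lognormal, parameterised by arithmetic mean and
SD via moment matching (σ² = ln(1 + (sd/mean)²), μ = ln(mean) − σ²/2).
The lognormal is the conventional choice for right-skewed dietary
exposures in distribution-shift comparative risk assessment; only mean ±
SD are published per stratum.

The relative risk is log-linear in intake and anchored at RR(0) = 1:
RR(x) = rr<sup>x/2</sup> with rr the published risk ratio per 2 %E.
Because the PIF is a ratio of risk-weighted masses, any multiplicative
re-anchoring of RR cancels exactly (tested). Published RR bands are
decadal from 25–34 to ≥75; model bands younger than 25 use the youngest
published estimate.

Both PIF integrals are evaluated on [0, m] by order-adaptive
Gauss–Legendre quadrature (order doubled until two successive estimates
agree to 1e-9 relative; the final refinement is the reported error
estimate — in practice ~1e-14, far below the 1e-6 contract). The upper
bound m leaves < 1e-10 of probability mass above it in either
distribution, and at least mean + 12 SD of the wider one; the result is
invariant to doubling m within 1e-6 (tested). A degenerate point-mass
family is supported for closed-form checks. The same PIF, computed at the
band level, applies to every single year of age within the band.

In the primary scenario the post-intervention distribution equals the
theoretical-minimum-risk distribution (0.50 ± 0.05 %E): a ban is assumed
to remove industrial *trans* fat entirely, leaving ruminant sources.

## Health-adjusted life years

Each discounted person-year is weighted by (1 − YLD), the all-cause
prevalent years-lived-with-disability fraction at that age. When
differencing scenarios, the reduction in prevalent IHD person-years is
additionally credited with the IHD disability weight (male 7.67%, female
7.63%, a weighted average over myocardial infarction, angina, and heart
failure), since the all-cause YLD schedule is held fixed across arms.
With zero YLD and zero disability weight, HALYs reduce exactly to life
years (tested).

Averted deaths and events are reported undiscounted; life years, HALYs,
and all money are discounted at 3% (0% and 6% in sensitivity), with year-t
amounts discounted by (1+r)<sup>−t</sup> from t = 1 and one-off year-0
payments at face value. The "lifetime" horizon is 80 simulation years, the
time for the youngest entrants (age 20) to reach 100.

## Costs and cost-effectiveness

All money is AUD at 2010 prices. Policy costs (extended health-sector
perspective):

| Component | Value | Timing |
|---|---|---|
| Legislation | gamma, mean 1,090,000, SD 77,497 | year 0 |
| Monitoring | 1,557,422 / year | years 1+ |
| Initial reformulation | 6,010,391 (131 products) | year 0 |
| Repackaging | 10% of reformulation | year 0 |
| Ongoing industry cost | 1% of reformulation / year | years 1+ |

The aggregate published figures are taken as canonical inputs rather than
recomputed from per-product foreign-currency amounts, whose printed
conversion does not reproduce them exactly. The gamma is moment-matched
(shape = (mean/sd)², scale = sd²/mean). The doubled-product sensitivity
variant doubles the reformulation base and, with it, repackaging and the
ongoing industry cost exactly.

IHD-related healthcare costs attach to prevalent IHD case-years (AUD per
prevalent case per year); no event-based cost split is published. Total
healthcare adds the unrelated healthcare cost of every person-year lived,
so life extension carries its future healthcare costs — IHD savings and
total costs can therefore have opposite signs over long horizons. Net cost
= policy total + total healthcare delta; ICER = net cost / HALYs gained;
classification against AUD 169,361/HALY is strict (<), with negative net
cost classified cost-saving (dominant when HALYs are gained) and
non-positive HALY gains yielding an undefined-ICER flag rather than an
exception.

Per-capita cost outputs are deliberately not hard-wired to a population
denominator: published per-capita and total figures are not reconcilable
through any single obvious denominator, so per-capita reporting is left to
the caller with an explicit denominator.

## Subgroups and equity

Subgroup models (SEIFA quintiles q1 most disadvantaged … q5 most
advantaged; major city / inner regional / other regional) substitute
subgroup-specific intake, population, and rates. Where subgroup rate
schedules are unavailable per year of age, they are derived by scaling the
total-population schedule with a subgroup-to-total standardised ratio
(mortality ratio for all-cause mortality; hospitalisation ratio for IHD
incidence and prevalence — the same ratio for both, as the published
construction implies but does not state). Scaled rates are clipped to
[0, 1] and case fatality is capped so IHD deaths never exceed all-cause
deaths; both adjustments are logged. Because subgroup rates are scaled
independently, subgroup results are not exactly additive to the total
(the test suite checks 5% consistency on remoteness partitions).

Equity is summarised by the extreme-quintile HALY difference (q1 − q5)
and the grouped concentration index
CI = Σ<sub>q</sub> p<sub>q</sub> (μ<sub>q</sub>/μ)(2R<sub>q</sub> − 1),
with R<sub>q</sub> cumulative population-rank midpoints. The grouped form
matches the available stratification (no individual-level data). Quintiles
are treated as equal-sized by default, with a population-weighted mode
available, since the published computation does not state which was used.
Within a Monte Carlo iteration the relative-risk draw is shared across
quintiles (a common etiology; subgroup-specific RR draws would manufacture
spurious between-group variance) while intake means are drawn per
quintile.

## Uncertainty

Monte Carlo (default n = 2,000) redraws per iteration: log relative risks
per age band (normal on the log scale, SE = (ln CI<sub>hi</sub> − ln
CI<sub>lo</sub>)/(2×1.96)), stratum intake means, and the legislation
cost. Epidemiological rates and healthcare unit costs are fixed across
iterations. Summaries are the 50th (point estimate) and 2.5th/97.5th
percentiles; runs are exactly reproducible from (seed, config).

The largest interpretive choice is the intake draw: "drawing from the
intake distribution" could mean sampling the population spread or the
sampling error of the stratum mean. This implementation draws the
*mean*, with SE = sd/√n_effective and n_effective = 100 by default
(configurable), roughly the precision of a moderate survey stratum;
drawing from the full spread would conflate within-population variation
(already inside the PIF integral) with parameter uncertainty.

The deterministic sensitivity suite covers: discount 0% and 6%; a lower
counterfactual (0.40 ± 0.04 %E); less effective elimination (post means
0.52/0.56/0.60 %E with SD at 10% or 50% of the mean); a halved pre–post
intake gap (pre means moved halfway toward the post mean, relative spread
kept); doubled product count; no industry costs; monitoring +25%.

## Synthetic data

The stratified source tables (intake by age/sex/subgroup, population by
year of age, mortality, IHD incidence/prevalence/case fatality) are not
publicly deposited, so `tfaban.synthetic` generates them:

- **Intake**: lognormal means built from a mild age slope and sex factor,
  normalised so the population-weighted mean equals the configured total
  (0.59 %E by default, the national survey mean); SD = 50% of the mean,
  which puts roughly 1 in 11 adults above the 1 %E guideline, matching
  the published skew. Quintile offsets (±15% relative, linear) and
  remoteness offsets are multiplicative, so population-weighted subgroup
  means reproduce the total exactly by construction.
- **Mortality**: Gompertz per sex (level 5.5e-4/3.5e-4 at age 20, slope
  0.092/0.095), monotone by construction.
- **IHD curves**: logistic in age for incidence, prevalence, and case
  fatality, with case fatality capped so IHD deaths cannot exceed
  all-cause deaths; a configuration requiring more than a factor-2 cap
  raises a generation error naming the constraint.
- **Subgroup ratios**: q1 1.25 → q5 0.82 for mortality, 1.30 → 0.78 for
  IHD (disadvantage gradient); remoteness 0.97/1.08/1.15 and
  0.96/1.10/1.20 — magnitudes typical of Australian area-level mortality
  and CVD-hospitalisation gradients.
- **Healthcare unit costs**: linear-in-age IHD cost per prevalent
  case-year (3,500 + 60/year of age) and exponentially growing other
  healthcare cost per person-year.

Generation is deterministic under the seed (1% multiplicative jitter on
the curves, then monotonicity restored). Population size is 16.5 million
adults, 51% female, quintiles 20% each, remoteness shares 68/18/11%.

What the synthetic bundle does *not* emulate: the real tables' non-
parametric age detail, cohort effects, any correlation between intake and
epidemiology beyond the configured gradients, and survey weighting.
Passing tests on synthetic data therefore demonstrate the *mechanics* —
conservation, closed-form agreement, invariances, directional responses —
not the published health-outcome magnitudes, which require the real
stratified inputs. The policy-cost results are the exception: they depend
only on published scalars and are reproduced exactly.

## Numerical and problem-size choices

- PIF quadrature: spectral Gauss–Legendre, orders 64→1024, converged at
  ~1e-14; sampling cross-checks use 10⁶ draws (3 SE criterion).
- Life tables are exact recursions in float64; conservation holds to
  1e-12 relative.
- Default test problem sizes: full 32-cohort populations for point
  estimates; Monte Carlo consistency checks at n = 40 vs n = 200; the
  microsimulation oracle uses 10⁵ persons. The shipped acceptance script
  uses the full n = 2,000 draws for policy costs.
- Ties and degenerate inputs: zero incidence/mortality cohorts are legal
  (conservation only); PIF of identical distributions is exactly 0;
  ICER with non-positive HALY gain returns a flagged undefined result.

## Known limitations

- No substitution modelling: risks are for *trans*-fat change against the
  overall diet, not replacement by specific fats; if iTFA were replaced by
  saturated fat, benefits would be overstated.
- No indirect (productivity) costs; societal savings are understated.
- Cohorts under 20 are excluded; benefits accruing after their later
  entry are not counted.
- The intake-uncertainty interpretation (mean-sampling error) is a
  modelling choice; widening n_effective downward inflates all uncertainty
  intervals roughly proportionally.
- Subgroup rate scaling assumes proportional hazards across age within a
  subgroup, and the same hospitalisation ratio for incidence and
  prevalence.
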