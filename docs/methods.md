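# Methods

This note documents the models, parameter choices, and numerical
conventions behind `heatattrib`, and what the synthetic study design does
and does not demonstrate.

## Heatwave definition and detection

A heatwave day in grid cell *p* is a day belonging to a maximal run of at
least `min_run = 3` consecutive days with daily maximum temperature
strictly above that cell's threshold, inside the warm-season window
May–September. The threshold is the 92.5th percentile of the cell's
pooled daily Tmax over the 1986–2005 reference period.

Conventions that the one-sentence definition leaves open, fixed here:

- **Thresholds are per grid cell.** No spatial pooling; two cells with
  different climates get different thresholds.
- **Percentile basis.** By default the percentile is computed over
  *in-season* (May–September) reference days, so ≈ 7.5% of in-season
  reference days exceed it — consistent with an analysis confined to the
  warm season. `season_only=False` switches to all-year pooling; both are
  supported because the convention differs between studies.
- **Interpolation.** Linear interpolation between order statistics
  (numpy's default). The test oracle pins the same convention.
- **Strict exceedance** (`>`, not `≥`).
- **Month allocation.** Days of a run are credited to the calendar month
  they fall in, because the burden formula indexes heatwave days by month.
  A 5-day spell over July 30–August 3 contributes 2 days to July and 3 to
  August.
- **Season truncation.** Runs are truncated at the season edges *before*
  the length test: a spell over April 28–May 2 contributes nothing (its
  in-season part is 2 days), while April 28–May 4 contributes May 1–4.
  The winter gap also prevents runs from spanning calendar years.

The calendar is a 365-day no-leap calendar throughout, matching common
climate-model output; February always has 28 days.

## Exposure-response model

Location-level fits use a Poisson GLM with log link,

    log E[deaths_t] = α + β·HW_t + Σ_j γ_j x_jt ,

estimated by IRLS (statsmodels) to relative tolerance 1e-8. β is the log
relative risk of death on a heatwave day. Confounder adjustment is
deliberately generic: callers supply covariate columns (the shipped
fixture uses annual sine/cosine terms and day-of-week indicators), since
real confounder sets (air-quality index, humidity, holiday terms, spline
bases) are study-specific. A constant heatwave indicator is rejected
rather than silently returning an unidentifiable coefficient.

Zone pooling follows the heterogeneity-gated rule: compute Cochran's
Q = Σ w_i (β_i − β_FE)², its p-value on k−1 df, and
I² = max(0, (Q − (k−1))/Q)·100. If p < 0.05 **and** I² ≥ 50, pool with
DerSimonian-Laird random effects (moment estimator of τ², non-iterative);
otherwise inverse-variance fixed effects. The 0.05 level is a fixed
choice ("statistically significant" left unquantified in common usage);
REML would be a reasonable alternative τ² estimator but DL is standard
and closed-form. A single-site zone passes through unchanged.

## Attribution

AF = (RR − 1)/RR. RR < 1 ("protective" heatwaves, usually noise) is
floored to AF = 0 by default with a counted warning; `allow_protective`
disables the floor. The attributable number is

    AN(y,p) = Σ_m Pop(y,p) · [Mort(y,p) · prop_m / days_m] · HW(m,y,p) · AF(y,p)

summed over May–September, and over age groups when demography is
age-stratified (age-specific population and rates, optionally
age-specific AF). Monthly death proportions default to uniform-over-days
(prop_m = days_m/365, making the daily rate exactly rate/365); real
monthly tables can be supplied. Mortality rates are frozen at their
2010s mean for all years after 2019, encoding the standard assumption
that future baseline rates match the recent past; no adaptation to heat
is modelled.

AN is exactly linear in population, rate, heatwave days, and AF
separately, and additive over cells and months. These identities are what
make the decade averaging, the driver decomposition, and the fast
Monte-Carlo evaluation below correct, and are enforced by property tests.

Reporting windows are 20-year means: 1986–2005 (baseline), 2021–2040
("2030"), 2051–2070 ("2060"), 2081–2100 ("2090"); growth rate is
(AN_future − AN_baseline)/AN_baseline × 100.

The stabilized-warming (1.5 °C analogue) burden combines the heatwave
statistics of 2021–2040 under the *low* scenario with end-of-century
(2081–2100) population and frozen mortality rates. Pairing
early-century climate with late-century demography is the point of the
comparison — what would the 2090 burden be if warming stopped at the
stabilized level; the mixed-period evaluator used for the driver
decomposition performs exactly this combination.

## Monte-Carlo uncertainty

Model coefficients, not relative risks, are treated as normal: each zone's
β is drawn from Normal(β̂, SE), 1,000 draws by default. Because AN is
linear in AF with a zone-constant AF, the burden per draw is
Σ_z base_z · AF(exp(β_z)) with `base_z` precomputed once per ensemble
member and window — Monte Carlo costs microseconds per draw. The point
estimate is the burden at β̂ averaged over ensemble members; the 95%
empirical CI is the 2.5th/97.5th percentile of the pooled draws × members
distribution. With SE = 0 and one member the CI collapses onto the point
estimate; with SE = 0 and several members it spans exactly their values.

**Uncertainty-source shares.** The variability of the decade-average
burden is allocated among coefficient noise, climate-model spread, and
population scenario by a Shapley variance decomposition: for each subset
of sources, the variance of the burden over that subset's levels (other
sources pinned at central values — β̂, the member-mean burden base, the
medium population) defines a set function; each source receives its
permutation-averaged marginal variance increase. Variance is the chosen
variability measure; range would weight extremes more. Negative marginal
terms (possible under interactions) are clipped at zero before
normalising shares to 100%. Shares are order- and label-invariant by
construction.

## Driver decomposition

The change in burden between two periods is attributed to **climate**
(the period's heatwave calendar), **size** (total population), and
**aging** (the age-share vector, with age-specific rates riding along) by
sequential substitution: walk from the period-1 state to the period-2
state switching one factor at a time; a factor's contribution in an
ordering is the burden difference at its switch step; the final
contribution averages the 3! = 6 orderings. Telescoping makes the
contributions sum to the total change exactly (to floating-point), per
ordering and hence on average.

Operationalizing the factors required a construction: population is
factored as total × age shares, so that size and aging are independently
switchable and size × shares × age-specific rates reconstructs the full
age-specific death weight. Relative risks are held fixed across states —
"climate" means the heatwave calendar only. Mortality-rate change is not
a factor (rates are frozen by assumption). When contributions have mixed
signs, percentage shares are reported against the sum of positive
contributions and flagged (`mixed_sign`), since percent-of-total is not a
composition in that case; with agreeing signs, shares are
contribution/total × 100 and sum to 100.

## Synthetic study design

The generators emulate the statistical structure of the real inputs, not
the inputs themselves:

- **Temperature**: per cell, annual-mean level (graded ~1.2 °C per degree
  latitude, warmer south) + a 12 °C-amplitude annual sinusoid peaking
  mid-July + a linear warming trend + AR(1) noise (innovation SD 2 °C,
  lag-1 autocorrelation 0.7 — a few-day weather decorrelation scale).
  Scenario trends are 0.1 / 0.25 / 0.5 °C per decade (low / mid / high),
  spanning the qualitative range from strong-mitigation to high-emission
  pathways; three ensemble members per scenario differ by their noise
  seed, sharing the trend. Thresholds and the reference burden come from
  the low-trend run's 1986–2005 segment.
- **Population**: a Gaussian-in-time national trajectory peaking in 2030
  (medium; 2028/2035 for low/high fertility variants), distributed over
  cells with fixed Dirichlet weights (persistent hotspots). Aging enters
  as a linearly increasing 75+ share (+0.25 %-points/yr, medium); the
  younger bands (<65, 65–74) split the complement in their initial
  proportions. Age-specific death rates 0.002 / 0.02 / 0.08 per
  person-year.
- **Deaths**: Poisson counts from the log-linear model with true zone
  log-RRs graded 0.10 (south) to 0.05 (north) — RR 1.05–1.10, the range
  heatwave main effects typically occupy — baseline 30 deaths/day per
  site, 3 sites per zone, 7 observation years (2007–2013 analogue).

The default grid is 10×10 half-degree cells in 4 latitude-band zones — a
deliberate scale-down from the thousands of cells and 7 zones of a
national analysis, sized so the full pipeline (9 scenario × member runs
of 115 years of daily data, 1,000-draw Monte Carlo) completes in tens of
seconds on one CPU.

What the synthetic design does **not** carry over from real data:
bias-corrected regional-model fields (no drift, no spatially correlated
weather between cells), realistic confounder structure (no pollution or
humidity processes), migration or urbanization, cause-specific mortality,
or any calibration to an actual country's totals. Passing tests therefore
validate the *computational machinery* — detection, estimation, pooling,
attribution arithmetic, uncertainty propagation, decomposition
exactness — and the qualitative scenario ordering, not any real-world
burden number.

## Numerical details and edge cases

- All randomness fans out from one root seed through SHA-256-derived
  substreams (stable across platforms, all below 2³¹).
- Percentile interpolation everywhere is numpy's linear convention; the
  empirical-CI bounds therefore coincide with burden evaluated at the
  coefficient-draw quantiles when the sample size places the percentile
  on an order statistic (e.g. 1,001 draws), a property the tests use.
- Degenerate inputs fail loudly: empty reference series, percentile
  outside (0,100), constant heatwave indicator, negative rates or SEs,
  unmapped cells, partially covered windows, zero total change in share
  computation.
- Output CSVs carry `# config_hash=… # seed=…` comment headers; reruns
  with the same config are byte-identical.
- NetCDF I/O uses the NETCDF3-classic backend with integer day offsets
  and explicit year/month/day-of-year coordinates plus a
  `calendar="noleap"` attribute, avoiding backend-specific date decoding
  while keeping CF-style dims (time, lat, lon).

## Known limitations

Heatwave intensity/duration metrics beyond day counts, humidity-based
indices, distributed-lag nonlinear exposure-response, added-vs-main
effect separation, adaptation, morbidity, and economic valuation are out
of scope. The Q/I² gate is applied per zone with small site counts, where
Q has low power; with many sites per zone a pre-specified random-effects
model may be preferable. The uncertainty decomposition treats ensemble
members as exchangeable levels of a single "model" source and ignores
interaction terms beyond the clipped Shapley allocation.
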