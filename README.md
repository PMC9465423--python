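# heatattrib

Projection of heatwave-attributable mortality on a climate-model grid:
a tested pipeline for climate-health impact assessment, built for
environmental epidemiologists and climate-impact modellers who need the
full chain from daily temperature fields to an attributable-death burden
with honest uncertainty.

## What it computes

**Heatwave detection.** On gridded daily maximum temperature, a heatwave
is a run of ≥ 3 consecutive warm-season days (May–September) strictly
above the cell's 92.5th-percentile threshold from a 1986–2005 reference
period. Every day of a qualifying run counts and is credited to the
calendar month it falls in.

**Exposure-response.** Per location, the log relative risk β of death on
heatwave vs non-heatwave days comes from a Poisson GLM,
log E[deaths_t] = α + β·HW_t + Σ γ_j x_jt, with confounders as covariate
columns. Location estimates are pooled to climate-zone level by
inverse-variance meta-analysis; when Cochran's Q is significant *and*
I² ≥ 50% the DerSimonian-Laird random-effects model is used, otherwise
fixed effects.

**Attribution.** The attributable fraction is AF = (RR − 1)/RR, and the
attributable number per grid cell *p* and year *y* is

    AN(y,p) = Σ_m  Pop(y,p) · Mort_d(m,y,p) · HW(m,y,p) · AF(y,p)

with daily baseline mortality Mort_d = yearly rate × monthly death
proportion / days in month, summed over the warm-season months (and over
age groups when demography is age-stratified). Burdens are reported as
20-year window means (baseline 1986–2005; 2021–2040 "2030"; 2051–2070
"2060"; 2081–2100 "2090") with growth rates
(AN_future − AN_baseline)/AN_baseline × 100.

**Uncertainty.** Coefficients are sampled (1,000 draws by default) from
Normal(β̂, SE); 95% empirical CIs are the 2.5th/97.5th percentiles of the
burden across draws × climate-model ensemble members. The contributions of
coefficient noise, model spread, and population scenario to the total
variability, and the contributions of climate, population size, and aging
to the *change* in burden, are both allocated by sequential substitution
averaged over all factor orderings (Shapley decomposition), so the parts
sum exactly to the whole.

Because the real inputs of such studies (regional climate runs,
vital-registration mortality, census population surfaces) are not
redistributable, the package ships a first-class synthetic-data module —
seasonal-cycle + AR(1) + warming-trend temperature fields, age-structured
population trajectories with a mid-century peak and an aging trend, and
Poisson daily death counts with known true relative risks — so the whole
pipeline runs and is validated offline.

## Worked example

```python
>>> from heatattrib import attributable_fraction, growth_rate, scenario_difference
>>> attributable_fraction(1.08)        # RR 1.08 -> 7.4% of heatwave-day deaths
0.07407407407407414
>>> growth_rate(20303, 10264)          # end-of-century vs baseline burden, %
97.8078721745908
>>> scenario_difference(20303.0, 16769.0)  # avoided deaths under 1.5 degC
3534.0
```

The full synthetic study (10×10 half-degree grid, three warming scenarios
× three ensemble members, 1986–2100) runs end-to-end in well under a
minute:

```sh
heatattrib run-all --config examples/demo_config.yaml --out results/
```

which prints the national window summary (deaths per year; excerpt):

```
scenario   window           an      ci_low      ci_high  growth_pct
     low baseline   700.171317  484.939162   905.537455    0.000000
     low     2090  2352.817335 1624.501170  3040.926424  236.034522
     mid     2090  5503.008814 3798.347562  7123.528530  590.027949
    high     2090 13304.349597 9222.066930 17203.064741 1254.867824
```

Read: under the strongest-warming scenario the synthetic national burden
grows from ~982 to ~13,304 deaths/year by 2081–2100 (+1255%), and the CI
reflects coefficient and ensemble spread. `results/` also receives the
heatwave calendars, pooled relative risks with heterogeneity diagnostics,
driver decompositions, uncertainty-source shares, and the
stabilized-warming (1.5 °C analogue) comparison, each CSV stamped with the
config hash and seed.

Stage-by-stage subcommands (`simulate`, `detect`, `fit`, `attribute`,
`uncertainty`, `decompose`, `report`) expose the same operations on files;
see `heatattrib --help`. The model and numerical choices are documented in
`docs/methods.md`.

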