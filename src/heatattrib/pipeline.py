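"""End-to-end projection pipeline.

Stages, in order: synthesize (or load) gridded daily Tmax per scenario and
ensemble member → reference-period percentile thresholds → heatwave
calendars → location Poisson fits on daily deaths → zone-pooled relative
risks mapped onto the grid → attributable fractions and attributable
deaths per cell-year → 20-year-window point estimates with Monte-Carlo
empirical CIs → growth rates, driver decomposition (climate / population
size / aging), uncertainty-source shares, and the stabilized-warming
(1.5 °C analogue) comparison. All randomness fans out from one root seed;
every output table carries the configuration hash and that seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .attribution import (DEFAULT_WINDOWS, AttributionResult,
                          attributable_deaths, attributable_fraction,
                          decade_average, growth_rate)
from .cube import MONTH_DAYS, TemperatureCube
from .decomposition import FactorState, contribution_shares, decompose_change
from .demography import DemographyTable
from .exposure import (RREstimate, estimates_to_frame, fit_poisson_rr,
                       map_rr_to_grid, pool_zone)
from .grid import GridSpec
from .heatwave import (HeatwaveCalendar, compute_threshold,
                       detect_heatwave_days, heatwave_day_mask,
                       summarize_heatwaves)
from .io import config_hash, write_table
from .synthetic import (ClimateScenarioSpec, PopulationScenarioSpec,
                        TrueEffectSpec, generate_daily_mortality,
                        generate_population, generate_temperature,
                        latitude_graded_base_mean, seasonal_covariates)
from .uncertainty import (MonteCarloConfig, draw_betas, mc_attributable,
                          decompose_uncertainty, zone_base_burden)

log = logging.getLogger("heatattrib")


def substream(root_seed: int, *keys) -> int:
    """Deterministic, platform-stable child seed below 2^31."""
    token = f"{root_seed}|" + "|".join(str(k) for k in keys)
    digest = hashlib.sha256(token.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Full configuration of the synthetic demonstration study."""

    # grid
    nlat: int = 10
    nlon: int = 10
    lat0: float = 25.0
    lon0: float = 105.0
    spacing: float = 0.5
    n_zones: int = 4
    # periods
    ref_period: tuple[int, int] = (1986, 2005)
    horizon: tuple[int, int] = (1986, 2100)
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    # heatwave definition
    percentile: float = 92.5
    min_run: int = 3
    season: tuple[int, int] = (5, 9)
    # climate scenarios: name -> warming trend (°C per decade); the first
    # (weakest-trend) scenario doubles as the reference run for thresholds
    scenario_trends: dict = field(default_factory=lambda: {
        "low": 0.1, "mid": 0.25, "high": 0.5})
    n_models: int = 3
    sigma: float = 2.0
    rho: float = 0.7
    seasonal_amp: float = 12.0
    south_mean: float = 26.0
    lat_gradient: float = 1.2
    # exposure-response fitting
    obs_period: tuple[int, int] = (2007, 2013)
    sites_per_zone: int = 3
    site_baseline_deaths: float = 30.0
    true_log_rr_range: tuple[float, float] = (0.05, 0.10)
    confounder_coefs: dict = field(default_factory=lambda: {
        "season_sin": 0.05, "season_cos": -0.03})
    alpha_q: float = 0.05
    # population scenarios: name -> (peak_total, peak_year, aging_rate)
    pop_scenarios: dict = field(default_factory=lambda: {
        "low": (4.5e7, 2028, 0.0030),
        "medium": (5.0e7, 2030, 0.0025),
        "high": (5.5e7, 2035, 0.0020)})
    central_pop: str = "medium"
    # Monte Carlo
    mc_samples: int = 1000
    mc_percentiles: tuple[float, float] = (2.5, 97.5)
    uncertainty_param_draws: int = 200
    # root seed
    seed: int = 1234

    def __post_init__(self) -> None:
        self.ref_period = tuple(self.ref_period)
        self.horizon = tuple(self.horizon)
        self.season = tuple(self.season)
        self.obs_period = tuple(self.obs_period)
        self.windows = {k: tuple(v) for k, v in self.windows.items()}
        if self.central_pop not in self.pop_scenarios:
            raise ValueError("central_pop must be one of pop_scenarios")
        for name, (y0, y1) in self.windows.items():
            if y0 < self.horizon[0] or y1 > self.horizon[1]:
                raise ValueError(f"window {name!r} outside the data horizon")

    @property
    def ref_scenario(self) -> str:
        return min(self.scenario_trends, key=self.scenario_trends.get)

    def grid(self) -> GridSpec:
        return GridSpec(self.nlat, self.nlon, self.lat0, self.lon0,
                        self.spacing, self.n_zones)

    def models(self) -> list[str]:
        return [f"M{i + 1}" for i in range(self.n_models)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["windows"] = {k: list(v) for k, v in self.windows.items()}
        return d

    def hash(self) -> str:
        return config_hash(self.to_dict())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pop_scenarios" in raw:
            # YAML 1.1 reads exponent literals without a sign ("5.0e7")
            # as strings; coerce the numeric triple explicitly
            raw["pop_scenarios"] = {
                k: (float(v[0]), int(v[1]), float(v[2]))
                for k, v in raw["pop_scenarios"].items()}
        return cls(**raw)


# --------------------------------------------------------------------------
# stage helpers
# --------------------------------------------------------------------------

def climate_spec(cfg: PipelineConfig, scenario: str) -> ClimateScenarioSpec:
    base = latitude_graded_base_mean(cfg.grid(), cfg.south_mean, cfg.lat_gradient)
    return ClimateScenarioSpec(
        name=scenario, years=cfg.horizon, trend=cfg.scenario_trends[scenario],
        sigma=cfg.sigma, rho=cfg.rho, seasonal_amp=cfg.seasonal_amp,
        base_mean=tuple(base))


def true_zone_effects(cfg: PipelineConfig) -> TrueEffectSpec:
    """Ground-truth log-RRs, graded south (warm, largest) to north."""
    zones = cfg.grid().zones()
    lo, hi = cfg.true_log_rr_range
    k = len(zones)
    vals = np.linspace(hi, lo, k) if k > 1 else np.array([(lo + hi) / 2])
    return TrueEffectSpec(dict(zip(zones, vals)), dict(cfg.confounder_coefs))


def window_mean_hw(cal: HeatwaveCalendar, window: tuple[int, int]) -> pd.DataFrame:
    """Window-mean heatwave days per cell and month: (cell_id, month, hw_days)."""
    t = cal.table
    sub = t[(t["year"] >= window[0]) & (t["year"] <= window[1])]
    if sub.empty:
        raise ValueError(f"calendar does not cover {window}")
    return sub.groupby(["cell_id", "month"], as_index=False)["hw_days"].mean()


def burden_from_components(hw_mean: pd.DataFrame, pop: pd.DataFrame,
                           rates: Mapping[str, float], prop: np.ndarray,
                           af: pd.Series) -> float:
    """Evaluate the AN sum from independently supplied components.

    ``hw_mean``: (cell_id, month, hw_days); ``pop``: (cell_id, age_group,
    population); ``rates``: age_group → yearly rate; ``prop``: 12 monthly
    death proportions; ``af``: per-cell attributable fraction. This is the
    mixed-state evaluator behind the driver decomposition and the
    stabilized-climate comparison: any period's climate can be combined
    with any period's population and age structure.
    """
    death_w = pop.assign(
        dw=pop["population"] * pop["age_group"].map(rates).astype(float)
    ).groupby("cell_id")["dw"].sum()
    df = hw_mean.merge(death_w.rename("dw"), left_on="cell_id", right_index=True)
    m = df["month"].to_numpy()
    daily = prop[m - 1] / MONTH_DAYS[m - 1]
    an = df["dw"].to_numpy() * daily * df["hw_days"].to_numpy() \
        * af.reindex(df["cell_id"]).to_numpy()
    if np.isnan(an).any():
        raise ValueError("missing AF or population for some cells")
    return float(an.sum())


def window_population(dem: DemographyTable, window: tuple[int, int]) -> pd.DataFrame:
    """Window-mean population per cell and age group."""
    p = dem.population
    sub = p[(p["year"] >= window[0]) & (p["year"] <= window[1])]
    return sub.groupby(["cell_id", "age_group"], as_index=False)["population"].mean()


def frozen_rates(dem: DemographyTable, year: int = 2090) -> dict[str, float]:
    df = dem.death_rates
    sel = df[df["year"] == year]
    if sel.empty:  # fall back to the last available year
        sel = df[df["year"] == df["year"].max()]
    return dict(zip(sel["age_group"], sel["yearly_rate"]))


# --------------------------------------------------------------------------
# the driver
# --------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage on the configured synthetic study; return all results.

    When ``outdir`` is given, each stage's tables are written there as CSV
    with provenance headers. The returned dict holds the in-memory tables
    (see the keys written below).
    """
    grid = cfg.grid()
    zone_map = grid.zone_table()
    models = cfg.models()
    provenance = {"config_hash": cfg.hash(), "seed": cfg.seed}
    log.info("grid: %d cells, %d zones; models: %s", grid.n_cells,
             cfg.n_zones, models)

    # ---- climate: cubes -> thresholds -> heatwave calendars -------------
    calendars: dict[str, dict[str, HeatwaveCalendar]] = {
        s: {} for s in cfg.scenario_trends}
    thresholds = {}
    obs_cube: TemperatureCube | None = None
    ref_scen = cfg.ref_scenario
    for model in models:
        model_seed = substream(cfg.seed, "climate", model)
        for scen in sorted(cfg.scenario_trends,
                           key=lambda s: (s != ref_scen, s)):
            cube = generate_temperature(climate_spec(cfg, scen), grid,
                                        seed=model_seed, model=model)
            if scen == ref_scen:
                thresholds[model] = compute_threshold(
                    cube.subset_years(*cfg.ref_period), cfg.percentile,
                    season_only=True, season=cfg.season)
                if model == models[0]:
                    obs_cube = cube.subset_years(*cfg.obs_period)
            calendars[scen][model] = detect_heatwave_days(
                cube, thresholds[model], cfg.min_run, cfg.season)
        log.info("model %s: thresholds + %d scenario calendars done",
                 model, len(cfg.scenario_trends))

    # ---- exposure-response: site fits -> zone pooling -> grid -----------
    effects = true_zone_effects(cfg)
    obs_mask = heatwave_day_mask(obs_cube, thresholds[models[0]],
                                 cfg.min_run, cfg.season)
    covariates = seasonal_covariates(obs_cube.n_days)
    zone_cells = zone_map.groupby("zone")["cell_id"].apply(list)
    site_estimates: list[RREstimate] = []
    pooled: dict[str, RREstimate] = {}
    for zone in grid.zones():
        cells = zone_cells[zone]
        picks = [cells[i * len(cells) // cfg.sites_per_zone]
                 for i in range(cfg.sites_per_zone)]
        ests = []
        for j, cell in enumerate(picks):
            daily = generate_daily_mortality(
                effects, obs_mask[:, list(grid.cell_ids).index(cell)],
                covariates, cfg.site_baseline_deaths,
                seed=substream(cfg.seed, "mortality", zone, j), zone=zone)
            ests.append(fit_poisson_rr(daily["deaths"], daily["hw"],
                                       covariates, unit=f"{zone}/cell{cell}"))
        site_estimates.extend(ests)
        pooled[zone] = pool_zone(ests, cfg.alpha_q, unit=zone)
        log.info("zone %s: pooled RR %.3f (%s effects, I2=%.0f%%)", zone,
                 pooled[zone].rr, pooled[zone].model_used, pooled[zone].I2)
    rr_grid = map_rr_to_grid(pooled, zone_map)
    af_cells = pd.Series(attributable_fraction(rr_grid["rr"].to_numpy()),
                         index=pd.Index(rr_grid["cell_id"], name="cell_id"))

    # ---- demography ------------------------------------------------------
    dems: dict[str, DemographyTable] = {}
    pop_seed = substream(cfg.seed, "population")
    for name, (peak_total, peak_year, aging) in cfg.pop_scenarios.items():
        dems[name] = generate_population(
            PopulationScenarioSpec(name=name, peak_year=peak_year,
                                   aging_rate=aging, peak_total=peak_total),
            grid, cfg.horizon, seed=pop_seed)
    dem = dems[cfg.central_pop]

    # ---- attribution: annual AN, window points, CIs, growth -------------
    mc_cfg = MonteCarloConfig(cfg.mc_samples, substream(cfg.seed, "mc"),
                              cfg.mc_percentiles)
    annual: dict[str, pd.DataFrame] = {}
    summary_rows = []
    window_points: dict[str, dict[str, float]] = {}
    for scen in cfg.scenario_trends:
        nat = []
        per_window = {w: [] for w in cfg.windows}
        for model in models:
            res = attributable_deaths(dem, calendars[scen][model], af_cells,
                                      year_range=cfg.horizon, zone_map=zone_map)
            nat.append(res.national_annual().set_index("year")["an"])
            for w, span in cfg.windows.items():
                per_window[w].append(decade_average(res, span)["national"])
        annual[scen] = (pd.concat(nat, axis=1).mean(axis=1)
                        .rename("an").reset_index())
        window_points[scen] = {w: float(np.mean(v)) for w, v in per_window.items()}
        base_an = window_points[scen]["baseline"]
        for w, span in cfg.windows.items():
            mc = mc_attributable(mc_cfg, pooled, calendars[scen], dem,
                                 zone_map, span)
            summary_rows.append({
                "scenario": scen, "window": w, "an": window_points[scen][w],
                "an_mc_point": mc.point, "ci_low": mc.ci_low,
                "ci_high": mc.ci_high,
                "growth_pct": (growth_rate(window_points[scen][w], base_an)
                               if w != "baseline" else 0.0)})
        log.info("scenario %s: AN baseline=%.1f, 2090=%.1f", scen,
                 base_an, window_points[scen].get("2090", float("nan")))
    summary = pd.DataFrame(summary_rows)

    # ---- driver decomposition -------------------------------------------
    cell_w = dem.total_population()
    centre = int(np.mean(cfg.ref_period))
    cw = cell_w[cell_w["year"] == centre].set_index("cell_id")["population"]
    cell_weights = cw / cw.sum()
    rates = frozen_rates(dem)
    prop = dem.monthly_proportion
    age_groups = dem.age_groups

    def shares_at(window: tuple[int, int]) -> np.ndarray:
        p = window_population(dem, window)
        tot = p.groupby("age_group")["population"].sum()
        tot = tot.reindex(age_groups)
        return (tot / tot.sum()).to_numpy()

    def make_state(scen: str, wname: str) -> FactorState:
        span = cfg.windows[wname]
        return FactorState(
            climate={m: window_mean_hw(calendars[scen][m], span) for m in models},
            size=float(window_population(dem, span)["population"].sum()),
            aging=shares_at(span))

    def an_evaluator(climate, size, aging) -> float:
        vals = []
        for m, hwdf in climate.items():
            pop = pd.DataFrame({
                "cell_id": np.repeat(cell_weights.index.to_numpy(), len(age_groups)),
                "age_group": np.tile(age_groups, len(cell_weights)),
                "population": (cell_weights.to_numpy()[:, None] * size
                               * np.asarray(aging)[None, :]).reshape(-1)})
            vals.append(burden_from_components(hwdf, pop, rates, prop, af_cells))
        return float(np.mean(vals))

    window_order = list(cfg.windows)
    pairs = [(window_order[i], window_order[i + 1])
             for i in range(len(window_order) - 1)]
    if (window_order[0], window_order[-1]) not in pairs:
        pairs.append((window_order[0], window_order[-1]))
    driver_rows = []
    for scen in cfg.scenario_trends:
        for w_from, w_to in pairs:
            dec = decompose_change(make_state(scen, w_from),
                                   make_state(scen, w_to), an_evaluator)
            shares = (contribution_shares(dec)
                      if dec.total_change != 0 else None)
            for factor, contrib in dec.contributions.items():
                driver_rows.append({
                    "scenario": scen, "period_pair": f"{w_from}->{w_to}",
                    "factor": factor, "contribution_deaths": contrib,
                    "share_pct": (float(shares[factor]) if shares is not None
                                  else float("nan")),
                    "mixed_sign": (bool(shares.attrs["mixed_sign"])
                                   if shares is not None else False),
                    "total_change": dec.total_change})
    drivers = pd.DataFrame(driver_rows)

    # ---- uncertainty-source shares (final window) -----------------------
    final_w = window_order[-1]
    span_f = cfg.windows[final_w]
    u_cfg = MonteCarloConfig(cfg.uncertainty_param_draws,
                             substream(cfg.seed, "uncertainty"),
                             cfg.mc_percentiles)
    beta_hat = {z: e.beta for z, e in pooled.items()}
    unc_rows = []
    for scen in cfg.scenario_trends:
        bases = {(m, p): zone_base_burden(dems[p], calendars[scen][m],
                                          zone_map, span_f)
                 for m in models for p in dems}
        mean_base = {p: sum(bases[(m, p)] for m in models) / len(models)
                     for p in dems}
        draws = draw_betas(u_cfg, pooled)
        draw_list = [{z: draws[z][i] for z in draws}
                     for i in range(u_cfg.n_samples)]

        def evaluate(assign: Mapping[str, object]) -> float:
            beta = assign["rr_parameters"]
            model = assign["climate_models"]
            popn = assign["population_scenarios"]
            base = (mean_base[popn] if model == "__mean__"
                    else bases[(model, popn)])
            rr = np.exp(np.array([beta[z] for z in base.index]))
            af = np.maximum((rr - 1.0) / rr, 0.0)
            return float(np.sum(base.to_numpy() * af))

        res = decompose_uncertainty(
            evaluate,
            levels={"rr_parameters": draw_list,
                    "climate_models": models,
                    "population_scenarios": list(dems)},
            central={"rr_parameters": beta_hat,
                     "climate_models": "__mean__",
                     "population_scenarios": cfg.central_pop})
        for src, pct in res.shares.items():
            unc_rows.append({"scenario": scen, "window": final_w,
                             "source": src, "share_pct": float(pct)})
    uncertainty = pd.DataFrame(unc_rows)

    # ---- 1.5 °C analogue: stabilized climate + end-of-century people ----
    stab_window = cfg.windows.get("2030", (2021, 2040))
    pop_f = window_population(dem, span_f)
    one5_vals = [burden_from_components(
        window_mean_hw(calendars[ref_scen][m], stab_window),
        pop_f, rates, prop, af_cells) for m in models]
    an_1p5 = float(np.mean(one5_vals))
    one_five = pd.DataFrame([
        {"scenario": s, "window": final_w,
         "an_scenario": window_points[s][final_w], "an_1p5": an_1p5,
         "avoided_deaths": window_points[s][final_w] - an_1p5}
        for s in cfg.scenario_trends])

    # ---- heatwave summaries ---------------------------------------------
    hw_rows = []
    for scen in cfg.scenario_trends:
        per_model = [summarize_heatwaves(calendars[scen][m],
                                         windows=cfg.windows)
                     for m in models]
        ann = (pd.concat([s["annual_mean"].set_index("year")["mean_hw_days"]
                          for s in per_model], axis=1).mean(axis=1))
        hw_rows.append(ann.rename(scen))
    hw_national = pd.concat(hw_rows, axis=1).reset_index()

    results = {
        "config_hash": cfg.hash(), "seed": cfg.seed,
        "zone_map": zone_map,
        "rr_estimates": estimates_to_frame(
            site_estimates + [pooled[z] for z in sorted(pooled)]),
        "rr_grid": rr_grid,
        "af": af_cells,
        "calendars": calendars,
        "pooled_rr": pooled,
        "demography": dems,
        "annual": annual,
        "summary": summary,
        "window_points": window_points,
        "drivers": drivers,
        "uncertainty": uncertainty,
        "one_five": one_five,
        "hw_national": hw_national,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(zone_map, outdir / "zones.csv", provenance)
        write_table(results["rr_estimates"], outdir / "rr_estimates.csv", provenance)
        write_table(rr_grid, outdir / "rr_grid.csv", provenance)
        write_table(summary, outdir / "summary_windows.csv", provenance)
        write_table(drivers, outdir / "drivers.csv", provenance)
        write_table(uncertainty, outdir / "uncertainty_shares.csv", provenance)
        write_table(one_five, outdir / "scenario_1p5.csv", provenance)
        write_table(hw_national, outdir / "hw_national.csv", provenance)
        for scen in cfg.scenario_trends:
            write_table(annual[scen], outdir / f"an_annual_{scen}.csv", provenance)
            for m in models:
                write_table(calendars[scen][m].table,
                            outdir / f"hw_calendar_{scen}_{m}.csv", provenance)
        write_table(dem.population, outdir / "population_medium.csv", provenance)
        write_table(dem.death_rates, outdir / "mortality_rates.csv", provenance)
        log.info("wrote outputs to %s", outdir)
    return results
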