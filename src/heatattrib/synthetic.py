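"""Synthetic climate, demography, and daily-mortality generators.

The real inputs behind national heatwave-mortality projections — regional
climate-model runs, census-based population surfaces, vital-registration
death counts — are rarely redistributable. This module generates stand-ins
with the statistical structure the downstream analysis assumes, so every
stage of the pipeline is testable offline:

* daily Tmax fields = per-cell annual mean + seasonal sinusoid (peaking
  mid-July) + a linear warming trend + AR(1) weather noise, on a 365-day
  no-leap calendar;
* age-structured population trajectories that rise to a configurable peak
  year then decline, with a secularly increasing 75+ share ("aging") and
  age-specific mortality rates frozen at their 2010s mean for future years;
* daily death counts drawn from a Poisson exposure-response model with a
  known true log relative risk per climate zone, for parameter-recovery
  tests of the regression stage.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .cube import DAYS_PER_YEAR, TemperatureCube, noleap_time_axis
from .demography import DemographyTable, uniform_monthly_proportion
from .grid import GridSpec

#: day-of-year of the seasonal-cycle maximum (mid-July).
SEASONAL_PEAK_DOY = 196


# --------------------------------------------------------------------------
# scenario specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClimateScenarioSpec:
    """One scenario/model temperature run.

    trend is °C of warming per decade, applied linearly over the run;
    sigma is the AR(1) innovation SD (°C) and rho the lag-1 autocorrelation,
    so day-to-day weather noise has stationary SD sigma/sqrt(1-rho²).
    base_mean is the annual-mean Tmax per cell: a scalar, or an array of
    one value per grid cell (letting latitude create climate zones).
    """

    name: str
    years: tuple[int, int]
    trend: float = 0.0
    sigma: float = 2.0
    rho: float = 0.7
    seasonal_amp: float = 12.0
    base_mean: float | tuple[float, ...] = 22.0

    def __post_init__(self) -> None:
        if self.years[1] < self.years[0]:
            raise ValueError("empty year range")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        vals = np.r_[self.trend, self.sigma, self.rho, self.seasonal_amp,
                     np.asarray(self.base_mean, dtype=float).ravel()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("scenario parameters must be finite")


@dataclass(frozen=True)
class PopulationScenarioSpec:
    """A fertility-variant population trajectory.

    The national total follows a bell curve peaking at ``peak_year``; the
    75+ population share increases linearly at ``aging_rate`` per year
    (the operational meaning of "aging" here), with the younger groups
    absorbing the complement in their initial proportions.
    """

    name: str = "medium"
    peak_year: int = 2030
    aging_rate: float = 0.0025
    age_groups: tuple[str, ...] = ("0-64", "65-74", "75+")
    initial_shares: tuple[float, ...] = (0.80, 0.12, 0.08)
    death_rates: tuple[float, ...] = (0.002, 0.02, 0.08)
    peak_total: float = 5.0e7
    traj_scale: float = 60.0
    rate_drift: float = 0.0
    rate_freeze_window: tuple[int, int] = (2010, 2019)

    def __post_init__(self) -> None:
        if len(self.initial_shares) != len(self.age_groups):
            raise ValueError("one initial share per age group")
        if len(self.death_rates) != len(self.age_groups):
            raise ValueError("one death rate per age group")
        if abs(sum(self.initial_shares) - 1.0) > 1e-9:
            raise ValueError("initial age shares must sum to 1")
        if any(r < 0 for r in self.death_rates):
            raise ValueError("negative mortality rate")
        if self.aging_rate < 0:
            raise ValueError("aging_rate must be nonnegative")


@dataclass(frozen=True)
class TrueEffectSpec:
    """Ground-truth effects for parameter-recovery tests.

    zone_log_rr maps climate zone → true log relative risk of death on a
    heatwave day; confounder_coefs maps covariate name → its coefficient
    in the log-linear mortality model.
    """

    zone_log_rr: dict[str, float] = field(default_factory=lambda: {"Z1": 0.07})
    confounder_coefs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = list(self.zone_log_rr.values()) + list(self.confounder_coefs.values())
        if not np.all(np.isfinite(vals)):
            raise ValueError("effect parameters must be finite")

    def log_rr(self, zone: str | None = None) -> float:
        if zone is None:
            if len(self.zone_log_rr) != 1:
                raise ValueError("zone must be given when several zones are defined")
            return next(iter(self.zone_log_rr.values()))
        return self.zone_log_rr[zone]


# --------------------------------------------------------------------------
# temperature
# --------------------------------------------------------------------------

def latitude_graded_base_mean(grid: GridSpec, south_mean: float = 26.0,
                              gradient_per_deg: float = 1.2) -> np.ndarray:
    """Annual-mean Tmax per cell, cooling with latitude (°C per degree north)."""
    return south_mean - gradient_per_deg * (grid.cell_lat() - grid.lat0)


def generate_temperature(spec: ClimateScenarioSpec, grid: GridSpec,
                         seed: int, model: str = "M1") -> TemperatureCube:
    """Simulate a daily Tmax cube for one scenario and ensemble member.

    Daily value per cell = base_mean + seasonal_amp·cos(2π(doy−196)/365)
    + (trend/10)·(years since run start) + AR(1) noise. Distinct ensemble
    members of the same scenario are produced by distinct seeds.
    """
    years, months, doy = noleap_time_axis(*spec.years)
    n_t = len(years)
    base = np.asarray(spec.base_mean, dtype=float).ravel()
    if base.size == 1:
        base = np.full(grid.n_cells, base[0])
    elif base.size != grid.n_cells:
        raise ValueError("base_mean length must equal the number of grid cells")

    seasonal = spec.seasonal_amp * np.cos(
        2 * np.pi * (doy - SEASONAL_PEAK_DOY) / DAYS_PER_YEAR
    )
    elapsed = (years - spec.years[0]) + (doy - 1) / DAYS_PER_YEAR
    trend = (spec.trend / 10.0) * elapsed

    rng = np.random.default_rng(seed)
    innov = rng.standard_normal((n_t, grid.n_cells)) * spec.sigma
    noise = lfilter([1.0], [1.0, -spec.rho], innov, axis=0)

    tasmax = base[None, :] + (seasonal + trend)[:, None] + noise
    return TemperatureCube(tasmax, years, months, doy, grid,
                           scenario=spec.name, model=model)


# --------------------------------------------------------------------------
# population & mortality rates
# --------------------------------------------------------------------------

def _age_shares(spec: PopulationScenarioSpec, years: np.ndarray) -> np.ndarray:
    """(n_years, n_groups) age-group shares; the last group is the 75+ band."""
    s_old0 = spec.initial_shares[-1]
    s_old = np.clip(s_old0 + spec.aging_rate * (years - years[0]), 0.0, 0.6)
    young0 = np.asarray(spec.initial_shares[:-1])
    young = (1.0 - s_old)[:, None] * (young0 / young0.sum())[None, :]
    return np.column_stack([young, s_old])


def generate_population(spec: PopulationScenarioSpec, grid: GridSpec,
                        years: range | tuple[int, int], seed: int) -> DemographyTable:
    """Simulate the gridded age-structured population and its death rates.

    The national total rises to ``peak_year`` then declines (Gaussian-in-
    time trajectory); each cell holds a fixed share of the total (Dirichlet
    weights drawn once from ``seed``, creating persistent population
    hotspots). Yearly mortality rates may drift before the freeze window
    and are held at the window mean for all later years, reflecting the
    standard assumption that future baseline rates match the recent past.
    """
    if not isinstance(years, range):
        years = range(years[0], years[1] + 1)
    yr = np.array(list(years))
    if yr.size == 0:
        raise ValueError("empty year range")

    total = spec.peak_total * np.exp(-0.5 * ((yr - spec.peak_year) / spec.traj_scale) ** 2)
    shares = _age_shares(spec, yr)

    rng = np.random.default_rng(seed)
    cell_w = rng.dirichlet(np.full(grid.n_cells, 5.0))

    n_g = len(spec.age_groups)
    pop = pd.DataFrame({
        "cell_id": np.repeat(grid.cell_ids, yr.size * n_g),
        "year": np.tile(np.repeat(yr, n_g), grid.n_cells),
        "age_group": np.tile(list(spec.age_groups), yr.size * grid.n_cells),
        "population": (
            cell_w[:, None, None] * total[None, :, None] * shares[None, :, :]
        ).reshape(-1),
    })

    f0, f1 = spec.rate_freeze_window
    base = np.asarray(spec.death_rates)
    drift = 1.0 + spec.rate_drift * (yr - f0)
    rates = np.where(yr[:, None] <= f1, base[None, :] * drift[:, None], np.nan)
    in_win = (yr >= f0) & (yr <= f1)
    frozen = (base[None, :] * drift[in_win, None]).mean(axis=0) if in_win.any() else base
    rates = np.where(np.isnan(rates), frozen[None, :], rates)
    if (rates < 0).any():
        raise ValueError("rate drift produced a negative mortality rate")

    rate_df = pd.DataFrame({
        "year": np.repeat(yr, n_g),
        "age_group": np.tile(list(spec.age_groups), yr.size),
        "yearly_rate": rates.reshape(-1),
    })
    return DemographyTable(pop, rate_df, uniform_monthly_proportion())


# --------------------------------------------------------------------------
# daily deaths for exposure-response fitting
# --------------------------------------------------------------------------

def seasonal_covariates(n_days: int, dow_start: int = 0) -> pd.DataFrame:
    """Default confounder columns: annual sin/cos terms and day-of-week dummies."""
    t = np.arange(n_days)
    cov = {
        "season_sin": np.sin(2 * np.pi * t / DAYS_PER_YEAR),
        "season_cos": np.cos(2 * np.pi * t / DAYS_PER_YEAR),
    }
    dow = (t + dow_start) % 7
    for d in range(1, 7):
        cov[f"dow_{d}"] = (dow == d).astype(float)
    return pd.DataFrame(cov)


def generate_daily_mortality(effects: TrueEffectSpec, hw_indicator: np.ndarray,
                             covariates: pd.DataFrame | None,
                             baseline_rate: float, seed: int,
                             zone: str | None = None) -> pd.DataFrame:
    """Draw daily death counts from the log-linear Poisson model.

    log E[deaths_t] = log(baseline_rate) + logRR·HW_t + Σ_j γ_j x_{jt}.
    Returns a table with columns deaths, hw, and the covariates, ready for
    the regression stage.
    """
    hw = np.asarray(hw_indicator, dtype=float)
    log_mu = np.log(baseline_rate) + effects.log_rr(zone) * hw
    if covariates is not None:
        if len(covariates) != len(hw):
            raise ValueError("covariates and hw series differ in length")
        for name, coef in effects.confounder_coefs.items():
            if name not in covariates.columns:
                raise ValueError(f"covariate {name!r} missing from table")
            log_mu = log_mu + coef * covariates[name].to_numpy()
    rng = np.random.default_rng(seed)
    deaths = rng.poisson(np.exp(log_mu))
    out = pd.DataFrame({"deaths": deaths, "hw": hw.astype(int)})
    if covariates is not None:
        out = pd.concat([out, covariates.reset_index(drop=True)], axis=1)
    return out
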