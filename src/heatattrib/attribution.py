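"""Attributable fraction and attributable deaths per grid cell and year.

The burden calculation converts relative risk into the attributable
fraction AF = (RR − 1)/RR, then accumulates attributable deaths over the
warm-season months:

    AN(y, p) = Σ_m Pop(y, p) · Mort_d(m, y, p) · HW(m, y, p) · AF(y, p),

where Mort_d(m, y, p) = yearly rate × monthly proportion(m) / days(m) is
the daily baseline mortality rate. With age-stratified demography the
product is evaluated per age group (age-specific population and rate, and
age-specific AF when supplied) and summed. AN is exactly linear in
population, mortality rate, heatwave days, and AF separately, and additive
over cells and months; those are load-bearing properties for the driver
decomposition and are covered by the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cube import MONTH_DAYS
from .demography import DemographyTable
from .heatwave import HeatwaveCalendar

AN_SCHEMA = ["cell_id", "year", "an"]

#: the four 20-year reporting windows, keyed by their conventional centre label
DEFAULT_WINDOWS: dict[str, tuple[int, int]] = {
    "baseline": (1986, 2005),
    "2030": (2021, 2040),
    "2060": (2051, 2070),
    "2090": (2081, 2100),
}


def attributable_fraction(rr, allow_protective: bool = False):
    """AF = (RR − 1)/RR, elementwise.

    RR below 1 would give a negative ("protective") fraction; by default
    such values are floored at 0 and a warning reports how many were
    floored. Pass ``allow_protective=True`` to keep them. RR ≤ 0 is
    rejected outright.
    """
    rr_arr = np.asarray(rr, dtype=float)
    if np.any(rr_arr <= 0):
        raise ValueError("relative risk must be positive")
    af = (rr_arr - 1.0) / rr_arr
    if not allow_protective:
        n_floored = int(np.sum(af < 0))
        if n_floored:
            warnings.warn(f"floored {n_floored} protective AF value(s) at 0",
                          stacklevel=2)
            af = np.maximum(af, 0.0)
    return af if rr_arr.ndim else float(af)


@dataclass
class AttributionResult:
    """Annual attributable deaths per grid cell.

    ``table`` has columns (cell_id, year, an); zone/province aggregation
    uses an optional assignment table carried alongside.
    """

    table: pd.DataFrame
    zone_map: pd.DataFrame | None = None
    scenario: str = ""
    model: str = ""

    def __post_init__(self) -> None:
        for col in AN_SCHEMA:
            if col not in self.table.columns:
                raise ValueError(f"attribution table missing column {col!r}")

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.table["year"].unique())

    def national_annual(self) -> pd.DataFrame:
        """National AN per year: columns (year, an)."""
        return self.table.groupby("year", as_index=False)["an"].sum()

    def by_region(self, region_col: str = "province") -> pd.DataFrame:
        if self.zone_map is None:
            raise ValueError("no zone/province assignment attached")
        merged = self.table.merge(self.zone_map[["cell_id", region_col]], on="cell_id")
        return merged.groupby([region_col, "year"], as_index=False)["an"].sum()


def _af_frame(af, age_groups: list[str]) -> pd.DataFrame:
    """Normalise the AF input to columns (cell_id[, age_group], af)."""
    if isinstance(af, pd.DataFrame):
        if "af" not in af.columns or "cell_id" not in af.columns:
            raise ValueError("AF table needs columns cell_id and af")
        return af
    if isinstance(af, pd.Series):
        return af.rename("af").rename_axis("cell_id").reset_index()
    raise TypeError("af must be a Series indexed by cell_id or a DataFrame")


def attributable_deaths(dem: DemographyTable, cal: HeatwaveCalendar, af,
                        year_range: tuple[int, int] | None = None,
                        zone_map: pd.DataFrame | None = None) -> AttributionResult:
    """Evaluate the AN sum for every cell and year.

    ``af`` is either a Series of per-cell attributable fractions (indexed
    by cell_id) or a DataFrame (cell_id[, age_group], af) for age-specific
    fractions. Only warm-season months carry heatwave days, so the month
    sum runs over the calendar's season window.
    """
    hw = cal.table
    if year_range is not None:
        hw = hw[(hw["year"] >= year_range[0]) & (hw["year"] <= year_range[1])]
        if sorted(hw["year"].unique()) != list(range(year_range[0], year_range[1] + 1)):
            raise ValueError(f"heatwave calendar does not cover {year_range}")
    if hw.empty:
        raise ValueError("no heatwave-calendar rows in the requested years")

    pop_years = set(dem.population["year"].unique())
    missing_years = set(hw["year"].unique()) - pop_years
    if missing_years:
        raise ValueError(f"demography missing years {sorted(missing_years)[:5]}")

    df = hw.merge(dem.population, on=["cell_id", "year"], how="left")
    if df["population"].isna().any():
        bad = df.loc[df["population"].isna(), "cell_id"].unique()
        raise ValueError(f"no population for cell(s) {bad[:5]}")
    df = df.merge(dem.death_rates, on=["year", "age_group"], how="left")
    if df["yearly_rate"].isna().any():
        raise ValueError("death-rate table does not cover all year/age-group pairs")

    prop = dem.monthly_proportion
    daily_rate = df["yearly_rate"].to_numpy() * prop[df["month"].to_numpy() - 1] \
        / MONTH_DAYS[df["month"].to_numpy() - 1]

    af_df = _af_frame(af, dem.age_groups)
    keys = ["cell_id", "age_group"] if "age_group" in af_df.columns else ["cell_id"]
    df = df.merge(af_df, on=keys, how="left")
    if df["af"].isna().any():
        bad = df.loc[df["af"].isna(), "cell_id"].unique()
        raise ValueError(f"no attributable fraction for cell(s) {bad[:5]}")

    df["an"] = df["population"].to_numpy() * daily_rate \
        * df["hw_days"].to_numpy() * df["af"].to_numpy()
    out = df.groupby(["cell_id", "year"], as_index=False)["an"].sum()
    return AttributionResult(out, zone_map=zone_map,
                             scenario=cal.scenario, model=cal.model)


def decade_average(res: AttributionResult, window: tuple[int, int]) -> dict:
    """Mean annual AN over a (typically 20-year) window.

    Returns {'national': scalar, 'per_cell': DataFrame(cell_id, an)}.
    The window must be fully covered by the result.
    """
    y0, y1 = window
    have = set(res.years)
    need = set(range(y0, y1 + 1))
    if not need <= have:
        raise ValueError(f"window {window} not fully covered; missing "
                         f"{sorted(need - have)[:5]}")
    sub = res.table[(res.table["year"] >= y0) & (res.table["year"] <= y1)]
    per_cell = sub.groupby("cell_id", as_index=False)["an"].mean()
    return {"national": float(per_cell["an"].sum()), "per_cell": per_cell}


def growth_rate(future: float, baseline: float) -> float:
    """Percentage change of the future burden relative to baseline:
    (future − baseline) / baseline × 100."""
    if baseline <= 0:
        raise ValueError("baseline burden must be positive")
    return (future - baseline) / baseline * 100.0


def scenario_difference(res_a, res_b, window: tuple[int, int] | None = None) -> dict | float:
    """Avoided deaths: decade-average AN under A minus under B.

    Accepts two AttributionResults (returns national scalar plus the
    per-cell field) or two plain decade-average numbers (returns their
    difference) for worked comparisons of published totals.
    """
    if np.isscalar(res_a) and np.isscalar(res_b):
        return float(res_a) - float(res_b)
    if window is None:
        raise ValueError("window required for gridded results")
    da, db = decade_average(res_a, window), decade_average(res_b, window)
    merged = da["per_cell"].merge(db["per_cell"], on="cell_id",
                                  suffixes=("_a", "_b"), how="outer")
    if merged[["an_a", "an_b"]].isna().any().any():
        raise ValueError("results cover different cells")
    merged["avoided"] = merged["an_a"] - merged["an_b"]
    return {"national": float(merged["avoided"].sum()),
            "per_cell": merged[["cell_id", "avoided"]]}
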