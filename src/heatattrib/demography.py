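"""Population, baseline mortality rates, and monthly death proportions.

The attributable-deaths formula needs, per grid cell and year: population
(optionally split into age groups), a yearly baseline mortality rate per
age group (deaths per person per year), and the fraction of a year's
deaths falling in each calendar month. ``DemographyTable`` bundles the
three; daily baseline mortality in month m is
``yearly_rate * monthly_proportion[m] / days_in_month[m]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cube import MONTH_DAYS

POPULATION_SCHEMA = ["cell_id", "year", "age_group", "population"]
RATE_SCHEMA = ["year", "age_group", "yearly_rate"]


def uniform_monthly_proportion() -> np.ndarray:
    """Deaths spread uniformly over days: month share = month length / 365."""
    return MONTH_DAYS / MONTH_DAYS.sum()


@dataclass
class DemographyTable:
    """Per-cell, per-year, per-age-group demography.

    Attributes
    ----------
    population : DataFrame with columns (cell_id, year, age_group, population).
    death_rates : DataFrame with columns (year, age_group, yearly_rate),
        deaths per person per year; applies to all cells.
    monthly_proportion : array of 12 month shares of annual deaths, summing
        to 1. Default: uniform over days.
    """

    population: pd.DataFrame
    death_rates: pd.DataFrame
    monthly_proportion: np.ndarray = field(default_factory=uniform_monthly_proportion)

    def __post_init__(self) -> None:
        for col in POPULATION_SCHEMA:
            if col not in self.population.columns:
                raise ValueError(f"population table missing column {col!r}")
        for col in RATE_SCHEMA:
            if col not in self.death_rates.columns:
                raise ValueError(f"death-rate table missing column {col!r}")
        self.monthly_proportion = np.asarray(self.monthly_proportion, dtype=float)
        if self.monthly_proportion.shape != (12,):
            raise ValueError("monthly_proportion must have 12 entries")
        if abs(self.monthly_proportion.sum() - 1.0) > 1e-9:
            raise ValueError("monthly proportions must sum to 1")
        if (self.population["population"] < 0).any():
            raise ValueError("negative population")
        if (self.death_rates["yearly_rate"] < 0).any():
            raise ValueError("negative mortality rate")

    @property
    def age_groups(self) -> list[str]:
        return list(pd.unique(self.population["age_group"]))

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.population["year"].unique())

    def total_population(self) -> pd.DataFrame:
        """Population summed over age groups: columns (cell_id, year, population)."""
        return (
            self.population.groupby(["cell_id", "year"], as_index=False)["population"]
            .sum()
        )

    def national_population(self, year: int) -> float:
        df = self.population
        return float(df.loc[df["year"] == year, "population"].sum())

    def rate(self, year: int, age_group: str) -> float:
        df = self.death_rates
        sel = df[(df["year"] == year) & (df["age_group"] == age_group)]
        if sel.empty:
            raise KeyError(f"no mortality rate for year={year}, age_group={age_group!r}")
        return float(sel["yearly_rate"].iloc[0])

    def scaled(self, factor: float) -> "DemographyTable":
        """Copy with every population count multiplied by ``factor``."""
        pop = self.population.copy()
        pop["population"] = pop["population"] * factor
        return DemographyTable(pop, self.death_rates, self.monthly_proportion)
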