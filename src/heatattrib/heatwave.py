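"""Percentile thresholds and run-length heatwave detection.

A heatwave is a run of at least ``min_run`` consecutive warm-season days
(May–September by default) on which daily maximum temperature strictly
exceeds the cell's reference-period percentile threshold (92.5th of
1986–2005 by default). Every day of a qualifying run is a heatwave day and
is credited to the calendar month it falls in, so a spell straddling a
month boundary splits its days between the two months. Spells are
truncated at the season edges before the run-length test: the out-of-season
part of a hot spell never counts, and the in-season part must itself reach
``min_run``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cube import TemperatureCube

CALENDAR_SCHEMA = ["cell_id", "year", "month", "hw_days"]

DEFAULT_PERCENTILE = 92.5
DEFAULT_MIN_RUN = 3
DEFAULT_SEASON = (5, 9)


@dataclass(frozen=True)
class ThresholdField:
    """Per-cell temperature threshold (°C) from a reference period."""

    values: np.ndarray
    percentile: float
    ref_years: tuple[int, int]
    season: tuple[int, int] | None = DEFAULT_SEASON

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("threshold field must be 1-D (one value per cell)")
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must be in (0, 100)")


@dataclass
class HeatwaveCalendar:
    """Heatwave-day counts per (cell, year, month).

    ``table`` has columns (cell_id, year, month, hw_days) and contains a
    row for every cell × year × in-season month, zeros included, so
    downstream joins never drop silent missing months.
    """

    table: pd.DataFrame
    min_run: int = DEFAULT_MIN_RUN
    season: tuple[int, int] = DEFAULT_SEASON
    scenario: str = ""
    model: str = ""

    def __post_init__(self) -> None:
        for col in CALENDAR_SCHEMA:
            if col not in self.table.columns:
                raise ValueError(f"heatwave calendar missing column {col!r}")
        if (self.table["hw_days"] < 0).any():
            raise ValueError("negative heatwave-day count")

    def annual(self) -> pd.DataFrame:
        """Heatwave days per cell and year: columns (cell_id, year, hw_days)."""
        return self.table.groupby(["cell_id", "year"], as_index=False)["hw_days"].sum()

    def subset_years(self, year_start: int, year_end: int) -> "HeatwaveCalendar":
        t = self.table
        sub = t[(t["year"] >= year_start) & (t["year"] <= year_end)].reset_index(drop=True)
        return HeatwaveCalendar(sub, self.min_run, self.season, self.scenario, self.model)


def season_mask(months: np.ndarray, season: tuple[int, int] = DEFAULT_SEASON) -> np.ndarray:
    lo, hi = season
    return (months >= lo) & (months <= hi)


def compute_threshold(ref: TemperatureCube, percentile: float = DEFAULT_PERCENTILE,
                      season_only: bool = True,
                      season: tuple[int, int] = DEFAULT_SEASON) -> ThresholdField:
    """Per-cell percentile of pooled reference-period daily Tmax.

    By default the percentile is taken over warm-season days only, so the
    threshold is exceeded on about (100−percentile)% of in-season days of
    the reference run itself. Linear interpolation between order statistics
    (numpy's default) is the fixed convention. Thresholds are strictly
    per-cell: no pooling across cells.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    if ref.n_days == 0:
        raise ValueError("empty reference series")
    vals = ref.tasmax
    if season_only:
        m = season_mask(ref.months, season)
        if not m.any():
            raise ValueError("reference cube has no in-season days")
        vals = vals[m]
    thr = np.percentile(vals, percentile, axis=0)
    return ThresholdField(thr, percentile, ref.year_range(),
                          season if season_only else None)


def heatwave_day_mask(cube: TemperatureCube, thr: ThresholdField,
                      min_run: int = DEFAULT_MIN_RUN,
                      season: tuple[int, int] = DEFAULT_SEASON) -> np.ndarray:
    """Boolean (time, cell) mask of heatwave days.

    A day qualifies iff it belongs to a maximal run of ≥ min_run
    consecutive days that are (a) in season and (b) strictly above the
    cell threshold. Because out-of-season days can never qualify, runs are
    automatically confined to the season window, and the winter gap
    prevents runs from spanning years.
    """
    if thr.values.size != cube.n_cells:
        raise ValueError("threshold field and cube disagree on cell count")
    if cube.n_days < min_run:
        raise ValueError("temperature series shorter than one heatwave")
    hot = (cube.tasmax > thr.values[None, :]) & season_mask(cube.months, season)[:, None]

    # per cell: locate run boundaries with a padded diff, keep runs >= min_run
    n_t, n_c = hot.shape
    out = np.zeros((n_t, n_c), dtype=bool)
    for c in range(n_c):
        edges = np.diff(np.r_[0, hot[:, c].astype(np.int8), 0])
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_run:
                out[s:e, c] = True
    return out


def detect_heatwave_days(cube: TemperatureCube, thr: ThresholdField,
                         min_run: int = DEFAULT_MIN_RUN,
                         season: tuple[int, int] = DEFAULT_SEASON) -> HeatwaveCalendar:
    """Count heatwave days per cell, year, and calendar month."""
    mask = heatwave_day_mask(cube, thr, min_run, season)
    years = np.unique(cube.years)
    months = np.arange(season[0], season[1] + 1)
    # aggregate with a dense (year, month) index so zero months are explicit
    yi = np.searchsorted(years, cube.years)
    mi = cube.months - season[0]
    counts = np.zeros((len(years), len(months), cube.n_cells), dtype=np.int64)
    in_seas = season_mask(cube.months, season)
    np.add.at(counts, (yi[in_seas], mi[in_seas]),
              mask[in_seas].astype(np.int64))
    table = pd.DataFrame({
        "cell_id": np.tile(cube.grid.cell_ids, len(years) * len(months)),
        "year": np.repeat(years, len(months) * cube.n_cells),
        "month": np.tile(np.repeat(months, cube.n_cells), len(years)),
        "hw_days": counts.reshape(-1),
    })
    return HeatwaveCalendar(table, min_run, season, cube.scenario, cube.model)


def summarize_heatwaves(cal: HeatwaveCalendar,
                        windows: dict[str, tuple[int, int]] | None = None,
                        area_threshold_days: float = 10.0) -> dict[str, pd.DataFrame | float]:
    """National annual totals, per-window multi-year means, and area fractions.

    Returns a dict with:
      annual_mean  — mean heatwave days per cell for each year (the national
                     annual-frequency curve);
      window_mean  — per-cell multi-year mean heatwave days per window;
      area_fraction — per window, fraction of cells whose multi-year mean
                     exceeds ``area_threshold_days``.
    """
    annual = cal.annual()
    national = annual.groupby("year", as_index=False)["hw_days"].mean()
    national = national.rename(columns={"hw_days": "mean_hw_days"})
    out: dict[str, pd.DataFrame | float] = {"annual_mean": national}
    if windows:
        rows, frac = [], {}
        for name, (y0, y1) in windows.items():
            sub = annual[(annual["year"] >= y0) & (annual["year"] <= y1)]
            per_cell = sub.groupby("cell_id", as_index=False)["hw_days"].mean()
            per_cell["window"] = name
            rows.append(per_cell)
            frac[name] = float((per_cell["hw_days"] > area_threshold_days).mean())
        out["window_mean"] = pd.concat(rows, ignore_index=True)
        out["area_fraction"] = pd.Series(frac)
    return out
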