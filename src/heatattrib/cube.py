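"""Gridded daily-maximum-temperature container on a 365-day no-leap calendar.

Climate-model output is conventionally delivered on a no-leap calendar;
every year here has exactly 365 days and February always has 28. The cube
stores values as a dense (time, cell) array with explicit year / month /
day-of-year coordinates, and converts to a CF-style (time, lat, lon) xarray
Dataset at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .grid import GridSpec

#: Days per month, no-leap calendar.
MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
DAYS_PER_YEAR = 365

# month (1..12) of each day-of-year (1..365)
_DOY_MONTH = np.repeat(np.arange(1, 13), MONTH_DAYS)


def month_of_doy(doy: np.ndarray) -> np.ndarray:
    """Calendar month (1-12) for day-of-year values on the no-leap calendar."""
    return _DOY_MONTH[np.asarray(doy) - 1]


def noleap_time_axis(year_start: int, year_end: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(years, months, doy) arrays for every day of [year_start, year_end]."""
    n_years = year_end - year_start + 1
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)
    years = np.repeat(np.arange(year_start, year_end + 1), DAYS_PER_YEAR)
    return years, month_of_doy(doy), doy


@dataclass
class TemperatureCube:
    """Daily Tmax (°C) for one model run and scenario.

    ``tasmax`` has shape (n_days, n_cells) with cells in the grid's
    row-major order; the time axis is strictly increasing by construction
    (consecutive no-leap days).
    """

    tasmax: np.ndarray
    years: np.ndarray
    months: np.ndarray
    doy: np.ndarray
    grid: GridSpec
    scenario: str = ""
    model: str = ""

    def __post_init__(self) -> None:
        self.tasmax = np.asarray(self.tasmax, dtype=float)
        if self.tasmax.ndim != 2:
            raise ValueError("tasmax must be 2-D (time, cell)")
        n_t, n_c = self.tasmax.shape
        if n_c != self.grid.n_cells:
            raise ValueError(f"cube has {n_c} cells, grid defines {self.grid.n_cells}")
        if not (len(self.years) == len(self.months) == len(self.doy) == n_t):
            raise ValueError("time coordinates must match the time dimension")
        if not np.all(np.isfinite(self.tasmax)):
            raise ValueError("tasmax contains non-finite values")
        serial = self.years.astype(np.int64) * DAYS_PER_YEAR + self.doy
        if np.any(np.diff(serial) <= 0):
            raise ValueError("time axis must be strictly increasing")

    @property
    def n_days(self) -> int:
        return self.tasmax.shape[0]

    @property
    def n_cells(self) -> int:
        return self.tasmax.shape[1]

    def year_range(self) -> tuple[int, int]:
        return int(self.years[0]), int(self.years[-1])

    def subset_years(self, year_start: int, year_end: int) -> "TemperatureCube":
        m = (self.years >= year_start) & (self.years <= year_end)
        if not m.any():
            raise ValueError(f"cube has no days in {year_start}-{year_end}")
        return TemperatureCube(
            self.tasmax[m], self.years[m], self.months[m], self.doy[m],
            self.grid, self.scenario, self.model,
        )

    def to_xarray(self) -> xr.Dataset:
        """CF-style Dataset: tasmax(time, lat, lon), noleap calendar.

        Time is stored as integer day offsets with year/month/doy auxiliary
        coordinates rather than encoded date objects, so the file reads
        back identically with any NetCDF backend.
        """
        g = self.grid
        cube3 = self.tasmax.reshape(self.n_days, g.nlat, g.nlon)
        ds = xr.Dataset(
            {"tasmax": (("time", "lat", "lon"), cube3)},
            coords={
                "time": ("time", np.arange(self.n_days)),
                "lat": ("lat", g.lats),
                "lon": ("lon", g.lons),
                "year": ("time", self.years.astype(np.int32)),
                "month": ("time", self.months.astype(np.int32)),
                "doy": ("time", self.doy.astype(np.int32)),
            },
        )
        ds["tasmax"].attrs.update(units="degC", long_name="daily maximum temperature")
        ds["time"].attrs.update(
            units=f"days since {int(self.years[0])}-01-01", calendar="noleap"
        )
        ds.attrs.update(scenario=self.scenario, model=self.model,
                        grid=f"{g.nlat}x{g.nlon}@{g.spacing}deg",
                        n_zones=g.n_zones, lat0=g.lat0, lon0=g.lon0)
        return ds

    @classmethod
    def from_xarray(cls, ds: xr.Dataset) -> "TemperatureCube":
        da = ds["tasmax"]
        nlat, nlon = da.sizes["lat"], da.sizes["lon"]
        spacing = float(ds["lat"][1] - ds["lat"][0]) if nlat > 1 else (
            float(ds["lon"][1] - ds["lon"][0]) if nlon > 1 else 0.5
        )
        grid = GridSpec(
            nlat=nlat, nlon=nlon,
            lat0=float(ds["lat"][0]), lon0=float(ds["lon"][0]),
            spacing=spacing, n_zones=int(ds.attrs.get("n_zones", 2)),
        )
        return cls(
            tasmax=da.values.reshape(da.sizes["time"], -1),
            years=ds["year"].values.astype(int),
            months=ds["month"].values.astype(int),
            doy=ds["doy"].values.astype(int),
            grid=grid,
            scenario=str(ds.attrs.get("scenario", "")),
            model=str(ds.attrs.get("model", "")),
        )
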