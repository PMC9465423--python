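"""Regular lat/lon analysis grid and its climate-zone / province assignment.

The analysis runs on a small regular grid of half-degree cells. Cells are
identified by integer ids in row-major order (latitude-major), and are
assigned to synthetic climate zones by latitude band — colder zones to the
north, warmer to the south — mirroring the way national heat-health studies
stratify a country into climatic divisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ZONE_SCHEMA = ["cell_id", "zone", "province"]


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid with latitude-band climate zones.

    Parameters
    ----------
    nlat, nlon : int
        Grid dimensions. Cells are numbered row-major from the southernmost
        latitude row.
    lat0, lon0 : float
        Coordinates of the first (south-west) cell centre, degrees.
    spacing : float
        Cell spacing in degrees (default half-degree, the resolution at
        which gridded climate-health projections are usually run).
    n_zones : int
        Number of latitude-band climate zones; the realistic range is
        2-7, and 1 is allowed for minimal single-cell fixtures.
    """

    nlat: int = 10
    nlon: int = 10
    lat0: float = 25.0
    lon0: float = 105.0
    spacing: float = 0.5
    n_zones: int = 4

    def __post_init__(self) -> None:
        if self.nlat < 1 or self.nlon < 1:
            raise ValueError("grid must have at least one cell")
        if not 1 <= self.n_zones <= 7:
            raise ValueError("n_zones must be between 1 and 7")
        if self.n_zones > self.nlat:
            raise ValueError("cannot have more zones than latitude rows")

    @property
    def n_cells(self) -> int:
        return self.nlat * self.nlon

    @property
    def lats(self) -> np.ndarray:
        return self.lat0 + self.spacing * np.arange(self.nlat)

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.spacing * np.arange(self.nlon)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def cell_lat(self) -> np.ndarray:
        """Latitude of every cell, row-major order."""
        return np.repeat(self.lats, self.nlon)

    def cell_zone(self) -> np.ndarray:
        """Zone label per cell: contiguous latitude bands Z1 (south) .. Zk (north)."""
        row = np.arange(self.nlat) * self.n_zones // self.nlat
        return np.array([f"Z{z + 1}" for z in np.repeat(row, self.nlon)])

    def zone_table(self) -> pd.DataFrame:
        """Cell → zone / province assignment.

        Provinces are a finer synthetic admin layer: one per latitude row,
        so several provinces share a climate zone, as in real divisions.
        """
        prov = np.repeat([f"P{r + 1:02d}" for r in range(self.nlat)], self.nlon)
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "zone": self.cell_zone(), "province": prov}
        )

    def zones(self) -> list[str]:
        return [f"Z{z + 1}" for z in range(self.n_zones)]
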