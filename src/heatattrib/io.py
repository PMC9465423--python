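"""File I/O: CF-style NetCDF temperature cubes and the CSV table schemas.

CSV outputs carry provenance — the configuration hash and the seeds used —
as ``#``-prefixed comment lines above the header, which pandas skips
transparently on read. NetCDF goes through xarray's scipy backend
(NETCDF3 classic), the lowest-common-denominator format every stack reads.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import xarray as xr
import yaml

from .cube import TemperatureCube


class SchemaError(ValueError):
    """A table does not match its expected schema."""


def config_hash(cfg: dict) -> str:
    """Short stable digest of a configuration mapping."""
    canon = yaml.safe_dump(cfg, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_cube(cube: TemperatureCube, path: str | Path) -> None:
    cube.to_xarray().to_netcdf(path, engine="scipy")


def read_cube(path: str | Path) -> TemperatureCube:
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        return TemperatureCube.from_xarray(ds.load())


def write_table(df: pd.DataFrame, path: str | Path,
                provenance: dict | None = None) -> None:
    """Write a CSV with optional '#'-comment provenance header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path, required: list[str] | None = None,
               no_missing: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, validating its schema.

    ``required`` columns must exist (a missing one raises SchemaError
    naming it); ``no_missing`` columns must additionally contain no NaN
    (the first offending row is named).
    """
    df = pd.read_csv(path, comment="#")
    for col in required or []:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in no_missing or []:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise SchemaError(f"{path}: missing value in column {col!r} at row {row}")
    return df


def read_provenance(path: str | Path) -> dict[str, str]:
    """Recover the '#'-comment provenance header of a CSV."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
    return meta
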