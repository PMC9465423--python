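"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (O(n²) scans,
sort-and-interpolate percentiles, hand-rolled inverse-variance pooling)
kept independent of the package's code paths so they can arbitrate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from heatattrib.cube import MONTH_DAYS, TemperatureCube, noleap_time_axis
from heatattrib.grid import GridSpec


# --------------------------------------------------------------------------
# cube builders
# --------------------------------------------------------------------------

def single_cell_grid() -> GridSpec:
    return GridSpec(nlat=1, nlon=1, n_zones=1)


def make_cube(values, year_start: int = 2000, grid: GridSpec | None = None,
              start_doy: int = 1) -> TemperatureCube:
    """Cube from a (time, cell) or (time,) array starting at a given day-of-year.

    The series must stay within one calendar year unless it starts on
    day 1; multi-year series start on January 1 of ``year_start``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n_t = values.shape[0]
    if grid is None:
        grid = single_cell_grid() if values.shape[1] == 1 else GridSpec(
            nlat=values.shape[1], nlon=1, n_zones=1)
    years_full, months_full, doy_full = noleap_time_axis(
        year_start, year_start + (start_doy - 1 + n_t - 1) // 365)
    i0 = start_doy - 1
    sel = slice(i0, i0 + n_t)
    return TemperatureCube(values, years_full[sel], months_full[sel],
                           doy_full[sel], grid)


def summer_doy_start(month: int = 6, day: int = 1) -> int:
    """Day-of-year of a given month/day on the no-leap calendar."""
    return int(MONTH_DAYS[: month - 1].sum()) + day


@pytest.fixture
def one_cell_grid() -> GridSpec:
    return single_cell_grid()


# --------------------------------------------------------------------------
# a shared small end-to-end pipeline run (session-scoped: runs once)
# --------------------------------------------------------------------------

SMALL_PIPELINE_KW = dict(nlat=4, nlon=4, n_zones=2, n_models=2,
                         sites_per_zone=2, mc_samples=100,
                         uncertainty_param_draws=40, seed=20240901)


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """One complete pipeline run on a reduced grid, shared across tests."""
    from heatattrib.pipeline import PipelineConfig, run_pipeline

    cfg = PipelineConfig(**SMALL_PIPELINE_KW)
    outdir = tmp_path_factory.mktemp("pipeline_out")
    results = run_pipeline(cfg, outdir)
    return cfg, outdir, results


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def percentile_oracle(values: np.ndarray, q: float) -> float:
    """Sorted-array percentile with linear interpolation between order stats."""
    s = np.sort(np.asarray(values, dtype=float))
    pos = q / 100.0 * (len(s) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(s[lo] * (1 - frac) + s[hi] * frac)


def brute_force_hw_days(temps: np.ndarray, thr: float, months: np.ndarray,
                        min_run: int, season=(5, 9)) -> np.ndarray:
    """O(n²) heatwave-day indicator: a day counts iff it sits inside some
    window of >= min_run consecutive candidate days (hot AND in season)."""
    temps = np.asarray(temps, dtype=float)
    cand = (temps > thr) & (months >= season[0]) & (months <= season[1])
    n = len(temps)
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        if not cand[i]:
            continue
        left = i
        while left > 0 and cand[left - 1]:
            left -= 1
        right = i
        while right < n - 1 and cand[right + 1]:
            right += 1
        if right - left + 1 >= min_run:
            out[i] = True
    return out


def fixed_effects_oracle(betas, ses) -> tuple[float, float]:
    """Inverse-variance pooled mean and its SE, computed longhand."""
    w = [1.0 / s**2 for s in ses]
    beta = sum(wi * bi for wi, bi in zip(w, betas)) / sum(w)
    return beta, (1.0 / sum(w)) ** 0.5


def dl_oracle(betas, ses) -> tuple[float, float, float]:
    """DerSimonian-Laird pooled mean, SE, and tau² by the moment formula."""
    betas = np.asarray(betas, float)
    w = 1.0 / np.asarray(ses, float) ** 2
    k = len(betas)
    bf = np.sum(w * betas) / np.sum(w)
    Q = np.sum(w * (betas - bf) ** 2)
    tau2 = max(0.0, (Q - (k - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
    wr = 1.0 / (np.asarray(ses, float) ** 2 + tau2)
    return (float(np.sum(wr * betas) / np.sum(wr)),
            float(np.sqrt(1.0 / np.sum(wr))), float(tau2))
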