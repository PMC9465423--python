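"""Monte-Carlo propagation of coefficient uncertainty and source attribution.

Coefficient uncertainty is propagated by sampling the log relative risk of
each climate zone from Normal(β̂, SE) — coefficients, not risks, are the
normally distributed quantity — evaluating the attributable-death total
for every draw and every climate-model ensemble member, and reading
empirical confidence bounds off the pooled draws × members distribution.
The point estimate is the burden at β̂ averaged over ensemble members.

The relative weight of the uncertainty sources (coefficient noise,
climate-model spread, population scenario) is measured by a Shapley-style
variance decomposition: the variance of the decade-average burden when a
subset of sources varies (the rest pinned at central values) defines a set
function whose permutation-averaged marginal increases allocate the total
variance among the sources, order-independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .attribution import decade_average
from .demography import DemographyTable
from .exposure import RREstimate
from .heatwave import HeatwaveCalendar


@dataclass(frozen=True)
class MonteCarloConfig:
    n_samples: int = 1000
    seed: int = 0
    percentiles: tuple[float, float] = (2.5, 97.5)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 Monte-Carlo samples")
        if not self.percentiles[0] < self.percentiles[1]:
            raise ValueError("percentiles must be ordered")


@dataclass
class MCResult:
    """Point estimate, empirical CI, and the raw sample matrix."""

    point: float
    ci_low: float
    ci_high: float
    samples: np.ndarray            # (n_samples, n_models)
    per_model_point: dict[str, float]


def zone_base_burden(dem: DemographyTable, cal: HeatwaveCalendar,
                     zone_map: pd.DataFrame,
                     window: tuple[int, int]) -> pd.Series:
    """Decade-average national AN per zone at AF = 1.

    AN is linear in AF with a zone-constant AF, so the burden for any draw
    of zone coefficients is Σ_z base_z · AF(exp(β_z)); precomputing base_z
    makes thousand-draw Monte Carlo loops cheap.
    """
    from .attribution import attributable_deaths  # local to avoid cycle noise

    af_one = pd.Series(1.0, index=pd.Index(zone_map["cell_id"], name="cell_id"))
    res = attributable_deaths(dem, cal.subset_years(*window), af_one)
    per_cell = decade_average(res, window)["per_cell"]
    merged = per_cell.merge(zone_map[["cell_id", "zone"]], on="cell_id")
    return merged.groupby("zone")["an"].sum()


def _burden_at(beta: Mapping[str, float], base: pd.Series) -> float:
    rr = np.exp(np.array([beta[z] for z in base.index]))
    af = np.maximum((rr - 1.0) / rr, 0.0)   # protective RRs floored, as in AF
    return float(np.sum(base.to_numpy() * af))


def draw_betas(cfg: MonteCarloConfig,
               rr_estimates: Mapping[str, RREstimate]) -> dict[str, np.ndarray]:
    """n_samples normal draws of the log-RR per zone, seeded from cfg."""
    rng = np.random.default_rng(cfg.seed)
    draws = {}
    for zone in sorted(rr_estimates):
        e = rr_estimates[zone]
        if e.se < 0 or not np.isfinite(e.se):
            raise ValueError(f"invalid SE for zone {zone!r}")
        draws[zone] = rng.normal(e.beta, e.se, size=cfg.n_samples)
    return draws


def mc_attributable(cfg: MonteCarloConfig,
                    rr_estimates: Mapping[str, RREstimate],
                    calendars: Mapping[str, HeatwaveCalendar],
                    dem: DemographyTable,
                    zone_map: pd.DataFrame,
                    window: tuple[int, int]) -> MCResult:
    """Empirical distribution of the decade-average national burden.

    ``calendars`` maps ensemble-member name → heatwave calendar. One set
    of coefficient draws is shared across members; the CI percentiles are
    taken over the pooled (draws × members) values.
    """
    if not calendars:
        raise ValueError("need at least one climate-model calendar")
    bases = {m: zone_base_burden(dem, cal, zone_map, window)
             for m, cal in calendars.items()}
    betas = draw_betas(cfg, rr_estimates)
    beta_hat = {z: e.beta for z, e in rr_estimates.items()}

    models = sorted(bases)
    samples = np.empty((cfg.n_samples, len(models)))
    for j, m in enumerate(models):
        base = bases[m]
        for i in range(cfg.n_samples):
            samples[i, j] = _burden_at({z: betas[z][i] for z in betas}, base)

    per_model_point = {m: _burden_at(beta_hat, bases[m]) for m in models}
    point = float(np.mean(list(per_model_point.values())))
    lo, hi = np.percentile(samples.ravel(), cfg.percentiles)
    return MCResult(point, float(lo), float(hi), samples, per_model_point)


@dataclass
class UncertaintyShares:
    """Percentage of total variability attributed to each source."""

    shares: pd.Series                  # % per source, sums to 100
    shapley_variance: dict[str, float]
    total_variance: float


def decompose_uncertainty(evaluate: Callable[[Mapping[str, object]], float],
                          levels: Mapping[str, Sequence],
                          central: Mapping[str, object] | None = None) -> UncertaintyShares:
    """Allocate output variance among uncertainty sources.

    ``levels[source]`` lists the settings that source can take (coefficient
    draws, ensemble members, population scenarios, ...); ``evaluate`` maps
    a full assignment {source: setting} to the scalar burden. For every
    subset S of sources, the variance of the burden over the product of
    S's levels (others at their central setting) is computed; each source's
    share is its Shapley value of that variance set function, i.e. the
    marginal variance it adds, averaged over all orders of introduction.
    Negative marginal terms (possible with interactions) are clipped at
    zero before normalising the shares to 100%.
    """
    sources = list(levels)
    if all(len(levels[s]) < 2 for s in sources):
        raise ValueError("at least one source needs two or more levels")
    if central is None:
        central = {s: levels[s][0] for s in sources}

    var_cache: dict[frozenset, float] = {}

    def variance(subset: frozenset) -> float:
        if subset not in var_cache:
            if not subset:
                var_cache[subset] = 0.0
            else:
                active = [s for s in sources if s in subset]
                vals = []
                for combo in product(*(levels[s] for s in active)):
                    assignment = dict(central)
                    assignment.update(dict(zip(active, combo)))
                    vals.append(float(evaluate(assignment)))
                var_cache[subset] = float(np.var(vals))
        return var_cache[subset]

    shapley = {s: 0.0 for s in sources}
    orders = list(permutations(sources))
    for order in orders:
        acc: frozenset = frozenset()
        prev = 0.0
        for s in order:
            acc = acc | {s}
            cur = variance(acc)
            shapley[s] += cur - prev
            prev = cur
    shapley = {s: v / len(orders) for s, v in shapley.items()}

    clipped = {s: max(0.0, v) for s, v in shapley.items()}
    total = sum(clipped.values())
    if total == 0:
        raise ValueError("no variability in any source")
    shares = pd.Series({s: clipped[s] / total * 100.0 for s in sources})
    return UncertaintyShares(shares, shapley, variance(frozenset(sources)))
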