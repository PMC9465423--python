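"""Heatwave-mortality relative risks: Poisson regression and meta-analytic pooling.

The exposure-response stage estimates, per location, the log relative risk
(β) of death on heatwave vs non-heatwave days from a Poisson generalized
linear model

    log E[deaths_t] = α + β·HW_t + Σ_j γ_j x_{jt},

with caller-supplied confounder columns x (air-quality, humidity, seasonal
terms, day-of-week, ...). Location estimates are then pooled to climate-zone
level by inverse-variance meta-analysis: Cochran's Q and I² decide between
fixed effects and DerSimonian-Laird random effects — random effects when
the Q test is significant (p < alpha_q) AND I² ≥ 50%, otherwise fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

RR_SCHEMA = ["level", "unit", "beta", "se", "rr", "n_sites", "Q", "I2", "model_used", "tau2"]

I2_RANDOM_CUTOFF = 50.0


@dataclass(frozen=True)
class RREstimate:
    """A log-relative-risk estimate with its standard error and, for pooled
    estimates, the heterogeneity diagnostics."""

    beta: float
    se: float
    level: str = "location"          # location | zone | pooled
    unit: str = ""
    n_sites: int = 1
    Q: float = float("nan")
    I2: float = float("nan")
    model_used: str = ""             # "" | fixed | random
    tau2: float = 0.0

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be nonnegative")
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")

    @property
    def rr(self) -> float:
        return math.exp(self.beta)


def fit_poisson_rr(deaths: np.ndarray, hw: np.ndarray,
                   covariates: pd.DataFrame | None = None,
                   unit: str = "") -> RREstimate:
    """Maximum-likelihood Poisson fit of the heatwave coefficient.

    ``deaths`` and ``hw`` are aligned daily series; ``covariates`` adds
    confounder columns. Raises if the heatwave indicator is constant
    (the coefficient is then unidentifiable) or the fit fails to converge.
    """
    deaths = np.asarray(deaths, dtype=float)
    hw = np.asarray(hw, dtype=float)
    if deaths.shape != hw.shape:
        raise ValueError("deaths and hw series differ in length")
    if covariates is not None and len(covariates) != len(deaths):
        raise ValueError("covariates differ in length from the daily series")
    if hw.min() == hw.max():
        raise ValueError("heatwave indicator is constant: need both heatwave "
                         "and non-heatwave days to identify the relative risk")
    X = pd.DataFrame({"hw": hw})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X, prepend=True)
    model = sm.GLM(deaths, X, family=sm.families.Poisson())
    res = model.fit(tol=1e-8)
    if not res.converged:
        raise RuntimeError("Poisson IRLS did not converge")
    return RREstimate(beta=float(res.params["hw"]), se=float(res.bse["hw"]),
                      level="location", unit=unit)


def pool_zone(estimates: list[RREstimate], alpha_q: float = 0.05,
              unit: str = "") -> RREstimate:
    """Pool location estimates to one zone estimate.

    Computes Cochran's Q against the fixed-effects mean, its p-value on
    k−1 df, and I² = max(0, (Q−(k−1))/Q)·100. Significant heterogeneity
    (p < alpha_q and I² ≥ 50%) selects DerSimonian-Laird random effects
    with the moment estimator of the between-site variance τ²; otherwise
    inverse-variance fixed effects. A single estimate passes through.
    """
    if not estimates:
        raise ValueError("no estimates to pool")
    if len(estimates) == 1:
        e = estimates[0]
        return RREstimate(e.beta, e.se, level="zone", unit=unit or e.unit,
                          n_sites=1, Q=0.0, I2=0.0, model_used="fixed", tau2=0.0)

    beta = np.array([e.beta for e in estimates])
    se = np.array([e.se for e in estimates])
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("pooling requires finite positive standard errors")
    w = 1.0 / se**2
    k = len(beta)
    beta_f = float(np.sum(w * beta) / np.sum(w))
    se_f = float(np.sqrt(1.0 / np.sum(w)))

    Q = float(np.sum(w * (beta - beta_f) ** 2))
    p_q = float(stats.chi2.sf(Q, k - 1))
    I2 = float(max(0.0, (Q - (k - 1)) / Q) * 100.0) if Q > 0 else 0.0

    if p_q < alpha_q and I2 >= I2_RANDOM_CUTOFF:
        tau2 = max(0.0, (Q - (k - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
        w_r = 1.0 / (se**2 + tau2)
        beta_r = float(np.sum(w_r * beta) / np.sum(w_r))
        se_r = float(np.sqrt(1.0 / np.sum(w_r)))
        return RREstimate(beta_r, se_r, level="zone", unit=unit, n_sites=k,
                          Q=Q, I2=I2, model_used="random", tau2=float(tau2))
    return RREstimate(beta_f, se_f, level="zone", unit=unit, n_sites=k,
                      Q=Q, I2=I2, model_used="fixed", tau2=0.0)


def map_rr_to_grid(zone_rrs: dict[str, RREstimate],
                   zone_map: pd.DataFrame) -> pd.DataFrame:
    """Carry each zone's pooled estimate onto its grid cells.

    ``zone_map`` needs columns (cell_id, zone). Returns one row per cell:
    (cell_id, zone, beta, se, rr). Raises if any cell's zone has no estimate.
    """
    for col in ("cell_id", "zone"):
        if col not in zone_map.columns:
            raise ValueError(f"zone map missing column {col!r}")
    missing = sorted(set(zone_map["zone"]) - set(zone_rrs))
    if missing:
        raise KeyError(f"no RR estimate for zone(s) {missing}")
    out = zone_map[["cell_id", "zone"]].copy()
    out["beta"] = out["zone"].map(lambda z: zone_rrs[z].beta)
    out["se"] = out["zone"].map(lambda z: zone_rrs[z].se)
    out["rr"] = np.exp(out["beta"])
    return out


def estimates_to_frame(estimates: list[RREstimate]) -> pd.DataFrame:
    """Flatten estimates to the output CSV schema."""
    return pd.DataFrame([
        {"level": e.level, "unit": e.unit, "beta": e.beta, "se": e.se,
         "rr": e.rr, "n_sites": e.n_sites, "Q": e.Q, "I2": e.I2,
         "model_used": e.model_used, "tau2": e.tau2}
        for e in estimates
    ])
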