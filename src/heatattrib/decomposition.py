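"""Driver decomposition of the change in attributable deaths.

The change in burden between two periods is attributed to its drivers —
climate (the heatwave calendar), population size, and aging (the
age-structure shares) — by sequential factor substitution: walk from the
period-1 state to the period-2 state switching one factor at a time; the
AN difference at a factor's switch step is its contribution under that
ordering. Because a single ordering is arbitrary, contributions are
averaged over all orderings of the factors, which is exactly the Shapley
value of the cooperative game AN(state). The telescoping sum guarantees
the averaged contributions add up to the total change exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Callable, Mapping

import numpy as np
import pandas as pd

FACTORS = ("climate", "size", "aging")


@dataclass
class FactorState:
    """One period's factor settings.

    climate — the heatwave calendar of the period; size — total population
    (scalar multiplier or per-cell totals); aging — the age-structure
    shares (with their age-specific mortality rates riding along). The
    three are independently switchable: the AN evaluator must accept any
    mixed combination.
    """

    climate: object
    size: object
    aging: object

    def as_dict(self) -> dict[str, object]:
        return {"climate": self.climate, "size": self.size, "aging": self.aging}


@dataclass
class ContributionResult:
    """Per-factor contributions (deaths) to the total change."""

    contributions: dict[str, float]
    total_change: float
    an_start: float
    an_end: float
    n_orderings: int

    def shares(self) -> "pd.Series":
        return contribution_shares(self)


def decompose_change(state_1, state_2,
                     an_evaluator: Callable[..., float],
                     factors: tuple[str, ...] = FACTORS) -> ContributionResult:
    """Average the sequential-substitution contributions over all orderings.

    ``state_1`` and ``state_2`` are FactorStates or mappings factor→value;
    ``an_evaluator(**settings)`` returns the (scalar) attributable-death
    total under a possibly mixed assignment of factor settings.
    """
    s1 = state_1.as_dict() if isinstance(state_1, FactorState) else dict(state_1)
    s2 = state_2.as_dict() if isinstance(state_2, FactorState) else dict(state_2)
    if set(s1) != set(factors) or set(s2) != set(factors):
        raise ValueError(f"states must define exactly the factors {factors}")

    cache: dict[frozenset, float] = {}

    def evaluate(switched: frozenset) -> float:
        if switched not in cache:
            settings = {f: (s2[f] if f in switched else s1[f]) for f in factors}
            cache[switched] = float(an_evaluator(**settings))
        return cache[switched]

    totals = {f: 0.0 for f in factors}
    orderings = list(permutations(factors))
    for order in orderings:
        switched: frozenset = frozenset()
        prev = evaluate(switched)
        for f in order:
            switched = switched | {f}
            cur = evaluate(switched)
            totals[f] += cur - prev
            prev = cur
    n = len(orderings)
    contributions = {f: totals[f] / n for f in factors}
    an_start = evaluate(frozenset())
    an_end = evaluate(frozenset(factors))
    return ContributionResult(contributions, an_end - an_start,
                              an_start, an_end, n)


def contribution_shares(res: ContributionResult) -> pd.Series:
    """Factor contributions as percentages.

    When every contribution has the sign of the total change, shares are
    contribution / total × 100 and sum to 100. With mixed signs that ratio
    is not a composition, so each positive contribution is instead
    reported as a percentage of the sum of positive contributions
    (negative factors get negative percentages on the same denominator)
    and the result is flagged via the ``mixed_sign`` attribute.
    """
    if res.total_change == 0:
        raise ValueError("total change is zero; shares undefined")
    vals = pd.Series(res.contributions, dtype=float)
    same_sign = np.all(np.sign(vals[vals != 0]) == np.sign(res.total_change))
    if same_sign:
        shares = vals / res.total_change * 100.0
        shares.attrs["mixed_sign"] = False
    else:
        pos_sum = vals[vals > 0].sum()
        if pos_sum == 0:
            raise ValueError("no positive contributions to normalise against")
        shares = vals / pos_sum * 100.0
        shares.attrs["mixed_sign"] = True
    return shares
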