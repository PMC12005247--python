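"""The multiple-mutations traveling-wave regime: lead, minimum reproductive
excess, and proportion of deaths that are selective.

In an asexual population of size ``N`` with beneficial mutation rate ``U``
(per genome per generation) and effect ``s`` per mutation, several beneficial
mutations segregate concurrently and the fitness distribution forms a
traveling wave. Its "nose" -- the best genotype present -- leads the mean by
``q s`` (with mean relative fitness normalized to 1). Two consequences follow
directly from the lead:

* the minimum reproductive excess the best genotype needs in order for the
  wave (and a constant population size) to be sustained is ``q s``;
* the proportion of deaths that are selective is ``1 - 1/(1 + q s)``.

The lead factor ``q`` solves a transcendental self-consistency condition for
the steady-state wave. The class that will eventually dominate the
population is established at the nose with ~``1/(q s)`` individuals and must
grow to ~``N`` over the ``q`` establishment intervals (each of length
``ln(s/U) / ((q-1) s)``) during which its advantage over the mean decays
linearly from ``q s`` to 0, giving::

    q^2 / (2 (q - 1)) * ln(s/U) = ln(N s q)

whose solution approaches the familiar asymptotic ``q ~ 2 ln(N s)/ln(s/U)``
when ``ln(N s)`` is large. The solver brackets the root around that
asymptotic initializer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DomainError, NumericalError

__all__ = [
    "TravelingWaveParams",
    "TravelingWaveSolution",
    "RegimeWarning",
    "asymptotic_lead_factor",
    "lead_equation",
    "solve_lead",
    "proportion_selective",
    "sweep_rate",
    "parameter_grid",
]


class RegimeWarning(UserWarning):
    """Parameters are close to the edge of the multiple-mutations regime."""


@dataclass(frozen=True)
class TravelingWaveParams:
    """Population size N, beneficial mutation rate U, effect size s.

    Valid in the multiple-mutations regime: N >= 2, 0 < U < s < 1. When
    s/U < 3 the model's assumptions start to break down; a
    :class:`RegimeWarning` is emitted but the solve proceeds.
    """

    N: float
    U: float
    s: float

    def __post_init__(self) -> None:
        if self.N < 2:
            raise DomainError(f"population size must be >= 2, got {self.N}")
        if not (0.0 < self.s < 1.0):
            raise DomainError(f"selection coefficient must be in (0, 1), got {self.s}")
        if not (0.0 < self.U < self.s):
            raise DomainError(
                f"beneficial mutation rate must satisfy 0 < U < s, got "
                f"U={self.U}, s={self.s}"
            )
        if self.s / self.U < 3.0:
            warnings.warn(
                f"s/U = {self.s / self.U:.2f} < 3: close to the boundary of "
                "the multiple-mutations regime; results may be unreliable",
                RegimeWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class TravelingWaveSolution:
    """Solved lead and its demographic consequences."""

    params: TravelingWaveParams
    q: float

    @property
    def lead(self) -> float:
        """Fitness advantage q s of the wave's nose over the mean."""
        return self.q * self.params.s

    @property
    def min_reproductive_excess(self) -> float:
        """Minimum reproductive excess of the best genotype, equal to the lead."""
        return self.lead

    @property
    def prop_selective(self) -> float:
        """Proportion of deaths that are selective, 1 - 1/(1 + q s)."""
        return proportion_selective(self.q, self.params.s)

    @property
    def sweep_rate(self) -> float:
        """Substitutions per generation, 2 s ln(Ns) / ln^2(s/U)."""
        return sweep_rate(self.params)


def asymptotic_lead_factor(N: float, U: float, s: float) -> float:
    """Leading-order lead factor 2 ln(N s) / ln(s / U)."""
    return 2.0 * math.log(N * s) / math.log(s / U)


def lead_equation(q: float, N: float, U: float, s: float) -> float:
    """Residual of the steady-state lead condition (zero at the solution)."""
    if q <= 1.0:
        raise DomainError(f"lead factor q must exceed 1, got {q}")
    return q * q / (2.0 * (q - 1.0)) * math.log(s / U) - math.log(N * s * q)


def solve_lead(params: TravelingWaveParams, rtol: float = 1e-10) -> TravelingWaveSolution:
    """Solve the lead self-consistency condition for q.

    Expands a bracket around the asymptotic initializer
    ``2 ln(Ns)/ln(s/U)`` and root-finds with Brent's method to relative
    tolerance ``rtol``. Raises a :class:`NumericalError` with a parameter
    recommendation if no root exists in the admissible region q > 1.
    """
    N, U, s = params.N, params.U, params.s
    if N * s <= 1.0:
        raise DomainError(
            f"N*s = {N * s:.3g} <= 1: outside the multiple-mutations regime; "
            "increase N or s"
        )
    q0 = asymptotic_lead_factor(N, U, s)
    lo = max(1.0 + 1e-9, q0 / 2.0)
    hi = max(2.0 * q0, lo * 2.0)
    f = lambda q: lead_equation(q, N, U, s)  # noqa: E731
    for _ in range(80):
        if f(lo) * f(hi) < 0:
            break
        if f(lo) > 0:  # root below the bracket
            lo = 1.0 + (lo - 1.0) / 2.0
        else:
            hi *= 2.0
    else:
        raise NumericalError(
            f"no lead root found for N={N}, U={U}, s={s}; parameters are "
            "likely outside the multiple-mutations regime -- try larger N "
            "or s/U"
        )
    q = brentq(f, lo, hi, rtol=rtol)
    return TravelingWaveSolution(params=params, q=float(q))


def proportion_selective(q: float, s: float) -> float:
    """Proportion of deaths that are selective: 1 - 1/(1 + q s)."""
    if q < 0 or s < 0:
        raise DomainError("q and s must be non-negative")
    return 1.0 - 1.0 / (1.0 + q * s)


def sweep_rate(params: TravelingWaveParams) -> float:
    """Rate of beneficial sweeps in asexuals: 2 s ln(Ns) / ln^2(s/U)."""
    N, U, s = params.N, params.U, params.s
    if s / U <= 1.0:
        raise DomainError(f"s/U must exceed 1, got {s / U}")
    if N * s < 1.0:
        raise DomainError(f"N*s must be >= 1, got {N * s}")
    return 2.0 * s * math.log(N * s) / math.log(s / U) ** 2


def parameter_grid(
    vary: str,
    low: float,
    high: float,
    num: int = 25,
    N: float = 1e6,
    U: float = 1e-3,
    s: float = 1e-2,
) -> pd.DataFrame:
    """Solve the wave over a geometric grid of one parameter.

    ``vary`` is one of "N", "U", "s"; the other two stay at their defaults.
    Grid endpoints are clipped so that s/U >= 3 everywhere. Returns a tidy
    DataFrame with columns (parameter value, q, lead, min_RE,
    prop_selective, sweep_rate).
    """
    if vary not in ("N", "U", "s"):
        raise DomainError(f"vary must be one of 'N', 'U', 's', got {vary!r}")
    if not (0 < low < high):
        raise DomainError("need 0 < low < high for a geometric grid")
    if vary == "U":
        high = min(high, s / 3.0)
    elif vary == "s":
        low = max(low, 3.0 * U)
    values = np.geomspace(low, high, num)
    rows = []
    for v in values:
        kwargs = {"N": N, "U": U, "s": s, vary: float(v)}
        sol = solve_lead(TravelingWaveParams(**kwargs))
        rows.append(
            {
                vary: float(v),
                "q": sol.q,
                "lead": sol.lead,
                "min_RE": sol.min_reproductive_excess,
                "prop_selective": sol.prop_selective,
                "sweep_rate": sol.sweep_rate,
            }
        )
    return pd.DataFrame(rows)
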