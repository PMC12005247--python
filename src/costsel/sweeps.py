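"""Cost-of-selection accounting for selective sweeps.

During a sweep, individuals carrying the old allele suffer deaths (or forego
offspring) that individuals carrying the new allele would not have suffered.
These "selective deaths" are the currency in which selection is paid for: at
allele frequency ``p`` a haploid population of size ``N`` incurs ``s(1-p)N``
of them per generation, and the cumulative per-capita total over one complete
sweep -- the cost of selection ``D`` -- is close to ``-ln(p0)`` for a haploid
locus and ``-2 ln(p0)`` for a diploid locus with genic selection, nearly
independently of ``s``.

This module provides the per-generation and per-sweep cost calculators, the
multi-locus lag-load factor, selection intensity, and load summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import integrate

from .errors import DomainError, NumericalError

__all__ = [
    "PloidyModel",
    "SweepParams",
    "SweepSet",
    "LoadSummary",
    "IntensitySpec",
    "MultiLocusFactor",
    "instantaneous_cost",
    "cost_per_sweep",
    "multi_locus_fitness_factor",
    "selection_intensity",
    "loads",
    "fecundity_selective_deaths",
]


class PloidyModel(str, Enum):
    """Genetic model for the selected locus.

    ``HAPLOID``
        one allele copy per individual, fitnesses 1 and 1-s.
    ``DIPLOID_GENIC``
        two copies, genic (additive) selection: genotype fitnesses 1, 1-s,
        1-2s for beneficial homozygote, heterozygote, wild-type homozygote.

    Dominant/recessive/inbred diploid variants are enumerated for
    completeness but not implemented.
    """

    HAPLOID = "haploid"
    DIPLOID_GENIC = "diploid_genic"
    DIPLOID_DOMINANT = "diploid_dominant"
    DIPLOID_RECESSIVE = "diploid_recessive"


#: allele copies per individual, which scales per-capita selective deaths
_COPIES = {PloidyModel.HAPLOID: 1, PloidyModel.DIPLOID_GENIC: 2}


@dataclass(frozen=True)
class SweepParams:
    """Parameters of a single selective sweep.

    Parameters
    ----------
    p0
        Initial frequency of the beneficial allele, 0 < p0 < 1.
    s
        Selection coefficient, 0 < s < 1.
    model
        Genetic model, see :class:`PloidyModel`.
    N
        Census size at the selected life-history stage (>= 1). Only used to
        convert per-capita costs into absolute numbers of deaths.
    """

    p0: float
    s: float
    model: PloidyModel = PloidyModel.HAPLOID
    N: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < 1.0):
            raise DomainError(f"initial frequency p0 must be in (0, 1), got {self.p0}")
        if not (0.0 < self.s < 1.0):
            raise DomainError(f"selection coefficient s must be in (0, 1), got {self.s}")
        if self.N < 1:
            raise DomainError(f"population size N must be >= 1, got {self.N}")
        object.__setattr__(self, "model", PloidyModel(self.model))


@dataclass(frozen=True)
class SweepSet:
    """A collection of concurrently segregating sweeps.

    Each locus is a ``(p, s)`` pair of current frequency and selection
    coefficient; the per-locus fitness deficit is ``d = s (1 - p)``.
    """

    loci: tuple[tuple[float, float], ...]

    def __init__(self, loci: Iterable[Sequence[float]]):
        loci = tuple((float(p), float(s)) for p, s in loci)
        for p, s in loci:
            if not (0.0 <= p <= 1.0):
                raise DomainError(f"allele frequency must be in [0, 1], got {p}")
            if not (0.0 < s < 1.0):
                raise DomainError(f"selection coefficient must be in (0, 1), got {s}")
        object.__setattr__(self, "loci", loci)

    @property
    def d(self) -> np.ndarray:
        """Per-locus deficits d_i = s_i (1 - p_i)."""
        return np.array([s * (1.0 - p) for p, s in self.loci])

    @property
    def x(self) -> int:
        """Number of segregating loci."""
        return len(self.loci)


@dataclass(frozen=True)
class LoadSummary:
    """Lag load and lead for a pair of reference and mean fitnesses.

    Lag load is (W_opt - W_mean)/W_opt with W_opt a possibly hypothetical
    optimum; lead is (W_opt - W_mean)/W_mean with W_opt the best genotype
    actually present.
    """

    w_opt: float
    w_mean: float

    def __post_init__(self) -> None:
        if self.w_mean <= 0 or self.w_opt <= 0:
            raise DomainError("fitnesses must be positive")
        if self.w_opt < self.w_mean:
            raise DomainError(
                f"reference fitness {self.w_opt} below mean fitness {self.w_mean}"
            )

    @property
    def lag_load(self) -> float:
        return (self.w_opt - self.w_mean) / self.w_opt

    @property
    def lead(self) -> float:
        return (self.w_opt - self.w_mean) / self.w_mean


@dataclass(frozen=True)
class IntensitySpec:
    """Selection intensity I = ln(s_o / S).

    ``s_o`` is the survival probability of the best genotype present and
    ``S`` the population mean survival; I >= 0 in nats.
    """

    s_o: float
    S: float

    def __post_init__(self) -> None:
        if not (0.0 < self.S <= 1.0) or not (0.0 < self.s_o <= 1.0):
            raise DomainError("survival probabilities must be in (0, 1]")
        if self.S > self.s_o:
            raise DomainError(
                "mean survival exceeds best-genotype survival "
                f"({self.S} > {self.s_o})"
            )

    @property
    def I(self) -> float:  # noqa: E743 - the field's standard symbol
        return math.log(self.s_o / self.S)


@dataclass(frozen=True)
class MultiLocusFactor:
    """Exact and exponential-approximate multi-locus fitness factors."""

    exact: float
    approx: float
    total_d: float


def instantaneous_cost(p: float, s: float, N: float) -> float:
    """Selective deaths per generation at allele frequency ``p``: s(1-p)N."""
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"allele frequency must be in [0, 1], got {p}")
    if not (0.0 < s < 1.0):
        raise DomainError(f"selection coefficient must be in (0, 1), got {s}")
    if N < 1:
        raise DomainError(f"population size must be >= 1, got {N}")
    return s * (1.0 - p) * N


def cost_per_sweep(
    params: SweepParams,
    p_end: float | None = None,
    rtol: float = 1e-8,
) -> float:
    """Per-capita cost of selection D for one complete sweep.

    Integrates the per-capita selective-death rate along the deterministic
    continuous-time sweep trajectory dp/dt = s p (1 - p), from ``p0`` to
    ``p_end`` (default 1 - p0, a symmetric truncation of fixation). The
    per-capita rate is s(1-p) for a haploid locus and 2 s (1-p) for the
    diploid genic model (two allele copies per individual), so D approaches
    -ln(p0) and -2 ln(p0) respectively for small s and p0.

    Returns D in units of N; multiply by the census size for absolute deaths.
    """
    model = PloidyModel(params.model)
    if model not in _COPIES:
        raise NotImplementedError(
            f"ploidy model {model.value!r} is enumerated but not implemented; "
            "use haploid or diploid_genic"
        )
    copies = _COPIES[model]
    p0, s = params.p0, params.s
    if p_end is None:
        # symmetric truncation of fixation; a sweep already past 1/2 keeps a
        # valid (possibly empty) integration range
        p_end = max(1.0 - p0, p0)
    if not (p0 <= p_end < 1.0):
        raise DomainError(f"p_end must be in [p0, 1), got {p_end}")
    if p_end == p0:
        return 0.0

    def integrand(p: float) -> float:
        # per-capita deaths per unit time divided by dp/dt, i.e. deaths per
        # unit allele-frequency advance
        return (copies * s * (1.0 - p)) / (s * p * (1.0 - p))

    value, abserr = integrate.quad(integrand, p0, p_end, epsrel=rtol, limit=200)
    if not math.isfinite(value) or abserr > max(1e-6, 10 * rtol * abs(value)):
        raise NumericalError(
            f"sweep-cost quadrature did not converge: value={value}, "
            f"abserr={abserr}, p0={p0}, p_end={p_end}, s={s}"
        )
    return value


def multi_locus_fitness_factor(sweeps: SweepSet | Iterable[Sequence[float]]) -> MultiLocusFactor:
    """Mean fitness relative to the post-sweep population, across loci.

    With independent sites the population mean fitness is lower than the
    all-swept reference by the exact product prod_i (1 - d_i), which is well
    approximated by exp(-sum_i d_i) when every d_i is small.
    """
    if not isinstance(sweeps, SweepSet):
        sweeps = SweepSet(sweeps)
    d = sweeps.d
    exact = float(np.prod(1.0 - d)) if sweeps.x else 1.0
    total = float(d.sum())
    return MultiLocusFactor(exact=exact, approx=math.exp(-total), total_d=total)


def selection_intensity(s_o: float, S: float) -> float:
    """Selection intensity I = ln(s_o / S) in nats; requires 0 < S <= s_o <= 1."""
    return IntensitySpec(s_o=s_o, S=S).I


def loads(w_opt: float, w_mean: float) -> LoadSummary:
    """Lag load and lead for reference fitness ``w_opt`` and mean ``w_mean``."""
    return LoadSummary(w_opt=w_opt, w_mean=w_mean)


def fecundity_selective_deaths(
    N_i: Sequence[float], b_i: Sequence[float]
) -> np.ndarray:
    """Selective "deaths" from differential fecundity: N_i (b_best - b_i).

    Foregone offspring are mathematically equivalent to deaths immediately
    after reproduction. ``b_best`` is the highest fecundity among genotypes
    present; the best genotype contributes zero.
    """
    N = np.asarray(N_i, dtype=float)
    b = np.asarray(b_i, dtype=float)
    if N.size == 0 or b.size == 0:
        raise DomainError("at least one genotype is required")
    if N.shape != b.shape:
        raise DomainError("counts and fecundities must have matching shapes")
    if (N < 0).any() or (b < 0).any():
        raise DomainError("counts and fecundities must be non-negative")
    return N * (b.max() - b)
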