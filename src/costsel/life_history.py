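"""Reproductive excess and selective deaths for arbitrary life cycles.

A life cycle is an ordered list of transitions, each multiplying the stage
population by a per-genotype factor ``k`` (k <= 1 for survival, k > 1
allowed for reproduction). Stage boundaries are indexed so that boundary
``j`` is the population entering transition ``j``::

    N_0 --[transition 0]--> N_1 --[transition 1]--> ... --> N_T (wraps to N_0)

For a focal transition ``j``, ``N_min,j+1`` is the smallest population at
the *end* of transition ``j`` that still lets the cycle return to ``N_j``
at the start of the same transition next cycle, holding all other
transitions at their baseline behaviour. The reproductive excess of the
focal transition is then ``RE_j = k_j N_j - N_min,j+1`` -- the budget out
of which selective deaths during transition ``j`` can be paid without the
population shrinking.

Two focal populations are supported: the *actual* population (genotype
frequencies as given) and the *best* population (every individual carries
the per-transition best genotype). The best-genotype mode always yields the
smaller ``N_min`` and is the one used for evolutionary-rescue style
questions.

Density-regulated transitions may declare ``k`` as a callable
``(stage_size, frequencies) -> multiplier``; because ``N_min`` is defined
as a counterfactual holding everything else constant, such callables are
evaluated at the baseline trajectory's stage sizes, not at perturbed ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "Transition",
    "LifeCycle",
    "BottleneckSpec",
    "CycleState",
    "WrightFisherIdentities",
    "wf_identities",
    "selective_deaths_per_transition",
]

Genotype = Hashable
KValue = float | Callable[[float, Mapping[Genotype, float]], float]

_TOL = 1e-9


@dataclass(frozen=True)
class Transition:
    """One life-history transition with per-genotype multipliers.

    Parameters
    ----------
    label
        Human-readable name ("germination", "dispersal", ...).
    kind
        ``"survival"`` (k <= 1) or ``"reproduction"`` (k > 1 allowed).
    k
        Mapping genotype -> multiplier. A multiplier may be a positive float
        or a callable ``(stage_size, frequencies) -> float`` for
        density-regulated transitions.
    """

    label: str
    kind: str
    k: Mapping[Genotype, KValue]

    def __post_init__(self) -> None:
        if self.kind not in ("survival", "reproduction"):
            raise ValidationError(
                f"transition {self.label!r}: kind must be 'survival' or "
                f"'reproduction', got {self.kind!r}"
            )
        if not self.k:
            raise ValidationError(f"transition {self.label!r}: no genotypes")
        for g, v in self.k.items():
            if not callable(v):
                self._check_value(g, float(v))

    def _check_value(self, genotype: Genotype, value: float) -> float:
        if not (value > 0) or not math.isfinite(value):
            raise ValidationError(
                f"transition {self.label!r}, genotype {genotype!r}: "
                f"multiplier must be positive and finite, got {value}"
            )
        if self.kind == "survival" and value > 1.0 + _TOL:
            raise ValidationError(
                f"transition {self.label!r}, genotype {genotype!r}: "
                f"survival multiplier must be <= 1, got {value}"
            )
        return value

    @property
    def genotypes(self) -> tuple[Genotype, ...]:
        return tuple(self.k)

    def multiplier(
        self,
        genotype: Genotype,
        stage_size: float | None = None,
        frequencies: Mapping[Genotype, float] | None = None,
    ) -> float:
        """Evaluate this transition's multiplier for one genotype."""
        try:
            v = self.k[genotype]
        except KeyError:
            raise ValidationError(
                f"transition {self.label!r} has no multiplier for genotype "
                f"{genotype!r}"
            ) from None
        if callable(v):
            v = v(stage_size, frequencies)
        return self._check_value(genotype, float(v))

    def best(
        self,
        stage_size: float | None = None,
        frequencies: Mapping[Genotype, float] | None = None,
    ) -> tuple[Genotype, float]:
        """Best genotype at this transition (ties broken by sort order)."""
        values = {
            g: self.multiplier(g, stage_size, frequencies) for g in self.k
        }
        best_k = max(values.values())
        best_g = sorted(
            (g for g, v in values.items() if v == best_k), key=repr
        )[0]
        return best_g, best_k


@dataclass(frozen=True)
class CycleState:
    """Baseline forward simulation of one cycle.

    ``stage_sizes[j]`` is the deterministic population entering transition
    ``j`` (length T+1, the last entry being the end of the cycle), and
    ``stage_frequencies[j]`` the genotype frequencies at that boundary.
    Fractional individuals are allowed: these are deterministic
    expectations.
    """

    stage_sizes: tuple[float, ...]
    stage_frequencies: tuple[Mapping[Genotype, float], ...]


@dataclass(frozen=True)
class BottleneckSpec:
    """Bottleneck generalization for variable life cycles.

    ``n_bot`` is the smallest population that reliably escapes extinction
    after the bottleneck; ``paths`` is a finite distribution over the
    sequences of transitions that may lie between the focal transition and
    the bottleneck, as ``(weight, transitions)`` pairs with weights summing
    to one.
    """

    n_bot: float
    paths: Sequence[tuple[float, Sequence[Transition]]]

    def __post_init__(self) -> None:
        if self.n_bot < 1:
            raise ValidationError(f"N_bot must be >= 1, got {self.n_bot}")
        if not self.paths:
            raise ValidationError("at least one path is required")
        total = sum(w for w, _ in self.paths)
        if abs(total - 1.0) > 1e-8:
            raise ValidationError(f"path weights must sum to 1, got {total}")
        if any(w < 0 for w, _ in self.paths):
            raise ValidationError("path weights must be non-negative")


class LifeCycle:
    """An ordered life cycle with genotype frequencies and a starting size.

    Parameters
    ----------
    transitions
        Ordered transitions, numbered 0..T-1.
    initial_size
        Population size entering transition 0 (may be fractional).
    genotype_frequencies
        Frequencies at the start of the cycle; must be non-negative and sum
        to one, over the same genotype set as every transition.
    """

    def __init__(
        self,
        transitions: Sequence[Transition],
        initial_size: float,
        genotype_frequencies: Mapping[Genotype, float],
    ):
        if not transitions:
            raise ValidationError("a life cycle needs at least one transition")
        if initial_size <= 0:
            raise ValidationError(f"initial size must be positive, got {initial_size}")
        freqs = {g: float(f) for g, f in genotype_frequencies.items()}
        if not freqs:
            raise ValidationError("at least one genotype is required")
        if any(f < 0 for f in freqs.values()):
            raise ValidationError("genotype frequencies must be non-negative")
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-8:
            raise ValidationError(f"genotype frequencies must sum to 1, got {total}")
        genotypes = set(freqs)
        for t in transitions:
            if set(t.k) != genotypes:
                raise ValidationError(
                    f"transition {t.label!r} covers genotypes {sorted(map(repr, t.k))}, "
                    f"expected {sorted(map(repr, genotypes))}"
                )
        self.transitions = tuple(transitions)
        self.initial_size = float(initial_size)
        self.genotype_frequencies = freqs

    # -- baseline dynamics -------------------------------------------------

    def simulate_cycle(self) -> CycleState:
        """Deterministic forward pass through one cycle.

        Stage sizes follow N_{j+1} = N_j * sum_i f_i k_{i,j}; frequencies
        update as f_i' proportional to f_i k_{i,j}.
        """
        sizes = [self.initial_size]
        freqs: list[Mapping[Genotype, float]] = [dict(self.genotype_frequencies)]
        for t in self.transitions:
            n, f = sizes[-1], freqs[-1]
            kvals = {g: t.multiplier(g, n, f) for g in f}
            mean_k = sum(f[g] * kvals[g] for g in f)
            if mean_k <= 0:
                raise ValidationError(
                    f"transition {t.label!r}: mean multiplier is not positive"
                )
            sizes.append(n * mean_k)
            freqs.append({g: f[g] * kvals[g] / mean_k for g in f})
        return CycleState(tuple(sizes), tuple(freqs))

    def _baseline_multipliers(self, state: CycleState) -> list[dict[Genotype, float]]:
        """Per-transition multipliers evaluated on the baseline trajectory."""
        out = []
        for j, t in enumerate(self.transitions):
            n, f = state.stage_sizes[j], state.stage_frequencies[j]
            out.append({g: t.multiplier(g, n, f) for g in t.k})
        return out

    # -- N_min solvers -----------------------------------------------------

    def solve_nmin(self, focal: int, mode: str = "actual") -> float:
        """Minimum end-of-focal-transition size sustaining the cycle.

        ``mode="actual"`` solves N_j = N_min sum_i f_i prod_{x != j} k_{i,x}
        with f the cycle-start frequencies; ``mode="best"`` solves
        N_j = N_min prod_{x != j} k_best,x with the per-transition best
        genotype. Non-focal density-dependent multipliers are evaluated at
        the baseline trajectory (the counterfactual holds all else constant).
        """
        self._check_focal(focal)
        state = self.simulate_cycle()
        ks = self._baseline_multipliers(state)
        n_focal_start = state.stage_sizes[focal]
        if mode == "actual":
            f = self.genotype_frequencies
            denom = 0.0
            for g in f:
                prod = 1.0
                for x, kx in enumerate(ks):
                    if x != focal:
                        prod *= kx[g]
                denom += f[g] * prod
        elif mode == "best":
            denom = 1.0
            for x, t in enumerate(self.transitions):
                if x == focal:
                    continue
                denom *= max(ks[x].values())
        else:
            raise DomainError(f"mode must be 'actual' or 'best', got {mode!r}")
        if denom <= 0 or not math.isfinite(denom):
            offending = self.transitions[focal].label
            raise DomainError(
                f"non-focal multiplier product is {denom} when solving N_min "
                f"for focal transition {offending!r}"
            )
        return n_focal_start / denom

    def _check_focal(self, focal: int) -> None:
        if not (0 <= focal < len(self.transitions)):
            raise DomainError(
                f"focal transition index {focal} out of range "
                f"0..{len(self.transitions) - 1}"
            )

    def _focal_output(self, focal: int, mode: str, state: CycleState) -> float:
        """Realized k_j N_j of the focal transition for the focal population."""
        ks = self._baseline_multipliers(state)[focal]
        n = state.stage_sizes[focal]
        if mode == "best":
            return n * max(ks.values())
        f = self.genotype_frequencies
        return n * sum(f[g] * ks[g] for g in f)

    # -- reproductive excess -----------------------------------------------

    def reproductive_excess(self, focal: int, nmin_mode: str = "best") -> float:
        """RE_j = k_j N_j - N_min,j+1 for the chosen focal population.

        May be negative, signalling a cycle that is not self-sustaining.
        """
        self._check_focal(focal)
        state = self.simulate_cycle()
        return self._focal_output(focal, nmin_mode, state) - self.solve_nmin(
            focal, nmin_mode
        )

    def reproductive_excess_bottleneck(
        self, focal: int, spec: BottleneckSpec
    ) -> float:
        """RE with a variable path to a bottleneck of size ``N_bot``.

        Solves N_bot = N_min * E[prod_x k_best,x] over the path
        distribution, then RE = k_j N_j - N_min (best-genotype focal
        population). With a single path equal to the cycle's non-focal
        transitions and N_bot = N_j this reduces exactly to
        :meth:`reproductive_excess`.
        """
        self._check_focal(focal)
        expected = 0.0
        for w, path in spec.paths:
            prod = 1.0
            for t in path:
                _, best_k = t.best()
                prod *= best_k
            expected += w * prod
        if expected <= 0:
            raise DomainError("expected best-genotype path product is not positive")
        n_min = spec.n_bot / expected
        state = self.simulate_cycle()
        return self._focal_output(focal, "best", state) - n_min


@dataclass(frozen=True)
class WrightFisherIdentities:
    """Absolute-fitness Wright-Fisher identities for one transition pair."""

    selective_deaths_per_capita: float
    n_min: float
    reproductive_excess_per_capita: float


def wf_identities(k_mean: float, k_best: float, N: float) -> WrightFisherIdentities:
    """Per-capita identities for the absolute-fitness Wright-Fisher model.

    Adults of genotype i leave k_i offspring and die. Then selective deaths
    per capita are k_best - k_mean, N = N_min * k_best, and per-capita
    reproductive excess is k_mean - 1/k_best.
    """
    if k_mean <= 0:
        raise DomainError(f"mean absolute fitness must be positive, got {k_mean}")
    if k_mean > k_best:
        raise DomainError(
            f"mean absolute fitness {k_mean} exceeds best {k_best}"
        )
    if N <= 0:
        raise DomainError(f"population size must be positive, got {N}")
    return WrightFisherIdentities(
        selective_deaths_per_capita=k_best - k_mean,
        n_min=N / k_best,
        reproductive_excess_per_capita=k_mean - 1.0 / k_best,
    )


def selective_deaths_per_transition(
    transition: Transition, counts: Mapping[Genotype, float]
) -> tuple[dict[Genotype, float], float]:
    """Per-genotype and total selective deaths during one transition.

    Each genotype's selective deaths are the deaths (or foregone offspring)
    it would not have experienced had it carried the transition's best
    genotype: N_i (k_best - k_i). The best genotype is resolved per
    transition, so antagonistic pleiotropy yields positive totals at every
    transition involved; selective deaths never cancel across transitions.
    """
    if not counts:
        raise DomainError("at least one genotype with counts is required")
    if any(c < 0 for c in counts.values()):
        raise DomainError("counts must be non-negative")
    total_n = sum(counts.values())
    freqs = (
        {g: c / total_n for g, c in counts.items()}
        if total_n > 0
        else {g: 0.0 for g in counts}
    )
    ks = {g: transition.multiplier(g, total_n, freqs) for g in counts}
    best_k = max(ks.values())
    per_genotype = {g: counts[g] * (best_k - ks[g]) for g in counts}
    return per_genotype, sum(per_genotype.values())
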