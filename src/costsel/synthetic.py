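"""Synthetic cohort-table generator emulating a factorial common-garden
experiment.

The generator mimics the structure the empirical pipeline assumes: hundreds
of homozygous genotypes grown in a 2 x 2 x 2 factorial of location, water,
and density, 30 seeds per pot at high density, ~10 seeds thinned to a single
seedling at low density, binomial survival with genotype-specific true rates
drawn from per-condition beta priors, and overdispersed (gamma-Poisson)
per-survivor seed production. Alongside the table it returns a truth record
-- the true rates and the proportion of deaths that would be selective under
them -- so estimator consistency and bias corrections can be tested without
any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .empirical import (
    CohortTable,
    SEEDLING_RE_CAP,
    proportion_selective_deaths,
)
from .errors import UndefinedResultError, ValidationError

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "worked_fixture"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the synthetic cohort generator.

    Defaults emulate the factorial design the pipeline targets: 517
    genotypes, 2 locations x 2 water levels x 2 densities, one pot per
    genotype per environment, 30 seeds per high-density pot, 10 seeds sown
    and thinned to 1 seedling per low-density pot. True seedling-to-adult
    survival is drawn per genotype from a water-dependent beta prior
    (benign high-water Beta(20, 5) vs adverse low-water Beta(2, 5)); a
    shared, nonselective germination stage precedes it, so the
    planted-seed-to-adult rate is the germination fraction times the beta
    draw. Optional location and crowding multipliers default to 1 (note
    that non-unit values change the true-rate family from a beta scaled by
    a known germination bound to one scaled by an unobservable constant,
    which weakens the winner's-curse deconvolution). Per-survivor seed
    counts are gamma-Poisson with shape 4 (CV 0.5 across survivors).
    """

    n_genotypes: int = 517
    locations: tuple[str, ...] = ("madrid", "tuebingen")
    waters: tuple[str, ...] = ("high_water", "low_water")
    densities: tuple[str, ...] = ("high_density", "low_density")
    pots_per_genotype: int = 1
    seeds_per_pot_high: int = 30
    seeds_sown_low: int = 10
    thin_to: int = 1
    germination_rate: float = 0.75
    survival_prior: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"high_water": (20.0, 5.0), "low_water": (2.0, 5.0)}
    )
    location_effect: Mapping[str, float] = field(
        default_factory=lambda: {"madrid": 1.0, "tuebingen": 1.0}
    )
    density_effect: Mapping[str, float] = field(
        default_factory=lambda: {"high_density": 1.0, "low_density": 1.0}
    )
    fecundity_mean: float = 2000.0
    fecundity_shape: float = 4.0
    genotype_fecundity_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ValidationError("need at least 2 genotypes")
        if min(
            self.pots_per_genotype,
            self.seeds_per_pot_high,
            self.seeds_sown_low,
            self.thin_to,
        ) < 1:
            raise ValidationError("counts must be positive")
        if self.thin_to > self.seeds_sown_low:
            raise ValidationError(
                f"cannot thin to {self.thin_to} seedlings from "
                f"{self.seeds_sown_low} sown seeds"
            )
        if not (0.0 < self.germination_rate <= 1.0):
            raise ValidationError("germination rate must be in (0, 1]")
        for water in self.waters:
            a, b = self.survival_prior[water]
            if a <= 0 or b <= 0:
                raise ValidationError(f"beta parameters must be positive ({water})")
        if self.fecundity_mean <= 0 or self.fecundity_shape <= 0:
            raise ValidationError("fecundity mean and shape must be positive")

    @property
    def environments(self) -> list[str]:
        return [
            f"{loc}_{water}_{dens}"
            for loc in self.locations
            for water in self.waters
            for dens in self.densities
        ]

    @property
    def density_map(self) -> dict[str, str]:
        return {
            env: ("high" if env.endswith("high_density") else "low")
            for env in self.environments
        }


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated table plus the truth record it was generated from.

    ``truth_rates`` has one row per genotype x environment with the true
    seedling-to-adult and planted-seed-to-adult survival probabilities;
    ``truth`` has one row per environment with the proportion of deaths
    that would be selective under the true rates and the per-pot
    reproductive excesses implied by the expected stage occupancies
    (at each end of ``dispersal_survival``).
    """

    table: CohortTable
    truth_rates: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticConfig


def _true_prop_selective(rates: np.ndarray, denom: float) -> float:
    denominators = np.full(rates.size, denom)
    try:
        return proportion_selective_deaths(rates, denominators)
    except UndefinedResultError:
        return math.nan


def generate(
    config: SyntheticConfig | None = None,
    dispersal_survival: tuple[float, float] = (0.03, 0.3),
) -> SyntheticDataset:
    """Draw one synthetic experiment; identical (config, seed) pairs give
    identical output."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    G = config.n_genotypes
    genotypes = np.array([f"g{i:04d}" for i in range(G)])

    # genotype-level latent draws: a base survival per water level keeps a
    # genotype's identity comparable across locations and densities
    base = {
        water: rng.beta(*config.survival_prior[water], size=G)
        for water in config.waters
    }
    if config.genotype_fecundity_sd > 0:
        sd = config.genotype_fecundity_sd
        fec_mult = rng.lognormal(-0.5 * sd**2, sd, size=G)
    else:
        fec_mult = np.ones(G)

    frames = []
    truth_rate_rows = []
    truth_rows = []
    for env in config.environments:
        loc, water, dens = _parse_env(env, config)
        r_true = np.clip(
            base[water]
            * config.location_effect[loc]
            * config.density_effect[dens],
            1e-9,
            1.0,
        )
        g = config.germination_rate
        pots = config.pots_per_genotype
        high = dens == "high_density"
        if high:
            planted = np.full((G, pots), config.seeds_per_pot_high)
            seedlings = rng.binomial(planted, g)
            adults = rng.binomial(seedlings, r_true[:, None])
        else:
            planted = np.full((G, pots), config.seeds_sown_low)
            germinated = rng.binomial(planted, g)
            seedlings = np.minimum(germinated, config.thin_to)
            adults = rng.binomial(seedlings, r_true[:, None])
        mean_seeds = config.fecundity_mean * fec_mult[:, None]
        lam = np.where(
            adults > 0,
            rng.gamma(
                config.fecundity_shape * np.maximum(adults, 1),
                mean_seeds / config.fecundity_shape,
            ),
            0.0,
        )
        seeds_out = rng.poisson(lam)
        frames.append(
            pd.DataFrame(
                {
                    "genotype": np.repeat(genotypes, pots),
                    "environment": env,
                    "pot": np.tile(
                        np.array([f"pot{p + 1}" for p in range(pots)]), G
                    ),
                    "seeds_planted": planted.ravel(),
                    "seedlings_retained": seedlings.ravel(),
                    "adults": adults.ravel(),
                    "seeds_produced": seeds_out.ravel(),
                }
            )
        )
        # truth record, from the true (not sampled) rates
        seed_to_adult = g * r_true
        truth_rate_rows.append(
            pd.DataFrame(
                {
                    "genotype": genotypes,
                    "environment": env,
                    "seedling_to_adult": r_true,
                    "seed_to_adult": seed_to_adult,
                }
            )
        )
        if high:
            scoped = seed_to_adult
            denom_per_geno = float(config.seeds_per_pot_high * pots)
            seedlings_per_pot = config.seeds_per_pot_high * g
        else:
            scoped = r_true
            denom_per_geno = float(config.thin_to * pots)
            seedlings_per_pot = float(config.thin_to)
        adults_per_pot = float(np.mean(scoped) * planted[0, 0]) if high else float(
            np.mean(r_true) * config.thin_to
        )
        establishment = seedlings_per_pot / planted[0, 0]
        b = config.fecundity_mean
        r_best = float(r_true.max())
        lo, hi = dispersal_survival
        re_seeds = tuple(
            b * adults_per_pot - adults_per_pot / (d * establishment * r_best)
            for d in (lo, hi)
        )
        cap = SEEDLING_RE_CAP["high" if high else "low"]
        re_seedlings = tuple(
            min(
                r_best * seedlings_per_pot
                - seedlings_per_pot / (b * d * establishment),
                cap,
            )
            for d in (lo, hi)
        )
        truth_rows.append(
            {
                "environment": env,
                "prop_selective": _true_prop_selective(scoped, denom_per_geno),
                "best_true_rate": float(scoped.max()),
                "mean_true_rate": float(scoped.mean()),
                "re_seeds_low": min(re_seeds),
                "re_seeds_high": max(re_seeds),
                "re_seedlings_low": min(re_seedlings),
                "re_seedlings_high": max(re_seedlings),
            }
        )

    data = pd.concat(frames, ignore_index=True)
    table = CohortTable(data=data, density_map=config.density_map)
    return SyntheticDataset(
        table=table,
        truth_rates=pd.concat(truth_rate_rows, ignore_index=True),
        truth=pd.DataFrame(truth_rows).set_index("environment"),
        config=config,
    )


def _parse_env(env: str, config: SyntheticConfig) -> tuple[str, str, str]:
    for loc in config.locations:
        for water in config.waters:
            for dens in config.densities:
                if env == f"{loc}_{water}_{dens}":
                    return loc, water, dens
    raise ValidationError(f"unparseable environment id {env!r}")


def worked_fixture(seeds_per_survivor: int = 20) -> CohortTable:
    """Tiny hand-checkable cohort: 2 genotypes, 100 low-density pots each.

    Genotype A's retained seedling survives in 90 pots, genotype B's in 50,
    so the pooled survival rates are {0.9, 0.5} on denominators {100, 100}
    and the raw proportion of selective deaths is
    (100*0 + 100*0.4) / (100*0.1 + 100*0.5) = 40/60 = 2/3.
    """
    rows = []
    for genotype, survivors in (("A", 90), ("B", 50)):
        for pot in range(100):
            adults = 1 if pot < survivors else 0
            rows.append(
                {
                    "genotype": genotype,
                    "environment": "toy_low_density",
                    "pot": f"pot{pot + 1}",
                    "seeds_planted": 10,
                    "seedlings_retained": 1,
                    "adults": adults,
                    "seeds_produced": seeds_per_survivor * adults,
                }
            )
    return CohortTable(
        data=pd.DataFrame(rows), density_map={"toy_low_density": "low"}
    )
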