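"""Estimating the proportion of deaths that are selective from cohort data.

The input is a genotype x environment x pot table of counts at successive
life stages (seeds planted -> seedlings retained -> adults -> seeds
produced), emulating a common-garden design in which many inbred genotypes
are grown under factorial environmental conditions. Per environment the
pipeline

1. pools pots into per-genotype survival rates (seed->adult under high
   density, seedling->adult under low density, where thinning removes the
   seed stage from the accounting);
2. computes the raw proportion of deaths that are selective,
   ``sum_i n_i (r_best - r_i) / sum_i n_i (1 - r_i)`` -- the share of
   observed deaths that would have been avoided had every pot carried the
   best genotype;
3. corrects the winner's curse: the maximum of hundreds of noisy survival
   estimates overstates the best genotype's true rate, so both the maximum
   and the proportion are bias-adjusted by a parametric bootstrap (see
   :func:`adjust_extreme_value`);
4. tests for genotype differences in fecundity with a permutation test and,
   absent evidence, sets fecundity selective deaths to zero;
5. converts the observed stage occupancies into per-pot reproductive-excess
   ranges for the seed and seedling transitions, spanning a plausible
   (default 10-fold) range of seed survival during dispersal, for which
   such experiments carry no information.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedResultError, ValidationError
from .life_history import LifeCycle, Transition

__all__ = [
    "REQUIRED_COLUMNS",
    "CohortTable",
    "SurvivalEstimates",
    "ExtremeValueAdjustment",
    "FecundityGateResult",
    "ReproductiveExcessRange",
    "SelectiveDeathSummary",
    "PipelineConfig",
    "PipelineReport",
    "estimate_survival",
    "proportion_selective_deaths",
    "adjust_extreme_value",
    "fecundity_gate",
    "empirical_reproductive_excess",
    "run_all",
]

logger = logging.getLogger("costsel")

REQUIRED_COLUMNS = (
    "genotype",
    "environment",
    "pot",
    "seeds_planted",
    "seedlings_retained",
    "adults",
    "seeds_produced",
)

_COUNT_COLUMNS = ("seeds_planted", "seedlings_retained", "adults", "seeds_produced")

#: per-pot caps on seedling-stage reproductive excess imposed by the design
SEEDLING_RE_CAP = {"low": 1.0, "high": 30.0}


@dataclass
class CohortTable:
    """Validated cohort counts plus the environment -> density mapping.

    ``data`` holds one row per genotype x environment x pot with the columns
    in :data:`REQUIRED_COLUMNS`; ``density_map`` labels each environment
    ``"high"`` or ``"low"`` density, which decides the survival denominator
    (seeds planted vs seedlings retained after thinning).
    """

    data: pd.DataFrame
    density_map: Mapping[str, str]

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        for col in _COUNT_COLUMNS:
            values = pd.to_numeric(df[col], errors="coerce")
            bad = values.isna() | (values < 0) | (values % 1 != 0)
            if bad.any():
                raise ValidationError(
                    f"column {col!r}: non-count values at rows "
                    f"{list(df.index[bad])[:10]}"
                )
            df[col] = values.astype(np.int64)
        bad = df.index[
            (df["adults"] > df["seedlings_retained"])
            | (df["seedlings_retained"] > df["seeds_planted"])
        ]
        if len(bad):
            raise ValidationError(
                "stage counts must satisfy adults <= seedlings_retained <= "
                f"seeds_planted; violated at rows {list(bad)[:10]}"
            )
        envs = set(df["environment"].unique())
        unmapped = envs - set(self.density_map)
        if unmapped:
            raise ValidationError(
                f"environments missing from density_map: {sorted(unmapped)}"
            )
        for env, dens in self.density_map.items():
            if dens not in ("high", "low"):
                raise ValidationError(
                    f"density for environment {env!r} must be 'high' or 'low', "
                    f"got {dens!r}"
                )
        for env in sorted(envs):
            sub = df[df["environment"] == env]
            if self.density_map[env] == "low":
                if (sub["seedlings_retained"] > 1).any():
                    raise ValidationError(
                        f"low-density environment {env!r} has pots with more "
                        "than 1 retained seedling"
                    )
            else:
                planted = sub["seeds_planted"].unique()
                if set(planted) != {30}:
                    warnings.warn(
                        f"high-density environment {env!r} has seeds_planted "
                        f"{sorted(planted)} rather than the usual 30 per pot",
                        stacklevel=2,
                    )
        self.data = df.reset_index(drop=True)

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["environment"].unique())

    def density(self, environment: str) -> str:
        return self.density_map[environment]

    def subset(self, environment: str) -> pd.DataFrame:
        sub = self.data[self.data["environment"] == environment]
        if sub.empty:
            raise DomainError(f"environment {environment!r} not present in table")
        return sub


@dataclass(frozen=True)
class SurvivalEstimates:
    """Pooled per-genotype survival rates for one environment."""

    environment: str
    transition_scope: str  # "seed_to_adult" or "seedling_to_adult"
    table: pd.DataFrame  # index genotype; columns survivors, denominator, rate
    excluded: tuple = ()

    @property
    def rates(self) -> np.ndarray:
        return self.table["rate"].to_numpy()

    @property
    def denominators(self) -> np.ndarray:
        return self.table["denominator"].to_numpy()

    @property
    def best_genotype(self) -> str:
        best = self.table["rate"].max()
        ties = sorted(self.table.index[self.table["rate"] == best])
        return ties[0]


def estimate_survival(table: CohortTable, environment: str) -> SurvivalEstimates:
    """Per-genotype survival rates, pooled over pots.

    Pools numerators and denominators across pots (the minimum-variance
    binomial estimator given equal-design replicates). High-density
    environments use seeds planted as the denominator (seed -> adult
    survival); low-density environments use retained seedlings
    (seedling -> adult), since thinning makes seed-stage deaths
    uninformative there. Genotypes with a zero denominator are excluded
    with a logged warning.
    """
    sub = table.subset(environment)
    density = table.density(environment)
    denom_col = "seeds_planted" if density == "high" else "seedlings_retained"
    scope = "seed_to_adult" if density == "high" else "seedling_to_adult"
    grouped = sub.groupby("genotype")[["adults", denom_col]].sum()
    grouped.columns = ["survivors", "denominator"]
    excluded = tuple(grouped.index[grouped["denominator"] == 0])
    if excluded:
        logger.warning(
            "environment %s: excluding %d genotype(s) with zero denominator: %s",
            environment,
            len(excluded),
            list(excluded)[:5],
        )
        grouped = grouped[grouped["denominator"] > 0]
    if len(grouped) < 2:
        raise DomainError(
            f"environment {environment!r}: need >= 2 genotypes with nonzero "
            f"denominators, have {len(grouped)}"
        )
    grouped["rate"] = grouped["survivors"] / grouped["denominator"]
    return SurvivalEstimates(
        environment=environment,
        transition_scope=scope,
        table=grouped.sort_index(),
        excluded=excluded,
    )


def proportion_selective_deaths(
    rates: Sequence[float],
    denominators: Sequence[float],
    r_best: float | None = None,
) -> float:
    """Share of deaths that are selective for one environment.

    ``sum_i n_i max(r_best - r_i, 0) / sum_i n_i (1 - r_i)`` where
    ``r_best`` defaults to the maximum observed rate (pass a bias-adjusted
    value to compose with the winner's-curse correction). Equals 0 when all
    rates are equal and 1 when the best genotype survives perfectly. Raises
    :class:`UndefinedResultError` when no deaths occurred at all.
    """
    r = np.asarray(rates, dtype=float)
    n = np.asarray(denominators, dtype=float)
    if r.size < 2:
        raise DomainError(f"need >= 2 genotypes, got {r.size}")
    if r.shape != n.shape:
        raise DomainError("rates and denominators must have matching shapes")
    if (n <= 0).any() or (r < 0).any() or (r > 1).any():
        raise DomainError("rates must be in [0, 1] and denominators positive")
    if r_best is None:
        r_best = float(r.max())
    total_deaths = float((n * (1.0 - r)).sum())
    if total_deaths == 0:
        raise UndefinedResultError(
            "no deaths occurred: the proportion of selective deaths is undefined"
        )
    selective = float((n * np.clip(r_best - r, 0.0, None)).sum())
    return selective / total_deaths


# ---------------------------------------------------------------------------
# winner's-curse (extreme-value bias) adjustment


@dataclass(frozen=True)
class ExtremeValueAdjustment:
    """Bias-adjusted best rate and proportion of selective deaths.

    ``inflation`` is the estimated winner's-curse excess of the observed
    maximum rate over the true best rate; ``bias`` the corresponding excess
    of the raw proportion over the truth. Both are subtracted (with floors)
    to give the adjusted values, which never exceed the raw ones.
    """

    strategy: str
    n_replicates: int
    r_best_raw: float
    r_best_adjusted: float
    inflation: float
    prop_raw: float
    prop_adjusted: float
    bias: float


def _tarone_z(rates: np.ndarray, denominators: np.ndarray) -> float:
    """Tarone's standard-normal score statistic for binomial overdispersion.

    Large positive values indicate genotype-to-genotype spread in the true
    rates beyond binomial sampling noise.
    """
    n = denominators
    x = rates * n
    p = float(x.sum() / n.sum())
    if p <= 0.0 or p >= 1.0:
        return 0.0
    pairs = float((n * (n - 1.0)).sum())
    if pairs <= 0.0:  # all denominators are 1: overdispersion undetectable
        return 0.0
    chi = float(((x - n * p) ** 2 / (p * (1.0 - p))).sum())
    return (chi - float(n.sum())) / math.sqrt(2.0 * pairs)


# One-sided 0.1% normal critical value for the overdispersion pre-test. The
# stringency is deliberate: a false heterogeneity call biases the max-based
# proportion by roughly ten times the spurious fitted spread, whereas any
# biologically meaningful spread in designs of this size gives Z >> 10.
_TARONE_CRITICAL = 3.09


def _fit_beta_truth(
    rates: np.ndarray, denominators: np.ndarray, scale: float = 1.0
) -> tuple[float, float] | float:
    """Deconvolve the true-rate distribution from noisy binomial rates.

    The maximum of hundreds of rates is so sensitive to spurious fitted
    spread that an overdispersion pre-test is essential: unless Tarone's
    statistic rejects a shared rate, the truth is treated as a point mass at
    the pooled rate. Otherwise the true rates are modelled as
    ``scale * Beta(a, b)`` -- ``scale`` being a known upper bound such as
    the nonselective germination fraction -- with (a, b) matched to the
    observed mean and to the observed spread minus the unbiased binomial
    sampling variance (E[r(1-r)/(n-1)] = pq/n). Anchoring the support at a
    known bound matters because the fitted upper tail, which the likelihood
    alone identifies only weakly, drives the expected maximum.

    Returns (a, b) for the beta factor, or a plain float (the pooled rate)
    for the point-mass case.
    """
    n = denominators
    m = float(np.clip(np.average(rates, weights=n), 1e-9, 1.0 - 1e-9))
    if rates.size < 2:
        return m
    if _tarone_z(rates, n) <= _TARONE_CRITICAL:
        return m
    total_var = float(rates.var(ddof=1))
    sampling_var = float(np.mean(rates * (1.0 - rates) / np.maximum(n - 1.0, 1.0)))
    true_var = (total_var - sampling_var) / scale**2
    m_t = min(m / scale, 1.0 - 1e-9)
    upper = m_t * (1.0 - m_t)
    if true_var <= 1e-12:
        return m
    if true_var >= upper:  # heavier-tailed than any beta: keep maximal spread
        true_var = 0.999 * upper
    common = upper / true_var - 1.0
    a, b = m_t * common, (1.0 - m_t) * common
    if a <= 0 or b <= 0 or not (math.isfinite(a) and math.isfinite(b)):
        return m
    return (a, b)


def _posterior_rates(
    rates: np.ndarray,
    denominators: np.ndarray,
    a: float,
    b: float,
    c: float,
    B: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample true rates conditional on the data under the fitted prior.

    Empirical-Bayes posterior draws: each genotype's true rate is
    ``c * t`` with prior ``t ~ Beta(a, b)`` and likelihood
    ``x ~ Binomial(n, c t)``. The scaled likelihood breaks beta
    conjugacy, so the posterior is evaluated on a fine grid of ``t`` and
    sampled by inverse CDF. Returns a (B, G) array of plausible true-rate
    cohorts; conditioning on the observed counts (rather than resampling
    fresh cohorts from the prior) keeps the adjusted maximum aligned with
    the genotypes actually present.
    """
    t = np.linspace(5e-4, 1.0 - 5e-4, 2001)
    x = rates * denominators
    log_prior = (a - 1.0) * np.log(t) + (b - 1.0) * np.log1p(-t)
    p = np.clip(c * t, 1e-12, 1.0 - 1e-12)
    # (G, K) log posterior, binomial normalizing constants drop out
    log_post = (
        log_prior[None, :]
        + x[:, None] * np.log(p)[None, :]
        + (denominators - x)[:, None] * np.log1p(-p)[None, :]
    )
    log_post -= log_post.max(axis=1, keepdims=True)
    weights = np.exp(log_post)
    cdf = np.cumsum(weights, axis=1)
    cdf /= cdf[:, -1:]
    u = rng.random((B, rates.size))
    draws = np.empty_like(u)
    for g in range(rates.size):
        draws[:, g] = t[np.searchsorted(cdf[g], u[:, g])]
    return c * draws


def _prop_rows(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Row-wise proportion of selective deaths; NaN where no deaths."""
    deaths = (n[None, :] * (1.0 - r)).sum(axis=1)
    best = r.max(axis=1, keepdims=True)
    selective = (n[None, :] * np.clip(best - r, 0.0, None)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(deaths > 0, selective / np.where(deaths > 0, deaths, 1.0), np.nan)
    return out


def adjust_extreme_value(
    rates: Sequence[float],
    denominators: Sequence[float],
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    strategy: str = "beta",
    scale: float = 1.0,
) -> ExtremeValueAdjustment:
    """Correct the winner's curse in the best observed survival rate.

    The maximum of many noisy binomial rate estimates exceeds the true best
    rate, inflating the apparent proportion of selective deaths.

    Strategies (the correction is pluggable so an alternative published
    procedure can be slotted in):

    ``"beta"`` (default)
        Deconvolve-then-evaluate. The distribution of *true* rates is
        fitted as ``scale * Beta(a, b)`` by method of moments after
        subtracting binomial sampling variance (with an overdispersion
        pre-test, see :func:`_fit_beta_truth`); ``B`` cohorts of true rates
        are simulated from the fit and the adjusted best rate and adjusted
        proportion are their simulation means. Because the data's own noisy
        maximum never enters the adjusted values, a lucky perfect-survival
        genotype cannot inflate them. ``scale`` is a known upper bound on
        the true rates -- e.g. the pooled germination fraction when the
        survival denominator is planted seeds, since no more seeds can
        reach adulthood than germinate.
    ``"point"``
        Parametric bootstrap at the observed point estimates: resample each
        genotype's survivors binomially at its estimated rate and subtract
        the mean excess of the simulated maximum (and simulated
        proportion) over the estimates' own maximum (and proportion).
        Removes only the incremental curse; retained for comparison.

    Deterministic given ``seed``; adjusted values are clipped so that
    0 <= adjusted <= raw always holds.
    """
    if B < 100:
        raise DomainError(f"need at least 100 bootstrap replicates, got {B}")
    if strategy not in ("beta", "point"):
        raise DomainError(f"unknown adjustment strategy {strategy!r}")
    r = np.asarray(rates, dtype=float)
    n = np.asarray(denominators, dtype=float)
    if (n <= 0).any() or (r < 0).any() or (r > 1).any():
        raise DomainError("rates must be in [0, 1] and denominators positive")
    if not (0.0 < scale <= 1.0):
        raise DomainError(f"scale must be in (0, 1], got {scale}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    r_best_raw = float(r.max())

    if r.size == 1 or float((n * (1.0 - r)).sum()) == 0:
        # single genotype (no extreme-value competition) or no deaths at
        # all: nothing to adjust, pass the observations through
        return ExtremeValueAdjustment(
            strategy, B, r_best_raw, r_best_raw, 0.0, math.nan, math.nan, 0.0
        )
    prop_raw = proportion_selective_deaths(r, n)
    mean_rate = float(np.average(r, weights=n))

    if strategy == "point":
        rho = np.broadcast_to(r, (B, r.size))
        counts = rng.binomial(n.astype(np.int64)[None, :], rho)
        r_star = counts / n[None, :]
        inflation = max(float(np.mean(r_star.max(axis=1)) - r_best_raw), 0.0)
        r_best_adjusted = float(
            np.clip(r_best_raw - inflation, mean_rate, r_best_raw)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bias = float(np.nanmean(_prop_rows(r_star, n)) - prop_raw)
        bias = max(bias, 0.0) if math.isfinite(bias) else 0.0
        prop_adjusted = float(np.clip(prop_raw - bias, 0.0, prop_raw))
    else:
        c = max(scale, r_best_raw)
        fit = _fit_beta_truth(r, n, c)
        if isinstance(fit, tuple):
            a, b = fit
            rho = _posterior_rates(r, n, a, b, c, B, rng)
        else:
            rho = np.full((B, r.size), fit)
        r_best_adjusted = float(np.mean(rho.max(axis=1)))
        r_best_adjusted = float(
            np.clip(r_best_adjusted, mean_rate, r_best_raw)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            prop_truth = float(np.nanmean(_prop_rows(rho, n)))
        if not math.isfinite(prop_truth):
            prop_truth = 0.0
        prop_adjusted = float(np.clip(prop_truth, 0.0, prop_raw))
        inflation = r_best_raw - r_best_adjusted
        bias = prop_raw - prop_adjusted
    return ExtremeValueAdjustment(
        strategy=strategy,
        n_replicates=B,
        r_best_raw=r_best_raw,
        r_best_adjusted=r_best_adjusted,
        inflation=inflation,
        prop_raw=prop_raw,
        prop_adjusted=prop_adjusted,
        bias=bias,
    )


# ---------------------------------------------------------------------------
# fecundity gate


@dataclass(frozen=True)
class FecundityGateResult:
    """Permutation test for genotype differences in per-survivor fecundity.

    When the test is not significant at ``alpha``, fecundity selective
    deaths are set to zero (no evidence of selection on fecundity);
    otherwise they are ``N_i (b_best - b_i)`` with ``b_i`` the genotype
    mean seeds per survivor.
    """

    environment: str
    significant: bool
    p_value: float
    fecundity: pd.Series  # genotype -> mean seeds per survivor
    deaths: pd.Series  # genotype -> fecundity selective deaths
    note: str = ""

    @property
    def total_deaths(self) -> float:
        return float(self.deaths.sum())


def fecundity_gate(
    table: CohortTable,
    environment: str,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> FecundityGateResult:
    """Gate fecundity selective deaths behind a permutation test.

    Pot-level seeds per survivor are permuted freely across genotype labels;
    the statistic is the variance of genotype means. The reported p-value
    uses the add-one convention, so ``alpha=1`` always passes (gate
    disabled).
    """
    if n_permutations < 1000:
        raise DomainError(
            f"need at least 1000 permutations, got {n_permutations}"
        )
    sub = table.subset(environment)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    with_adults = sub[sub["adults"] > 0]
    empty = pd.Series(dtype=float)
    if with_adults.empty:
        logger.warning(
            "environment %s: no surviving adults, fecundity gate skipped",
            environment,
        )
        return FecundityGateResult(
            environment, False, math.nan, empty, empty, note="no survivors"
        )
    adults = with_adults["adults"].to_numpy(float)
    seeds = with_adults["seeds_produced"].to_numpy(float)
    codes, genotypes = pd.factorize(with_adults["genotype"], sort=True)
    n_groups = len(genotypes)
    adults_by_geno = with_adults.groupby("genotype")["adults"].sum().sort_index()
    b = pd.Series(
        np.bincount(codes, weights=seeds, minlength=n_groups)
        / np.bincount(codes, weights=adults, minlength=n_groups),
        index=genotypes,
        name="seeds_per_survivor",
    )
    if n_groups < 2:
        return FecundityGateResult(
            environment,
            False,
            math.nan,
            b,
            pd.Series(0.0, index=b.index),
            note="fewer than 2 genotypes with survivors",
        )

    def weighted_var_stat(perm_codes: np.ndarray) -> float:
        # survivor-weighted among-genotype variance of pooled seeds per
        # survivor; weighting by survivors keeps the statistic calibrated
        # when pot means are noisier for genotypes with few survivors
        A = np.bincount(perm_codes, weights=adults, minlength=n_groups)
        S = np.bincount(perm_codes, weights=seeds, minlength=n_groups)
        present = A > 0
        bg = S[present] / A[present]
        b_pool = seeds.sum() / adults.sum()
        return float((A[present] * (bg - b_pool) ** 2).sum())

    observed = weighted_var_stat(codes)
    exceed = 0
    codes_work = codes.copy()
    for _ in range(n_permutations):
        rng.shuffle(codes_work)
        if weighted_var_stat(codes_work) >= observed:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_permutations)
    significant = p_value <= alpha
    if significant:
        deaths = adults_by_geno.astype(float) * (b.max() - b)
    else:
        deaths = pd.Series(0.0, index=b.index)
    return FecundityGateResult(environment, significant, p_value, b, deaths)


# ---------------------------------------------------------------------------
# reproductive excess from observed stage occupancies


@dataclass(frozen=True)
class ReproductiveExcessRange:
    """Per-pot reproductive-excess ranges for the seed and seedling
    transitions, spanning the assumed dispersal-survival range."""

    environment: str
    re_seeds: tuple[float, float]
    re_seedlings: tuple[float, float]
    dispersal_survival: tuple[float, float]
    components: Mapping[str, float] = field(default_factory=dict)


def _best_cycle_re(
    transitions: list[Transition],
    initial_size: float,
    frequencies: Mapping[str, float],
) -> float:
    cycle = LifeCycle(transitions, initial_size, frequencies)
    return cycle.reproductive_excess(0, nmin_mode="best")


def empirical_reproductive_excess(
    table: CohortTable,
    environment: str,
    dispersal_survival: tuple[float, float] = (0.03, 0.3),
) -> ReproductiveExcessRange:
    """Per-pot reproductive excess for seeds produced and for seedlings
    surviving to adulthood.

    Reconstructs the annual-plant life cycle implied by the experiment --
    adults -> seeds (reproduction) -> dispersal (survival, assumed) ->
    establishment (survival, observed seedlings per planted seed) ->
    adulthood (selective survival, observed per genotype) -- and evaluates
    the best-genotype-mode reproductive excess at each end of the assumed
    dispersal-survival range. Fecundity uses the pooled mean seeds per
    survivor (genotype differences are gated separately). Seedling-stage
    excess is capped at the design's pot capacity (1 per pot at low
    density, 30 at high density).
    """
    lo, hi = dispersal_survival
    if not (0.0 < lo <= hi <= 1.0):
        raise DomainError(
            f"dispersal survival range must satisfy 0 < low <= high <= 1, "
            f"got {dispersal_survival}"
        )
    sub = table.subset(environment)
    density = table.density(environment)
    n_pots = len(sub)
    total_adults = int(sub["adults"].sum())
    total_seedlings = int(sub["seedlings_retained"].sum())
    total_planted = int(sub["seeds_planted"].sum())
    total_seeds_out = int(sub["seeds_produced"].sum())
    if total_adults == 0 or total_seedlings == 0:
        raise UndefinedResultError(
            f"environment {environment!r}: no adults or no seedlings, "
            "reproductive excess undefined"
        )
    adults_per_pot = total_adults / n_pots
    seedlings_per_pot = total_seedlings / n_pots
    establishment = total_seedlings / total_planted
    fecundity = total_seeds_out / total_adults
    if fecundity <= 0:
        raise UndefinedResultError(
            f"environment {environment!r}: no seeds produced"
        )

    by_geno = sub.groupby("genotype")[["adults", "seedlings_retained"]].sum()
    by_geno = by_geno[by_geno["seedlings_retained"] > 0]
    # life-cycle multipliers must be positive; a genotype observed with zero
    # survivors is floored at a negligible rate (it never drives the
    # best-genotype-mode calculation anyway)
    survival = {
        g: max(v, 1e-9)
        for g, v in (by_geno["adults"] / by_geno["seedlings_retained"]).items()
    }
    if not survival:
        raise UndefinedResultError(
            f"environment {environment!r}: no genotype with seedlings"
        )
    # frequencies at each cycle's starting stage, by observed occupancy
    adult_share = (by_geno["adults"] / max(total_adults, 1)).to_dict()
    seedling_share = (
        by_geno["seedlings_retained"] / total_seedlings
    ).to_dict()
    genotypes = list(survival)
    if abs(sum(adult_share.values()) - 1.0) > 1e-9:
        # adults of genotypes without seedlings are impossible by the stage
        # ordering, so shares over this genotype set always sum to 1
        adult_share = {g: 1.0 / len(genotypes) for g in genotypes}

    def shared(label: str, kind: str, value: float) -> Transition:
        return Transition(label, kind, {g: value for g in genotypes})

    re_seeds, re_seedlings = [], []
    cap = SEEDLING_RE_CAP[density]
    for d in (lo, hi):
        survival_t = Transition("seedling_to_adult", "survival", survival)
        re_seeds.append(
            _best_cycle_re(
                [
                    shared("reproduction", "reproduction", fecundity),
                    shared("dispersal", "survival", d),
                    shared("establishment", "survival", establishment),
                    survival_t,
                ],
                adults_per_pot,
                adult_share,
            )
        )
        re_seedlings.append(
            min(
                _best_cycle_re(
                    [
                        survival_t,
                        shared("reproduction", "reproduction", fecundity),
                        shared("dispersal", "survival", d),
                        shared("establishment", "survival", establishment),
                    ],
                    seedlings_per_pot,
                    seedling_share,
                ),
                cap,
            )
        )
    return ReproductiveExcessRange(
        environment=environment,
        re_seeds=(min(re_seeds), max(re_seeds)),
        re_seedlings=(min(re_seedlings), max(re_seedlings)),
        dispersal_survival=(lo, hi),
        components={
            "adults_per_pot": adults_per_pot,
            "seedlings_per_pot": seedlings_per_pot,
            "establishment": establishment,
            "seeds_per_survivor": fecundity,
            "best_survival": max(survival.values()),
            "n_pots": float(n_pots),
        },
    )


# ---------------------------------------------------------------------------
# end-to-end driver


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs for the per-environment analysis chain."""

    dispersal_survival: tuple[float, float] = (0.03, 0.3)
    bootstrap_replicates: int = 1000
    alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    strategy: str = "beta"


@dataclass(frozen=True)
class SelectiveDeathSummary:
    """One environment's selective-death and reproductive-excess summary."""

    environment: str
    transition_scope: str
    prop_selective_raw: float
    prop_selective_adjusted: float
    re_seeds: tuple[float, float]
    re_seedlings: tuple[float, float]
    best_genotype: str
    n_genotypes: int
    fecundity_significant: bool
    fecundity_p_value: float
    fecundity_deaths_total: float

    def __post_init__(self) -> None:
        raw, adj = self.prop_selective_raw, self.prop_selective_adjusted
        if not (math.isnan(raw) or 0.0 <= adj <= raw <= 1.0):
            raise ValidationError(
                f"environment {self.environment!r}: need "
                f"0 <= adjusted <= raw <= 1, got adjusted={adj}, raw={raw}"
            )


@dataclass
class PipelineReport:
    """Summaries for every environment, plus isolated per-environment errors."""

    summaries: list[SelectiveDeathSummary]
    errors: dict[str, str]
    config: PipelineConfig

    def to_frame(self) -> pd.DataFrame:
        """Tidy table, one row per environment x transition."""
        rows = []
        for s in self.summaries:
            for transition, (re_lo, re_hi) in (
                ("seeds_produced", s.re_seeds),
                ("seedlings_to_adult", s.re_seedlings),
            ):
                rows.append(
                    {
                        "environment": s.environment,
                        "transition": transition,
                        "re_per_pot_low": re_lo,
                        "re_per_pot_high": re_hi,
                        "transition_scope": s.transition_scope,
                        "prop_selective_raw": s.prop_selective_raw,
                        "prop_selective_adjusted": s.prop_selective_adjusted,
                        "best_genotype": s.best_genotype,
                        "n_genotypes": s.n_genotypes,
                        "fecundity_significant": s.fecundity_significant,
                        "fecundity_p_value": s.fecundity_p_value,
                        "fecundity_deaths_total": s.fecundity_deaths_total,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "config": {
                "dispersal_survival": list(self.config.dispersal_survival),
                "bootstrap_replicates": self.config.bootstrap_replicates,
                "alpha": self.config.alpha,
                "n_permutations": self.config.n_permutations,
                "seed": self.config.seed,
                "strategy": self.config.strategy,
            },
            "environments": {
                s.environment: {
                    "transition_scope": s.transition_scope,
                    "prop_selective_raw": s.prop_selective_raw,
                    "prop_selective_adjusted": s.prop_selective_adjusted,
                    "re_seeds_per_pot": list(s.re_seeds),
                    "re_seedlings_per_pot": list(s.re_seedlings),
                    "best_genotype": s.best_genotype,
                    "n_genotypes": s.n_genotypes,
                    "fecundity_significant": s.fecundity_significant,
                    "fecundity_p_value": s.fecundity_p_value,
                    "fecundity_deaths_total": s.fecundity_deaths_total,
                }
                for s in self.summaries
            },
            "errors": dict(self.errors),
        }


def run_all(table: CohortTable, config: PipelineConfig | None = None) -> PipelineReport:
    """Run the full chain per environment: estimate -> adjust -> gate -> RE.

    Per-environment failures are caught and reported in ``errors`` rather
    than aborting the run. Reproducible: identical (table, config) pairs
    give identical reports, with per-environment random streams derived
    from ``config.seed`` and the environment's rank.
    """
    config = config or PipelineConfig()
    summaries: list[SelectiveDeathSummary] = []
    errors: dict[str, str] = {}
    for idx, env in enumerate(table.environments):
        rng = np.random.default_rng([config.seed, idx])
        try:
            est = estimate_survival(table, env)
            # when the denominator is planted seeds, germinating at all is a
            # prerequisite for adulthood, so the pooled germination fraction
            # bounds every genotype's true seed-to-adult rate
            scale = 1.0
            if table.density(env) == "high":
                sub = table.subset(env)
                planted = int(sub["seeds_planted"].sum())
                if planted > 0 and int(sub["seedlings_retained"].sum()) > 0:
                    scale = min(1.0, sub["seedlings_retained"].sum() / planted)
            adj = adjust_extreme_value(
                est.rates,
                est.denominators,
                B=config.bootstrap_replicates,
                seed=rng,
                strategy=config.strategy,
                scale=scale,
            )
            gate = fecundity_gate(
                table,
                env,
                alpha=config.alpha,
                n_permutations=config.n_permutations,
                seed=rng,
            )
            re = empirical_reproductive_excess(
                table, env, dispersal_survival=config.dispersal_survival
            )
            summaries.append(
                SelectiveDeathSummary(
                    environment=env,
                    transition_scope=est.transition_scope,
                    prop_selective_raw=adj.prop_raw,
                    prop_selective_adjusted=adj.prop_adjusted,
                    re_seeds=re.re_seeds,
                    re_seedlings=re.re_seedlings,
                    best_genotype=est.best_genotype,
                    n_genotypes=len(est.table),
                    fecundity_significant=gate.significant,
                    fecundity_p_value=gate.p_value,
                    fecundity_deaths_total=gate.total_deaths,
                )
            )
        except Exception as exc:  # noqa: BLE001 - isolate per-environment failures
            logger.warning("environment %s failed: %s", env, exc)
            errors[env] = f"{type(exc).__name__}: {exc}"
    return PipelineReport(summaries=summaries, errors=errors, config=config)
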