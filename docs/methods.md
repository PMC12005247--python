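# Methods

`costsel` quantifies two linked ideas: adaptive substitutions are paid for
in *selective deaths* (deaths, or foregone offspring, that causally change
allele frequencies), and the budget they are paid from is a population's
finite *reproductive excess*. This note records the models, the numerical
choices, and the limits of what the test suite demonstrates.

## Sweep costs and speed limits

**Trajectory model.** A sweep follows the deterministic continuous-time
logistic `dp/dt = s p (1-p)`. Per-capita selective deaths accrue at rate
`s(1-p)` for a haploid locus and `2s(1-p)` for a diploid locus under genic
selection (fitnesses 1, 1-s, 1-2s; two allele copies per individual). The
per-sweep cost `D` is the integral of that rate along the trajectory from
`p0` to `p_end`, computed by adaptive quadrature in `p` (the change of
variables removes time; relative tolerance 1e-8). Under this model `D`
equals `copies * ln(p_end/p0)` exactly, hence `-ln(p0)` (haploid) and
`-2 ln(p0)` (diploid genic) in the small-`p0` limit — 18.4 per capita at
`p0 = 1e-4`. `p_end` defaults to `max(1-p0, p0)`, a symmetric truncation of
fixation; the neglected tails are below reporting precision. Dominant,
recessive, and inbred diploid variants are enumerated in `PloidyModel` but
raise `NotImplementedError`: the package implements the two cases whose
printed values anchor the tests.

**Spacings.** Three conversions from cost to a minimum number of
generations per sweep:

* intensity-capped: `n = D_total / I_max` (30/0.1 = 300);
* reproductive-excess (finite fecundity `k` per adult, extrinsic mortality
  folded into `k_effective = k * survival`): `n = -ln(p0)/ln(k)`, 97 at
  `p0=1e-4, k=1.1`; algebraically identical to the intensity form with
  `ln(k)` in place of `I`, and equivalent to a substitution rate of
  `ln(RE/N + 1)/(-ln p0)` with `RE = (k-1)N`;
* lead-capped: with sweeps every `n` generations the fitness SD is
  `sqrt(s/n)`; the best genotype present sits `c = E[max of N standard
  normals]` SDs above the mean, so capping the lead gives
  `n = s (c/cap)^2`.

`E[max]` is computed by quadrature of the exact order-statistic expectation
for `N <= 1e8` (accurate to ~1e-3 SD) and by the Gumbel-limit expansion
`b_N + gamma/b'_N` above (overflow-safe past 1e12). At `N = 1e6` the value
is 4.863; with the conventional rounding to 4.9 the lead-capped spacing at
`s=0.01, cap=0.1` is ~24 generations. Historical accounts quote "around
20"; the difference traces entirely to the rounding of the 4.9 constant,
and the package reports the computed value.

## Life-history framework

A life cycle is an ordered list of transitions with per-genotype
multipliers `k` (`k <= 1` survival, `k > 1` allowed for reproduction);
stage boundary `j` is the population entering transition `j`, and
fractional individuals are allowed (everything is a deterministic
expectation). For a focal transition,

```
N_min,j+1 = N_j / (sum_i f_i prod_{x!=j} k_{i,x})     (actual population)
N_min,j+1 = N_j / (prod_{x!=j} k_best,x)              (best-genotype population)
RE_j      = k_j N_j - N_min,j+1
```

with `f_i` the cycle-start frequencies and the best genotype resolved *per
transition* (necessary for antagonistic pleiotropy, where selective deaths
at different transitions never cancel). Density-dependent multipliers are
accepted as callables `(stage_size, frequencies) -> k` and are evaluated on
the baseline trajectory when solving for `N_min`: the quantity is defined
as a counterfactual holding everything else constant. Variable life cycles
are handled by the bottleneck form `N_min = N_bot / E[prod k_best,x]`, the
expectation running over a finite distribution of transition paths;
`N_bot`, the smallest population that reliably escapes extinction, is a
user input with no default because it is an ecological judgment.

## Traveling-wave connection

For an asexual population in the multiple-mutations regime (parameters `N`,
`U`, `s`; validity `0 < U < s`, warning below `s/U = 3`), the lead `q s` of
the fitness nose determines both the minimum reproductive excess (`q s`)
and the proportion of deaths that are selective (`1 - 1/(1+qs)`). The lead
factor solves the steady-state self-consistency condition

```
q^2 / (2(q-1)) * ln(s/U) = ln(N s q)
```

derived from the wave's bookkeeping: the class that will eventually
dominate is established at the nose with ~`1/(qs)` individuals, grows to
~`N` over `q` establishment intervals of length `ln(s/U)/((q-1)s)`, and its
advantage over the mean decays linearly from `qs` to 0. The solution
approaches the familiar asymptote `q = 2 ln(Ns)/ln(s/U)` for large
`ln(Ns)`; the solver brackets expansively around that initializer and uses
Brent's method (relative tolerance 1e-10) rather than Newton steps, for
robustness near the regime boundary. The transcription of the steady-state
condition is this package's own; the in-repo guard rails are agreement with
the asymptote within 15% at the reference parameters (N=1e6, U=1e-3,
s=1e-2, where q = 8.76 vs 8.0) and monotonicity of the lead-derived outputs
in each of `N`, `U`, `s`. The sweep rate `2 s ln(Ns)/ln^2(s/U)` is *not*
monotone in `s` near the `s/U >= 3` boundary and is excluded from the
monotonicity guarantees.

## Empirical pipeline

Input is a genotype x environment x pot cohort table (seeds planted ->
seedlings retained -> adults -> seeds produced). Per environment:

**Survival.** Numerators and denominators are pooled across pots (the
minimum-variance binomial estimator for equal-design replicates). The
denominator is seeds planted at high density (seed-to-adult scope) and
retained seedlings at low density (seedling-to-adult scope — thinning makes
seed-stage deaths uninformative there). Genotypes with zero denominators
are excluded with a logged warning.

**Raw proportion of selective deaths.**
`sum_i n_i max(r_best - r_i, 0) / sum_i n_i (1 - r_i)`: the share of
observed deaths that would have been avoided had every pot carried the best
genotype. Zero total deaths makes the quantity undefined and raises rather
than returning 0. Ties for best genotype report the lexicographically first
label.

**Winner's-curse adjustment.** The maximum of hundreds of noisy binomial
rates overstates the best genotype's true rate. The default `"beta"`
strategy *deconvolves then evaluates*:

1. Tarone's score test for binomial overdispersion, at a deliberately
   stringent one-sided critical value of 3.09 (~0.1%): unless genotype
   heterogeneity is detectable, the true rates are treated as a single
   pooled value and the adjusted proportion is exactly 0. The stringency is
   an asymmetric-loss choice — a false heterogeneity call propagates into
   the max-based proportion at roughly ten times the spurious fitted
   spread, while any biologically meaningful spread in designs of hundreds
   of genotypes yields test statistics far above any conventional
   threshold.
2. Otherwise the true rates are modelled as `c * Beta(a,b)`, with `(a,b)`
   matched to the observed mean and to the observed variance minus the
   unbiased binomial sampling variance (`E[r(1-r)/(n-1)] = pq/n`). The
   scale `c` is *not* fitted — the likelihood is nearly flat in it while
   the expected maximum is highly sensitive to it — but anchored at a known
   bound: the pooled germination fraction when the denominator is planted
   seeds (no seed can reach adulthood without germinating), 1 otherwise.
3. `B` cohorts of true rates are drawn from the empirical-Bayes posterior
   (prior from step 2, binomial likelihood at each genotype's counts,
   sampled on a fine grid since the scaled likelihood breaks conjugacy).
   The adjusted best rate and adjusted proportion are the simulation means
   of the per-cohort maximum and proportion, clipped into `[0, raw]`.

A `"point"` strategy retains the simpler one-step parametric bootstrap
(resample at the point estimates, subtract the incremental inflation of the
maximum); it under-corrects by construction and is kept for comparison and
as the slot where an alternative published correction can be installed.
Additive bias subtraction was rejected during design because it cannot
absorb dataset-level fluctuations of the raw maximum: a single
all-survivors genotype pins the raw proportion at 1 regardless of the
subtracted bias.

**Fecundity gate.** Selection on fecundity is only reported if a
permutation test (>= 1000 free permutations of genotype labels across pots)
rejects homogeneity of per-survivor seed counts. The statistic is the
*survivor-weighted* among-genotype variance of pooled seeds-per-survivor:
pot means have variance proportional to 1/survivors, and the unweighted
variance statistic proved anti-conservative on null data because survival
differences induce exactly that heteroskedasticity. When the test is not
significant at `alpha` (add-one p-value, so `alpha = 1` disables the gate),
fecundity selective deaths are zero; otherwise they are
`N_i (b_best - b_i)`.

**Reproductive excess.** The observed stage occupancies parameterize an
annual-plant cycle — adults -> seeds (fecundity `b`, pooled) -> dispersal
(assumed survival `d`) -> establishment (observed seedlings per planted
seed) -> adulthood (observed per-genotype survival) — and the life-history
module's best-genotype-mode excess is evaluated per pot at each end of the
assumed dispersal range (default 0.03–0.3, a 10-fold span: such
experiments carry no dispersal information). Seedling-stage excess is
capped by the pot design (1 per pot at low density, 30 at high). Genotypes
observed with zero survivors are floored at a negligible rate of 1e-9 so
the cycle's positivity invariant holds; the floor cannot affect
best-genotype-mode results.

## Synthetic data generator

The generator emulates the factorial common-garden design the pipeline
targets: 517 homozygous genotypes, 2 locations x 2 water levels x 2
densities, 30 seeds per pot at high density, 10 seeds sown and thinned to 1
seedling at low density, 1 pot per genotype per environment by default.
True seedling-to-adult survival per genotype is drawn from a
water-dependent beta prior — Beta(20, 5) (benign, mean 0.8) for high water,
Beta(2, 5) (adverse, mean 0.29) for low water — shared across locations so
a genotype keeps its identity. Germination is nonselective at rate 0.75, so
the seed-to-adult truth is 0.75 x the beta draw; this two-stage structure
is what makes the germination fraction a legitimate known scale for the
deconvolution. Per-survivor seed counts are gamma-Poisson with mean 2000
(an annual plant producing thousands of seeds) and shape 4 (CV 0.5 across
survivors); genotype fecundity differences default to zero, matching the
empirical finding the fecundity gate encodes. Optional location/density
multipliers default to 1; turning them on changes the truth family to a
beta scaled by an *unobservable* constant and measurably degrades the
winner's-curse correction — a deliberate realism/testability trade-off.

Alongside the table the generator emits a truth record: per-environment
true rates, the proportion of deaths that would be selective under them,
and the reproductive excesses implied by the expected stage occupancies.

**What passing tests do and do not show.** The generator reproduces the
*statistical structure* the pipeline assumes — binomial survival around
beta-distributed genotype rates, overdispersed fecundity, design
denominators — so the tests validate estimator correctness, calibration of
the null adjustment, and directional environment contrasts. They do not
show that real cohorts satisfy those assumptions: real data have spatial
block effects, pot-level survival correlation, germination differences
among genotypes, and seed-count measurement error, none of which are
simulated. One directional claim deserves a caveat: the adverse arm shows a
*higher* proportion of selective deaths than the benign arm robustly on the
seed-to-adult (high-density) scope, but on the raw seedling-to-adult scope
the two beta priors give statistically indistinguishable (even slightly
reversed) orderings, because the benign prior's mean near 1 shrinks the
death denominator `1 - r` as fast as it shrinks the spread. Environment
contrasts are therefore asserted on the high-density scope.

## Statistical performance, as measured by the suite

* Null calibration: with 517 genotypes sharing one survival rate at n=30,
  the adjusted proportion is exactly 0 (the raw proportion, pure winner's
  curse, is ~0.7).
* Recovery: on the full design with 10 pots per genotype (n=300), the mean
  signed error of the adjusted proportion across the four high-density
  environments is ~0.015. Single environments fluctuate with sd ~0.025,
  dominated by the realization noise of the truth itself (the maximum of
  517 beta draws has sd ~0.02–0.04 in proportion units), so per-environment
  agreement beyond that is not attainable by any estimator and is not
  asserted.
* The fecundity gate shows no false positives across 12 null environments
  and p ~ 0.001 against a genotype with 3x fecundity.

## Known limitations

* The sweep-cost integrator is deterministic; drift, interference, and
  fixation probabilities are out of scope.
* The lead solver implements a specific transcription of the steady-state
  condition; alternative correction terms of the same asymptotic order
  would shift `q` by a few percent within the guard-rail band.
* Low-density cohorts with a single pot per genotype have Bernoulli
  denominators; overdispersion is then undetectable and the adjusted
  proportion conservatively collapses to 0. Replication (pots) is what
  buys power, not seeds per pot.
* `N_min` with density-dependent callables uses the baseline-trajectory
  evaluation; strongly nonlinear density responses evaluated far from
  baseline are outside the counterfactual's intended range.
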