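"""Empirical pipeline: survival estimation, selective-death proportions,
winner's-curse adjustment, fecundity gate, reproductive excess, end-to-end."""

import math

import numpy as np
import pandas as pd
import pytest

from costsel import (
    CohortTable,
    DomainError,
    PipelineConfig,
    UndefinedResultError,
    ValidationError,
    adjust_extreme_value,
    empirical_reproductive_excess,
    estimate_survival,
    fecundity_gate,
    proportion_selective_deaths,
    run_all,
)
from costsel.io import dump_json
from costsel.synthetic import SyntheticConfig, generate


class TestCohortTable:
    def test_stage_ordering_enforced(self):
        df = pd.DataFrame(
            {
                "genotype": ["A"],
                "environment": ["e_high_density"],
                "pot": ["p1"],
                "seeds_planted": [30],
                "seedlings_retained": [10],
                "adults": [12],
                "seeds_produced": [0],
            }
        )
        with pytest.raises(ValidationError):
            CohortTable(df, {"e_high_density": "high"})

    def test_low_density_thinning_enforced(self):
        df = pd.DataFrame(
            {
                "genotype": ["A"],
                "environment": ["e"],
                "pot": ["p1"],
                "seeds_planted": [10],
                "seedlings_retained": [3],
                "adults": [1],
                "seeds_produced": [5],
            }
        )
        with pytest.raises(ValidationError):
            CohortTable(df, {"e": "low"})


class TestEstimateSurvival:
    def test_pools_over_pots(self, worked_table):
        est = estimate_survival(worked_table, "toy_low_density")
        assert est.transition_scope == "seedling_to_adult"
        assert est.table.loc["A", "rate"] == pytest.approx(0.9)
        assert est.table.loc["B", "rate"] == pytest.approx(0.5)
        assert est.best_genotype == "A"

    def test_high_density_uses_planted_seeds(self, small_dataset):
        env = "madrid_high_water_high_density"
        est = estimate_survival(small_dataset.table, env)
        sub = small_dataset.table.subset(env)
        g0 = est.table.index[0]
        rows = sub[sub["genotype"] == g0]
        assert est.table.loc[g0, "denominator"] == rows["seeds_planted"].sum()

    def test_missing_environment_rejected(self, worked_table):
        with pytest.raises(DomainError):
            estimate_survival(worked_table, "nowhere")


class TestProportionSelectiveDeaths:
    def test_equal_rates_mean_zero(self):
        assert proportion_selective_deaths([0.4, 0.4, 0.4], [50, 50, 50]) == 0.0

    def test_perfect_best_genotype_makes_all_deaths_selective(self):
        assert proportion_selective_deaths([1.0, 0.3], [100, 100]) == pytest.approx(1.0)

    def test_worked_example(self):
        assert proportion_selective_deaths([0.9, 0.5], [100, 100]) == pytest.approx(2 / 3)

    def test_label_symmetric(self):
        a = proportion_selective_deaths([0.9, 0.5], [100, 100])
        b = proportion_selective_deaths([0.5, 0.9], [100, 100])
        assert a == b

    def test_no_deaths_is_undefined_not_zero(self):
        with pytest.raises(UndefinedResultError):
            proportion_selective_deaths([1.0, 1.0], [30, 30])

    def test_single_genotype_rejected(self):
        with pytest.raises(DomainError):
            proportion_selective_deaths([0.5], [30])


class TestAdjustExtremeValue:
    def test_null_adjusts_to_zero(self, rng):
        # shared true rate: the raw proportion is pure winner's curse and
        # the adjustment should remove essentially all of it
        r = rng.binomial(30, 0.7, 200) / 30
        n = np.full(200, 30.0)
        adj = adjust_extreme_value(r, n, B=500, seed=0)
        assert adj.prop_raw > 0.3
        assert adj.prop_adjusted <= 0.05
        assert adj.r_best_adjusted <= adj.r_best_raw

    def test_deterministic_given_seed(self, rng):
        r = rng.binomial(30, 0.6, 100) / 30
        n = np.full(100, 30.0)
        a = adjust_extreme_value(r, n, B=200, seed=42)
        b = adjust_extreme_value(r, n, B=200, seed=42)
        assert a == b

    def test_single_genotype_passthrough(self):
        adj = adjust_extreme_value([0.6], [30], B=200, seed=0)
        assert adj.inflation == 0.0
        assert adj.r_best_adjusted == adj.r_best_raw

    def test_large_samples_need_no_adjustment(self, rng):
        # with huge denominators the estimates are nearly exact, so the
        # adjusted proportion stays close to the raw one
        true = rng.beta(2, 5, 150)
        n = np.full(150, 100000.0)
        r = rng.binomial(100000, true, 150) / 100000
        adj = adjust_extreme_value(r, n, B=300, seed=1)
        assert adj.prop_adjusted == pytest.approx(adj.prop_raw, abs=0.02)

    def test_adjusted_never_exceeds_raw(self, rng):
        true = rng.beta(2, 2, 80)
        n = np.full(80, 25.0)
        r = rng.binomial(25, true, 80) / 25
        for strategy in ("beta", "point"):
            adj = adjust_extreme_value(r, n, B=300, seed=2, strategy=strategy)
            assert 0.0 <= adj.prop_adjusted <= adj.prop_raw <= 1.0

    def test_too_few_replicates_rejected(self):
        with pytest.raises(DomainError):
            adjust_extreme_value([0.5, 0.6], [30, 30], B=50)

    def test_no_deaths_passthrough(self):
        adj = adjust_extreme_value([1.0, 1.0], [30, 30], B=200, seed=0)
        assert adj.inflation == 0.0
        assert math.isnan(adj.prop_adjusted)


class TestFecundityGate:
    def _table(self, seeds_by_genotype, rng):
        rows = []
        for g, mean in seeds_by_genotype.items():
            for pot in range(12):
                adults = int(rng.integers(3, 8))
                rows.append(
                    {
                        "genotype": g,
                        "environment": "e_high_density",
                        "pot": f"p{pot}",
                        "seeds_planted": 30,
                        "seedlings_retained": 20,
                        "adults": adults,
                        "seeds_produced": int(rng.poisson(mean * adults)),
                    }
                )
        return CohortTable(pd.DataFrame(rows), {"e_high_density": "high"})

    def test_homogeneous_fecundity_not_significant(self, rng):
        table = self._table({g: 50.0 for g in "ABCDEF"}, rng)
        res = fecundity_gate(table, "e_high_density", seed=0)
        assert not res.significant
        assert res.total_deaths == 0.0

    def test_shifted_genotype_detected(self, rng):
        means = {g: 50.0 for g in "ABCDEF"}
        means["A"] = 150.0
        table = self._table(means, rng)
        res = fecundity_gate(table, "e_high_density", seed=0)
        assert res.significant
        assert res.total_deaths > 0
        assert res.deaths["A"] == 0.0  # the best genotype loses nothing

    def test_alpha_one_disables_the_gate(self, rng):
        table = self._table({g: 50.0 for g in "ABCD"}, rng)
        res = fecundity_gate(table, "e_high_density", alpha=1.0, seed=0)
        assert res.significant

    def test_no_survivors_skipped_with_note(self):
        df = pd.DataFrame(
            {
                "genotype": ["A", "B"],
                "environment": ["e"] * 2,
                "pot": ["p1", "p1"],
                "seeds_planted": [10, 10],
                "seedlings_retained": [1, 1],
                "adults": [0, 0],
                "seeds_produced": [0, 0],
            }
        )
        table = CohortTable(df, {"e": "low"})
        res = fecundity_gate(table, "e", seed=0)
        assert not res.significant
        assert res.note == "no survivors"


class TestEmpiricalReproductiveExcess:
    def _toy_table(self):
        # 2 genotypes x 10 low-density pots; survival {1.0, 0.5}; every
        # adult produces exactly 10 seeds
        rows = []
        for g, survivors in (("A", 10), ("B", 5)):
            for pot in range(10):
                adults = 1 if pot < survivors else 0
                rows.append(
                    {
                        "genotype": g,
                        "environment": "toy",
                        "pot": f"p{pot}",
                        "seeds_planted": 10,
                        "seedlings_retained": 1,
                        "adults": adults,
                        "seeds_produced": 10 * adults,
                    }
                )
        return CohortTable(pd.DataFrame(rows), {"toy": "low"})

    def test_hand_worked_toy(self):
        # per pot: adults A=0.75, seedlings S=1, establishment g=0.1,
        # fecundity b=10, best survival r=1. With dispersal d:
        #   RE_seeds     = b*A - A/(d*g*r)  = 7.5 - 0.75/(0.1 d)
        #   RE_seedlings = min(r*S - S/(b*d*g), 1) = min(1 - 1/d, 1)
        table = self._toy_table()
        res = empirical_reproductive_excess(table, "toy", dispersal_survival=(0.5, 1.0))
        assert res.re_seeds[0] == pytest.approx(7.5 - 0.75 / 0.05)
        assert res.re_seeds[1] == pytest.approx(7.5 - 0.75 / 0.1)
        assert res.re_seedlings[0] == pytest.approx(1 - 1 / 0.5)
        assert res.re_seedlings[1] == pytest.approx(0.0)

    def test_degenerate_range_has_zero_length(self):
        table = self._toy_table()
        res = empirical_reproductive_excess(table, "toy", dispersal_survival=(0.2, 0.2))
        assert res.re_seeds[0] == res.re_seeds[1]

    def test_doubling_fecundity_doubles_gross_seed_output(self):
        table = self._toy_table()
        res1 = empirical_reproductive_excess(table, "toy", dispersal_survival=(0.5, 0.5))
        doubled = table.data.copy()
        doubled["seeds_produced"] *= 2
        res2 = empirical_reproductive_excess(
            CohortTable(doubled, table.density_map), "toy", dispersal_survival=(0.5, 0.5)
        )
        # linearity in k_j N_j: the gross output term doubles at fixed N_min
        nmin = 0.75 / 0.05
        assert res2.re_seeds[0] + nmin == pytest.approx(2 * (res1.re_seeds[0] + nmin))

    def test_seedling_excess_respects_pot_caps(self, small_dataset):
        for env in small_dataset.table.environments:
            res = empirical_reproductive_excess(small_dataset.table, env)
            cap = 1.0 if small_dataset.table.density(env) == "low" else 30.0
            assert res.re_seedlings[1] <= cap + 1e-9

    def test_invalid_dispersal_range_rejected(self):
        with pytest.raises(DomainError):
            empirical_reproductive_excess(self._toy_table(), "toy", (0.5, 0.1))


@pytest.fixture(scope="module")
def dataset():
    return generate(SyntheticConfig(n_genotypes=120, pots_per_genotype=4, seed=5))


@pytest.fixture(scope="module")
def report(dataset):
    cfg = PipelineConfig(seed=3, bootstrap_replicates=300)
    return run_all(dataset.table, cfg)


class TestRunAll:
    def test_every_environment_summarized(self, dataset, report):
        assert not report.errors
        assert len(report.summaries) == 8
        assert {s.environment for s in report.summaries} == set(
            dataset.table.environments
        )

    def test_summary_invariants(self, report):
        for s in report.summaries:
            assert 0.0 <= s.prop_selective_adjusted <= s.prop_selective_raw <= 1.0
            assert s.re_seedlings[0] <= s.re_seedlings[1]
            cap = 1.0 if s.transition_scope == "seedling_to_adult" else 30.0
            assert s.re_seedlings[1] <= cap + 1e-9

    def test_reruns_are_byte_identical(self, dataset):
        cfg = PipelineConfig(seed=3, bootstrap_replicates=300)
        a = dump_json(run_all(dataset.table, cfg).to_dict())
        b = dump_json(run_all(dataset.table, cfg).to_dict())
        assert a == b

    def test_benign_environments_have_more_excess_fewer_selective_deaths(self, report):
        # high water is the benign arm: larger seed excess, and a smaller
        # share of selective deaths on the seed-to-adult (high-density) scope
        by_env = {s.environment: s for s in report.summaries}
        for loc in ("madrid", "tuebingen"):
            benign = by_env[f"{loc}_high_water_high_density"]
            adverse = by_env[f"{loc}_low_water_high_density"]
            assert benign.re_seeds[0] > adverse.re_seeds[0]
            assert (
                benign.prop_selective_adjusted < adverse.prop_selective_adjusted
            )

    def test_tidy_frame_shape(self, report):
        frame = report.to_frame()
        assert len(frame) == 16  # 8 environments x 2 transitions
        assert set(frame["transition"]) == {"seeds_produced", "seedlings_to_adult"}
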