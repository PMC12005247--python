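"""Life cycles: N_min solvers, reproductive excess, bottlenecks, and
per-transition selective deaths."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from costsel import (
    BottleneckSpec,
    DomainError,
    LifeCycle,
    Transition,
    ValidationError,
    selective_deaths_per_transition,
    wf_identities,
)


def two_transition_cycle(k_birth=2.0, k_death=0.5, n0=100.0):
    """Monomorphic birth/death cycle with product k_birth * k_death."""
    return LifeCycle(
        [
            Transition("birth", "reproduction", {"A": k_birth}),
            Transition("death", "survival", {"A": k_death}),
        ],
        n0,
        {"A": 1.0},
    )


def mixed_cycle():
    """Two genotypes, unequal non-focal product {2, 1} at frequencies 1/2."""
    return LifeCycle(
        [
            Transition("focal", "survival", {"A": 1.0, "B": 1.0}),
            Transition("other", "reproduction", {"A": 2.0, "B": 1.0}),
        ],
        120.0,
        {"A": 0.5, "B": 0.5},
    )


class TestValidation:
    def test_survival_multiplier_above_one_rejected(self):
        with pytest.raises(ValidationError):
            Transition("bad", "survival", {"A": 1.2})

    def test_frequencies_must_sum_to_one(self):
        t = Transition("t", "survival", {"A": 0.5})
        with pytest.raises(ValidationError):
            LifeCycle([t], 10.0, {"A": 0.7})

    def test_genotype_sets_must_match(self):
        t = Transition("t", "survival", {"A": 0.5})
        with pytest.raises(ValidationError):
            LifeCycle([t], 10.0, {"A": 0.5, "B": 0.5})

    def test_bottleneck_weights_must_sum_to_one(self):
        t = Transition("t", "survival", {"A": 0.5})
        with pytest.raises(ValidationError):
            BottleneckSpec(10, [(0.5, [t])])


class TestNminSolvers:
    def test_no_compensation_elsewhere_means_nmin_equals_nj(self):
        cycle = LifeCycle(
            [
                Transition("focal", "survival", {"A": 0.5}),
                Transition("other", "survival", {"A": 1.0}),
            ],
            200.0,
            {"A": 1.0},
        )
        assert cycle.solve_nmin(0, "actual") == pytest.approx(200.0)

    def test_actual_mode_mixes_genotype_products(self):
        # non-focal products {2, 1} at equal frequency: N_min = N_j / 1.5
        assert mixed_cycle().solve_nmin(0, "actual") == pytest.approx(120 / 1.5)

    def test_single_genotype_product(self):
        cycle = LifeCycle(
            [
                Transition("focal", "survival", {"A": 1.0}),
                Transition("other", "reproduction", {"A": 4.0}),
            ],
            100.0,
            {"A": 1.0},
        )
        assert cycle.solve_nmin(0, "actual") == pytest.approx(25.0)

    def test_best_mode_uses_best_genotype(self):
        cycle = mixed_cycle()
        assert cycle.solve_nmin(0, "best") == pytest.approx(120 / 2)
        assert cycle.solve_nmin(0, "best") < cycle.solve_nmin(0, "actual")

    def test_monomorphic_modes_agree(self):
        cycle = two_transition_cycle()
        assert cycle.solve_nmin(0, "best") == pytest.approx(
            cycle.solve_nmin(0, "actual")
        )

    def test_dilution_regrowth_needs_over_hundred(self):
        # 1:100 dilution elsewhere in the cycle forces N_min > 100 N
        cycle = LifeCycle(
            [
                Transition("stationary", "survival", {"A": 1.0}),
                Transition("dilution", "survival", {"A": 0.01}),
            ],
            1000.0,
            {"A": 1.0},
        )
        assert cycle.solve_nmin(0, "best") == pytest.approx(1000.0 / 0.01)

    @given(
        k_a=st.floats(0.1, 0.99),
        k_b=st.floats(0.1, 0.99),
        f=st.floats(0.01, 0.99),
    )
    @settings(max_examples=60, deadline=None)
    def test_best_mode_never_exceeds_actual_mode(self, k_a, k_b, f):
        cycle = LifeCycle(
            [
                Transition("focal", "reproduction", {"A": 2.0, "B": 2.0}),
                Transition("other", "survival", {"A": k_a, "B": k_b}),
            ],
            50.0,
            {"A": f, "B": 1.0 - f},
        )
        assert cycle.solve_nmin(0, "best") <= cycle.solve_nmin(0, "actual") + 1e-9


class TestReproductiveExcess:
    def test_exactly_replacing_cycle_has_zero_excess(self):
        cycle = two_transition_cycle(2.0, 0.5)
        for focal in (0, 1):
            assert cycle.reproductive_excess(focal, "best") == pytest.approx(0.0)

    def test_reproduction_focal_worked_example(self):
        # k_j = 2, N_j = 100, downstream best product 1 -> RE = 200 - 100
        cycle = LifeCycle(
            [
                Transition("birth", "reproduction", {"A": 2.0}),
                Transition("death", "survival", {"A": 1.0}),
            ],
            100.0,
            {"A": 1.0},
        )
        assert cycle.reproductive_excess(0, "best") == pytest.approx(100.0)

    def test_survival_focal_worked_example(self):
        # k_j = 0.5, N_j = 100, downstream product 4 -> RE = 50 - 25
        cycle = LifeCycle(
            [
                Transition("death", "survival", {"A": 0.5}),
                Transition("birth", "reproduction", {"A": 4.0}),
            ],
            100.0,
            {"A": 1.0},
        )
        assert cycle.reproductive_excess(0, "best") == pytest.approx(25.0)

    def test_round_trip_identity(self):
        # starting the best-genotype cycle from N_min at the post-focal
        # boundary returns exactly N_j at the focal stage next cycle
        cycle = LifeCycle(
            [
                Transition("a", "reproduction", {"A": 3.0}),
                Transition("b", "survival", {"A": 0.4}),
                Transition("c", "survival", {"A": 0.9}),
            ],
            500.0,
            {"A": 1.0},
        )
        focal = 1
        state = cycle.simulate_cycle()
        nmin = cycle.solve_nmin(focal, "best")
        downstream = nmin
        for x in (2, 0):  # transitions after the focal one, wrapping
            downstream *= cycle.transitions[x].k["A"]
        assert downstream == pytest.approx(state.stage_sizes[focal], rel=1e-12)

    def test_excess_monotone_in_nonfocal_k(self):
        lo = LifeCycle(
            [
                Transition("f", "reproduction", {"A": 2.0}),
                Transition("g", "survival", {"A": 0.5}),
            ],
            100.0,
            {"A": 1.0},
        ).reproductive_excess(0, "best")
        hi = LifeCycle(
            [
                Transition("f", "reproduction", {"A": 2.0}),
                Transition("g", "survival", {"A": 0.9}),
            ],
            100.0,
            {"A": 1.0},
        ).reproductive_excess(0, "best")
        assert hi > lo

    def test_density_dependent_k_evaluated_at_baseline(self):
        # a ceiling-regulated birth rate: k depends on the stage size
        def ceiling(stage_size, freqs):
            return min(2.0, 1000.0 / stage_size)

        cycle = LifeCycle(
            [
                Transition("birth", "reproduction", {"A": ceiling}),
                Transition("death", "survival", {"A": 0.5}),
            ],
            800.0,
            {"A": 1.0},
        )
        # baseline k at N=800 is 1000/800 = 1.25; focal output 1000
        assert cycle.reproductive_excess(0, "best") == pytest.approx(
            1000.0 - 800.0 / 0.5
        )


class TestBottleneck:
    def test_point_mass_path_reduces_to_fixed_cycle(self):
        cycle = two_transition_cycle(2.0, 0.5, n0=100.0)
        state = cycle.simulate_cycle()
        spec = BottleneckSpec(
            n_bot=state.stage_sizes[0],
            paths=[(1.0, [cycle.transitions[1]])],
        )
        assert cycle.reproductive_excess_bottleneck(0, spec) == pytest.approx(
            cycle.reproductive_excess(0, "best"), rel=1e-12
        )

    def test_expectation_over_paths(self):
        # two equiprobable paths with best products {1, 3}: N_min = N_bot / 2
        t1 = Transition("p1", "survival", {"A": 1.0})
        t3 = Transition("p3", "reproduction", {"A": 3.0})
        cycle = LifeCycle(
            [Transition("focal", "reproduction", {"A": 2.0})], 100.0, {"A": 1.0}
        )
        spec = BottleneckSpec(n_bot=60.0, paths=[(0.5, [t1]), (0.5, [t3])])
        assert cycle.reproductive_excess_bottleneck(0, spec) == pytest.approx(
            200.0 - 30.0
        )

    def test_tiny_bottleneck_with_huge_products_frees_everything(self):
        big = Transition("grow", "reproduction", {"A": 1e9})
        cycle = LifeCycle(
            [Transition("focal", "reproduction", {"A": 2.0})], 100.0, {"A": 1.0}
        )
        spec = BottleneckSpec(n_bot=1.0, paths=[(1.0, [big])])
        assert cycle.reproductive_excess_bottleneck(0, spec) == pytest.approx(
            200.0, abs=1e-6
        )


class TestWrightFisherIdentities:
    def test_stationary_monomorphic(self):
        res = wf_identities(1.0, 1.0, 1000)
        assert res.selective_deaths_per_capita == 0.0
        assert res.reproductive_excess_per_capita == pytest.approx(0.0)

    def test_worked_example(self):
        res = wf_identities(1.0, 1.1, 1000)
        assert res.selective_deaths_per_capita == pytest.approx(0.1)
        assert res.n_min == pytest.approx(1000 / 1.1)
        assert res.reproductive_excess_per_capita == pytest.approx(1 - 1 / 1.1)

    def test_fast_growing_monomorphic(self):
        res = wf_identities(2.0, 2.0, 100)
        assert res.selective_deaths_per_capita == 0.0
        assert res.reproductive_excess_per_capita == pytest.approx(1.5)

    def test_mean_cannot_exceed_best(self):
        with pytest.raises(DomainError):
            wf_identities(1.2, 1.0, 100)


class TestSelectiveDeathsPerTransition:
    def test_monomorphic_zero(self):
        t = Transition("s", "survival", {"A": 0.8})
        per, total = selective_deaths_per_transition(t, {"A": 100.0})
        assert total == 0.0

    def test_survival_worked_example(self):
        t = Transition("s", "survival", {"A": 0.9, "B": 0.6})
        per, total = selective_deaths_per_transition(t, {"A": 100.0, "B": 100.0})
        assert per == {"A": 0.0, "B": pytest.approx(30.0)}
        assert total == pytest.approx(30.0)

    def test_antagonistic_pleiotropy_never_cancels(self):
        # A best at transition 1, B best at transition 2: both transitions
        # contribute positive selective deaths even with static frequencies
        t1 = Transition("early", "survival", {"A": 0.9, "B": 0.6})
        t2 = Transition("late", "survival", {"A": 0.6, "B": 0.9})
        counts = {"A": 50.0, "B": 50.0}
        _, d1 = selective_deaths_per_transition(t1, counts)
        _, d2 = selective_deaths_per_transition(t2, counts)
        assert d1 > 0 and d2 > 0

    def test_empty_rejected(self):
        t = Transition("s", "survival", {"A": 0.8})
        with pytest.raises(DomainError):
            selective_deaths_per_transition(t, {})
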