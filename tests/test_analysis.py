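"""Derived statistics: arrival order, valleys, contingency, fitness walk."""

import itertools
import warnings

import numpy as np
import pytest

from nashpath import (
    AlleleUniverse,
    AllelicFormation,
    AllelicState,
    GameValidationError,
    arrival_order_probability,
    compare_contingency,
    contingency_universe,
    ensemble_endpoints,
    find_fitness_valleys,
    fitness_walk_statistics,
    hamming_distance,
    matrix_game,
    near_vertex_state,
    random_game,
    run_pdmp,
)
from nashpath.dynamics import DynamicsConfig
from nashpath.examples import rmf_modular_universe
from nashpath.games import CommonInterestsGame, enumerate_genotypes

from conftest import nash_scan

CFG = DynamicsConfig(max_samples=32)


class TestArrivalOrder:
    def test_closed_form_values(self):
        assert arrival_order_probability(1.0, 1.0) == pytest.approx(0.5)
        assert arrival_order_probability(3.0, 1.0) == pytest.approx(0.75)
        pa = arrival_order_probability(0.7, 1.3)
        pb = arrival_order_probability(1.3, 0.7)
        assert pa + pb == pytest.approx(1.0)

    def test_monte_carlo_agrees_with_closed_form(self):
        rng = np.random.default_rng(12)
        n = 100_000
        for lam_a, lam_b in [(1.0, 1.0), (3.0, 1.0), (0.2, 5.0)]:
            p = arrival_order_probability(lam_a, lam_b)
            phat = arrival_order_probability(
                lam_a, lam_b, method="monte_carlo", n=n, rng=rng
            )
            se = np.sqrt(p * (1 - p) / n)
            assert abs(phat - p) < 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            arrival_order_probability(-1.0, 1.0)
        with pytest.raises(ValueError):
            arrival_order_probability(1.0, 1.0, method="monte_carlo", n=0)

    def test_hamming(self):
        assert hamming_distance(("a1", "b1"), ("a2", "b2")) == 2
        assert hamming_distance(("a1", "b1"), ("a1", "b1")) == 0
        assert hamming_distance(("a1", "b1"), ("a1", "b2")) == 1
        with pytest.raises(GameValidationError):
            hamming_distance(("a1",), ("a1", "b1"))


def valley_scan(game):
    """Independent exhaustive valley detector used as the oracle."""
    maxima = nash_scan(game, strict=True)
    fit = game.to_dict()
    pairs = []
    for g1, g2 in itertools.product(maxima, repeat=2):
        if fit[g2] <= fit[g1]:
            continue
        d = sum(x != y for x, y in zip(g1, g2))
        if d < 2:
            continue
        if any(
            g3 not in (g1, g2)
            and sum(x != y for x, y in zip(g1, g3))
            + sum(x != y for x, y in zip(g3, g2))
            == d
            for g3 in maxima
        ):
            continue
        pairs.append((g1, g2))
    return pairs


class TestValleys:
    def test_valley_of_the_2x2_landscape(self, m1):
        (pair,) = find_fitness_valleys(m1)
        assert (pair.g1, pair.g2) == (("a1", "b1"), ("a2", "b2"))
        assert pair.hamming == 2
        assert (pair.w_g1, pair.w_g2) == (1.0, 2.0)

    def test_valley_of_the_3x2_landscape(self, m3):
        (pair,) = find_fitness_valleys(m3)
        assert (pair.g1, pair.g2) == (("a2", "b2"), ("a3", "b1"))

    def test_single_peak_has_no_valley(self, m2):
        assert find_fitness_valleys(m2) == []
        single = CommonInterestsGame(
            AllelicFormation(("L",), (("x",),)), {("x",): 1.0}
        )
        assert find_fitness_valleys(single) == []

    def test_matches_exhaustive_scan_on_random_games(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            shape = rng.integers(2, 4, size=rng.integers(2, 4))
            game = random_game(rng, shape)
            got = [(p.g1, p.g2) for p in find_fitness_valleys(game)]
            assert got == valley_scan(game)


class TestContingency:
    def test_mutation_order_changes_the_outcome(self):
        uni = contingency_universe()
        base = matrix_game(1).formation
        report = compare_contingency(
            uni, base, ("a1", "b1"),
            [("B", "b3"), ("A", "a3")], [("A", "a3"), ("B", "b3")],
            config=CFG,
        )
        assert report.result_a.final_eq == ("a2", "b2")
        assert report.result_a.final_fitness == pytest.approx(2.0)
        assert report.result_b.final_eq == ("a3", "b1")
        assert report.result_b.final_fitness == pytest.approx(3.0)
        assert report.divergent

    def test_identical_orders_agree_and_are_idempotent(self):
        uni = contingency_universe()
        base = matrix_game(1).formation
        order = [("B", "b3"), ("A", "a3")]
        r1 = compare_contingency(uni, base, ("a1", "b1"), order, order, config=CFG)
        r2 = compare_contingency(uni, base, ("a1", "b1"), order, order, config=CFG)
        assert not r1.divergent
        assert r1.to_dict() == r2.to_dict()

    def test_orders_must_be_permutations(self):
        uni = contingency_universe()
        base = matrix_game(1).formation
        with pytest.raises(GameValidationError):
            compare_contingency(
                uni, base, ("a1", "b1"), [("B", "b3")], [("A", "a3")], config=CFG
            )

    def test_near_vertex_state_is_interior(self, m1):
        q = near_vertex_state(m1.formation, ("a1", "b1"), 0.01)
        assert q.is_interior()
        assert q.frequency("A", "a1") == pytest.approx(0.995)


def _two_branch_universe(gain=0.5):
    """One deleterious and one beneficial novel allele, equally likely.

    The conditional distribution of the next equilibrium fitness is a
    symmetric two-point law {w, w + gain}, so the one-step conditional
    variance is (gain/2)**2.
    """
    formation = AllelicFormation(("A", "B"), (("a1", "ax"), ("b1", "by")))
    master = CommonInterestsGame(
        formation,
        {
            ("a1", "b1"): 1.0,
            ("ax", "b1"): 0.5,
            ("a1", "by"): 1.0 + gain,
            ("ax", "by"): 0.6,
        },
    )
    return AlleleUniverse(master)


def _quasi_static_run(universe, start_formation, seed):
    game = universe.restrict(start_formation)
    q0 = near_vertex_state(start_formation, game.max_genotype, 0.01)
    return run_pdmp(
        universe, q0, 1e-3, seed=seed, n_events=None, quasi_static=True, config=CFG
    )


class TestFitnessWalk:
    def test_deterministic_universe_has_flat_walk(self):
        """With a single possible continuation at every step, Y always equals
        its conditional expectation: Z stays at zero and F = 0."""
        formation = AllelicFormation(("L", "M"), (("x1", "x2", "x3"), ("y1",)))
        master = CommonInterestsGame(
            formation,
            {("x1", "y1"): 1.0, ("x2", "y1"): 1.5, ("x3", "y1"): 2.0},
        )
        uni = AlleleUniverse(master)
        start = AllelicFormation(("L", "M"), (("x1", "x2"), ("y1",)))
        runs = [_quasi_static_run(uni, start, s) for s in (0, 1)]
        walks = fitness_walk_statistics(runs, v=0.0, estimator="exact")
        for w in walks:
            np.testing.assert_allclose(w.Z, 0.0, atol=1e-12)
            assert w.F == 0.0

    def test_two_branch_universe_conditional_variance(self):
        gain = 0.5
        uni = _two_branch_universe(gain)
        start = AllelicFormation(("A", "B"), (("a1",), ("b1",)))
        runs = [_quasi_static_run(uni, start, s) for s in (0, 1)]
        walks = fitness_walk_statistics(runs, v=1e9, estimator="exact")
        for w in walks:
            assert w.sigma2[1] == pytest.approx((gain / 2) ** 2, abs=1e-9)
            assert w.excluded  # budget unreachable by construction

    def test_branching_estimator_needs_siblings(self):
        uni = _two_branch_universe()
        start = AllelicFormation(("A", "B"), (("a1",), ("b1",)))
        runs = [_quasi_static_run(uni, start, s) for s in (0, 1)]
        with pytest.raises(ValueError):
            fitness_walk_statistics(runs, v=0.1, estimator="branching", B=1)

    def test_unreachable_budget_warns_and_excludes(self):
        uni = _two_branch_universe()
        start = AllelicFormation(("A", "B"), (("a1",), ("b1",)))
        runs = [_quasi_static_run(uni, start, s) for s in (0, 1)]
        with pytest.warns(UserWarning, match="excluded"):
            walks = fitness_walk_statistics(runs, v=100.0, estimator="exact")
        assert all(w.excluded for w in walks)
        assert ensemble_endpoints(walks).size == 0

    def test_martingale_increments_center_on_zero(self):
        """Averaged over an ensemble, the centered increments have mean zero
        up to estimator noise."""
        rng = np.random.default_rng(123)
        runs = []
        for _ in range(30):
            uni, start = rmf_modular_universe(
                rng, 6, (2,), additive_effect=1.2, jitter=0.15
            )
            state = AllelicState.uniform(start)
            runs.append(
                run_pdmp(uni, state, 1e-3, rng=rng, n_events=None,
                         quasi_static=True, config=CFG)
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            walks = fitness_walk_statistics(runs, v=1e9, estimator="exact", rng=rng)
        incs = np.concatenate([np.diff(w.Z) for w in walks])
        se = incs.std(ddof=1) / np.sqrt(len(incs))
        assert abs(incs.mean()) < 4 * max(se, 1e-12)

    def test_branching_estimator_is_consistent_with_exact(self):
        rng = np.random.default_rng(5)
        uni, start = rmf_modular_universe(rng, 4, (2,), additive_effect=1.2,
                                          jitter=0.15)
        state = AllelicState.uniform(start)
        runs = [
            run_pdmp(uni, state, 1e-3, rng=rng, n_events=None,
                     quasi_static=True, config=CFG)
            for _ in range(2)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            exact = fitness_walk_statistics(runs, v=1e9, estimator="exact")
            br = fitness_walk_statistics(
                runs, v=1e9, estimator="branching", B=4000,
                rng=np.random.default_rng(0),
            )
        for we, wb in zip(exact, br):
            np.testing.assert_allclose(wb.Z, we.Z, atol=0.05)
            np.testing.assert_allclose(wb.sigma2, we.sigma2, atol=0.02)
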