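"""Static game layer: enumeration, fitness functionals, Nash equilibria."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nashpath import (
    AllelicFormation,
    AllelicState,
    GameValidationError,
    GenotypeState,
    allelic_state_of,
    enumerate_genotypes,
    marginal_fitness,
    marginal_fitness_vector,
    matrix_game,
    mean_fitness_allelic,
    mean_fitness_genotypic,
    pure_nash_equilibria,
    random_game,
    standing_variation_state,
)
from nashpath.games import CommonInterestsGame, DimensionMismatchError

from conftest import nash_scan, product_state


class TestFormation:
    def test_enumeration_is_lexicographic_product(self, m1):
        assert enumerate_genotypes(m1.formation) == [
            ("a1", "b1"), ("a1", "b2"), ("a2", "b1"), ("a2", "b2"),
        ]

    def test_degenerate_and_rectangular_counts(self, m2):
        single = AllelicFormation(("L",), (("x",),))
        assert enumerate_genotypes(single) == [("x",)]
        assert len(enumerate_genotypes(m2.formation)) == 6

    @pytest.mark.parametrize(
        "loci,alleles",
        [
            ((), ()),
            (("A",), ((),)),
            (("A", "A"), (("a1",), ("a2",))),
            (("A",), (("a1", "a1"),)),
            (("A", "B"), (("a1",),)),
        ],
    )
    def test_invalid_formations_rejected(self, loci, alleles):
        with pytest.raises(GameValidationError):
            AllelicFormation(loci, alleles)


class TestGameConstruction:
    def test_fitness_must_be_total_and_positive(self, m1):
        f = m1.formation
        good = m1.to_dict()
        missing = dict(good)
        del missing[("a2", "b2")]
        with pytest.raises(GameValidationError, match="missing"):
            CommonInterestsGame(f, missing)
        extra = dict(good)
        extra[("a9", "b9")] = 1.0
        with pytest.raises(GameValidationError, match="unknown"):
            CommonInterestsGame(f, extra)
        bad = dict(good)
        bad[("a1", "b2")] = -0.5
        with pytest.raises(GameValidationError, match="positive"):
            CommonInterestsGame(f, bad)

    def test_genericity_flag(self, m1):
        tied = np.array([[1.0, 2.0], [2.0, 0.5]])
        with pytest.raises(GameValidationError, match="unique"):
            CommonInterestsGame(m1.formation, tied, require_generic=True)


class TestStates:
    def test_state_simplex_validation(self, m1):
        with pytest.raises(GameValidationError):
            GenotypeState(m1.formation, [0.5, 0.5, 0.5, 0.5])
        with pytest.raises(GameValidationError):
            AllelicState(m1.formation, ([0.5, 0.5], [1.2, -0.2]))
        with pytest.raises(DimensionMismatchError):
            GenotypeState(m1.formation, [1.0, 0.0])

    def test_marginals_of_printed_initial_state(self, m1):
        p = standing_variation_state(m1.formation, ("a1", "b1"), 0.01)
        q = allelic_state_of(m1.formation, p)
        np.testing.assert_allclose(q.per_locus[0], [0.995, 0.005])
        np.testing.assert_allclose(q.per_locus[1], [0.995, 0.005])

    def test_monomorphic_and_uniform_marginals(self, m1):
        p = GenotypeState.monomorphic(m1.formation, ("a1", "b1"))
        q = allelic_state_of(m1.formation, p)
        np.testing.assert_allclose(q.per_locus[0], [1, 0])
        u = allelic_state_of(m1.formation, GenotypeState(m1.formation, [0.25] * 4))
        np.testing.assert_allclose(u.per_locus[0], [0.5, 0.5])


class TestFitnessFunctionals:
    def test_genotypic_mean_fitness_values(self, m1):
        vertex = GenotypeState.monomorphic(m1.formation, ("a2", "b2"))
        assert mean_fitness_genotypic(m1, vertex) == pytest.approx(2.0)
        uniform = GenotypeState(m1.formation, [0.25] * 4)
        assert mean_fitness_genotypic(m1, uniform) == pytest.approx(0.875)

    def test_allelic_mean_fitness_values(self, m1):
        vertex = AllelicState.vertex(m1.formation, ("a2", "b2"))
        assert mean_fitness_allelic(m1, vertex) == pytest.approx(2.0)
        assert mean_fitness_allelic(
            m1, AllelicState.uniform(m1.formation)
        ) == pytest.approx(0.875)

    def test_marginal_fitness_values(self, m1):
        q = AllelicState(m1.formation, ([1.0, 0.0], [1.0, 0.0]))
        assert marginal_fitness(m1, q, "A", "a1") == pytest.approx(1.0)
        q = AllelicState(m1.formation, ([0.5, 0.5], [0.5, 0.5]))
        assert marginal_fitness(m1, q, "A", "a1") == pytest.approx(0.625)

    def test_one_locus_marginal_is_fitness(self):
        game = CommonInterestsGame(
            AllelicFormation(("L",), (("x", "y"),)), {("x",): 1.5, ("y",): 0.7}
        )
        q = AllelicState(game.formation, ([0.3, 0.7],))
        assert marginal_fitness(game, q, "L", "x") == pytest.approx(1.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_product_consistency_and_envelope(self, seed):
        """w(q) equals the genotypic mean of the product distribution, and
        the frequency-weighted marginals reproduce w(q) at every locus."""
        rng = np.random.default_rng(seed)
        shape = rng.integers(2, 4, size=rng.integers(1, 4))
        game = random_game(rng, shape)
        q = AllelicState(
            game.formation, tuple(rng.dirichlet(np.ones(s)) for s in shape)
        )
        w = mean_fitness_allelic(game, q)
        p = product_state(q.per_locus)
        assert mean_fitness_genotypic(game, p) == pytest.approx(w, abs=1e-12)
        for locus, v in zip(game.formation.loci, q.per_locus):
            marg = marginal_fitness_vector(game, q, locus)
            assert float(v @ marg) == pytest.approx(w, abs=1e-10)

    def test_marginal_is_partial_derivative(self):
        rng = np.random.default_rng(3)
        game = random_game(rng, (2, 3))
        q = [rng.dirichlet(np.ones(2)), rng.dirichlet(np.ones(3))]
        h = 1e-6
        for i, locus in enumerate(game.formation.loci):
            for j in range(len(q[i])):
                up = [v.copy() for v in q]
                dn = [v.copy() for v in q]
                up[i][j] += h
                dn[i][j] -= h
                fd = (
                    mean_fitness_allelic(game, up) - mean_fitness_allelic(game, dn)
                ) / (2 * h)
                got = marginal_fitness_vector(game, q, locus)[j]
                assert got == pytest.approx(fd, abs=1e-7)


class TestPureNash:
    def test_fixture_games_match_deviation_scan(self, m1, m2, m3, m4):
        for game in (m1, m2, m3, m4):
            for strict in (True, False):
                assert pure_nash_equilibria(game, strict) == nash_scan(game, strict)

    def test_printed_equilibrium_sets(self, m1, m2, m3, m4):
        assert pure_nash_equilibria(m1) == [("a1", "b1"), ("a2", "b2")]
        assert pure_nash_equilibria(m2) == [("a2", "b2")]
        assert set(pure_nash_equilibria(m3)) == {("a2", "b2"), ("a3", "b1")}
        assert set(pure_nash_equilibria(m4)) == {("a2", "b2"), ("a3", "b1")}
        # the fitness tie at w(a1,b3)=w(a2,b3)=3/2 makes (a1,b3) weak only
        assert ("a1", "b3") in pure_nash_equilibria(m4, strict=False)
        assert ("a1", "b3") not in pure_nash_equilibria(m4, strict=True)

    def test_single_locus_argmax(self):
        game = CommonInterestsGame(
            AllelicFormation(("L",), (("x", "y", "z"),)),
            {("x",): 1.0, ("y",): 2.5, ("z",): 0.3},
        )
        assert pure_nash_equilibria(game) == [("y",)]

    def test_random_games_match_deviation_scan(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            shape = rng.integers(2, 4, size=rng.integers(1, 4))
            game = random_game(rng, shape)
            assert pure_nash_equilibria(game, True) == nash_scan(game, True)
            assert pure_nash_equilibria(game, False) == nash_scan(game, False)
            assert game.max_genotype in pure_nash_equilibria(game, True)
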