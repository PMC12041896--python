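"""Common-interests games played by loci.

The central modelling object: each locus of a haploid genome is a player,
its currently available alleles are its pure actions, and every player
receives the same payoff — the fitness ``w_g`` of the genotype ``g`` they
jointly form.  Because all interests coincide, the mean population fitness
is a potential function of the game, and both the asexual (genotypic) and
sexual (allelic, linkage-equilibrium) selection dynamics ascend it.

This module holds the static layer: allelic formations, genotype
enumeration, population states on the simplex / multi-simplex, fitness
functionals, and brute-force pure Nash enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GameValidationError",
    "DimensionMismatchError",
    "Genotype",
    "AllelicFormation",
    "CommonInterestsGame",
    "GenotypeState",
    "AllelicState",
    "enumerate_genotypes",
    "mean_fitness_genotypic",
    "mean_fitness_allelic",
    "marginal_fitness",
    "marginal_fitness_vector",
    "allelic_state_of",
    "pure_nash_equilibria",
]

#: tolerance for "sums to one" checks on probability vectors
SIMPLEX_ATOL = 1e-12

Genotype = tuple  # tuple of allele labels, one per locus, in locus order


class GameValidationError(ValueError):
    """A formation, game, or state violates a structural invariant."""


class DimensionMismatchError(GameValidationError):
    """A state vector does not match the game's genotype/allele space."""


@dataclass(frozen=True)
class AllelicFormation:
    """The profile of currently available allele sets, one per locus.

    Parameters
    ----------
    loci
        Ordered locus labels; length ``m >= 1``.
    alleles
        One ordered tuple of allele labels per locus, aligned with ``loci``.
        Labels must be unique within a locus.
    """

    loci: tuple
    alleles: tuple

    def __post_init__(self):
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "alleles", tuple(tuple(a) for a in self.alleles))
        if len(self.loci) < 1:
            raise GameValidationError("a formation needs at least one locus")
        if len(set(self.loci)) != len(self.loci):
            raise GameValidationError("locus labels must be unique")
        if len(self.alleles) != len(self.loci):
            raise GameValidationError(
                f"got {len(self.alleles)} allele sets for {len(self.loci)} loci"
            )
        for locus, pool in zip(self.loci, self.alleles):
            if len(pool) < 1:
                raise GameValidationError(f"locus {locus!r} has no alleles")
            if len(set(pool)) != len(pool):
                raise GameValidationError(f"duplicate allele labels at locus {locus!r}")

    @classmethod
    def from_dict(cls, loci: Sequence, alleles_by_locus: Mapping) -> "AllelicFormation":
        return cls(tuple(loci), tuple(tuple(alleles_by_locus[l]) for l in loci))

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def shape(self) -> tuple:
        """Number of alleles per locus; the shape of the fitness tensor."""
        return tuple(len(a) for a in self.alleles)

    def locus_index(self, locus) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise GameValidationError(f"unknown locus {locus!r}") from None

    def allele_index(self, locus, allele) -> int:
        i = self.locus_index(locus)
        try:
            return self.alleles[i].index(allele)
        except ValueError:
            raise GameValidationError(
                f"unknown allele {allele!r} at locus {locus!r}"
            ) from None

    def alleles_at(self, locus) -> tuple:
        return self.alleles[self.locus_index(locus)]

    def has_allele(self, locus, allele) -> bool:
        return allele in self.alleles[self.locus_index(locus)]

    def genotype_index(self, genotype: Genotype) -> tuple:
        """Multi-index of ``genotype`` in the fitness tensor."""
        if len(genotype) != self.n_loci:
            raise DimensionMismatchError(
                f"genotype {genotype!r} has {len(genotype)} entries for "
                f"{self.n_loci} loci"
            )
        return tuple(
            self.allele_index(locus, a) for locus, a in zip(self.loci, genotype)
        )

    def contains(self, other: "AllelicFormation") -> bool:
        """True if ``other`` uses the same loci and a subset of the alleles."""
        return other.loci == self.loci and all(
            set(o) <= set(s) for o, s in zip(other.alleles, self.alleles)
        )


def enumerate_genotypes(formation: AllelicFormation) -> list:
    """All genotypes of ``formation`` in lexicographic product order.

    The order is the C-order of the fitness tensor: the last locus varies
    fastest.  Every probability vector over genotypes is indexed by this
    ordering.
    """
    return [tuple(g) for g in itertools.product(*formation.alleles)]


class CommonInterestsGame:
    """A formation together with a strictly positive fitness for every genotype.

    Parameters
    ----------
    formation
        The allelic formation (the action sets of the loci-as-players).
    fitness
        Either a mapping ``genotype tuple -> fitness`` that is total over the
        formation's product space, or an ndarray of shape ``formation.shape``.
    require_generic
        If true, assert that the fitness-maximal genotype is unique.
    """

    def __init__(self, formation: AllelicFormation, fitness, *, require_generic=False):
        self.formation = formation
        shape = formation.shape
        if isinstance(fitness, np.ndarray):
            if fitness.shape != shape:
                raise GameValidationError(
                    f"fitness tensor shape {fitness.shape} != formation shape {shape}"
                )
            tensor = np.asarray(fitness, dtype=float).copy()
        else:
            fitness = dict(fitness)
            genotypes = enumerate_genotypes(formation)
            missing = [g for g in genotypes if g not in fitness]
            if missing:
                raise GameValidationError(f"missing fitness for genotype {missing[0]}")
            extra = set(fitness) - set(genotypes)
            if extra:
                raise GameValidationError(
                    f"fitness given for unknown genotype {sorted(extra)[0]}"
                )
            tensor = np.empty(shape, dtype=float)
            for g in genotypes:
                tensor[formation.genotype_index(g)] = fitness[g]
        if not np.all(np.isfinite(tensor)):
            raise GameValidationError("fitness values must be finite")
        if np.any(tensor <= 0):
            bad = enumerate_genotypes(formation)[int(np.argmax((tensor <= 0).ravel()))]
            raise GameValidationError(
                f"fitness must be strictly positive; genotype {bad} has "
                f"w={tensor[formation.genotype_index(bad)]}"
            )
        self.tensor = tensor
        self.tensor.setflags(write=False)
        if require_generic and np.sum(tensor == tensor.max()) != 1:
            raise GameValidationError("fitness maximum is not unique")

    # -- basic accessors ---------------------------------------------------

    def fitness_of(self, genotype: Genotype) -> float:
        return float(self.tensor[self.formation.genotype_index(genotype)])

    def genotypes(self) -> list:
        return enumerate_genotypes(self.formation)

    @property
    def max_genotype(self) -> Genotype:
        idx = np.unravel_index(int(np.argmax(self.tensor)), self.tensor.shape)
        return tuple(
            self.formation.alleles[i][j] for i, j in enumerate(idx)
        )

    def to_dict(self) -> dict:
        """Mapping genotype tuple -> fitness, in enumeration order."""
        return {g: self.fitness_of(g) for g in self.genotypes()}

    def __eq__(self, other):
        return (
            isinstance(other, CommonInterestsGame)
            and self.formation == other.formation
            and np.array_equal(self.tensor, other.tensor)
        )

    def __repr__(self):
        return (
            f"CommonInterestsGame(loci={self.formation.loci}, "
            f"shape={self.formation.shape})"
        )


def _check_simplex(vec: np.ndarray, what: str):
    if np.any(vec < 0):
        raise GameValidationError(f"{what} has negative entries")
    if abs(float(vec.sum()) - 1.0) > SIMPLEX_ATOL:
        raise GameValidationError(
            f"{what} sums to {vec.sum()!r}, not 1 within {SIMPLEX_ATOL}"
        )


@dataclass
class GenotypeState:
    """A probability distribution over the genotypes of a formation.

    ``weights`` is indexed by :func:`enumerate_genotypes` order.  The state
    of an asexually reproducing population.
    """

    formation: AllelicFormation
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = int(np.prod(self.formation.shape))
        if self.weights.shape != (n,):
            raise DimensionMismatchError(
                f"state has {self.weights.shape} weights for {n} genotypes"
            )
        _check_simplex(self.weights, "genotype state")

    @classmethod
    def monomorphic(cls, formation: AllelicFormation, genotype: Genotype):
        w = np.zeros(int(np.prod(formation.shape)))
        w[int(np.ravel_multi_index(formation.genotype_index(genotype), formation.shape))] = 1.0
        return cls(formation, w)

    @classmethod
    def from_dict(cls, formation: AllelicFormation, weights: Mapping):
        w = np.zeros(int(np.prod(formation.shape)))
        for g, x in weights.items():
            w[int(np.ravel_multi_index(formation.genotype_index(tuple(g)), formation.shape))] = x
        return cls(formation, w)

    def weight_of(self, genotype: Genotype) -> float:
        i = int(np.ravel_multi_index(
            self.formation.genotype_index(genotype), self.formation.shape))
        return float(self.weights[i])

    @property
    def leading_genotype(self) -> Genotype:
        return enumerate_genotypes(self.formation)[int(np.argmax(self.weights))]


@dataclass
class AllelicState:
    """One probability vector per locus: the multi-simplex state ``q``.

    The state of a sexually reproducing population at linkage equilibrium —
    alleles are assumed uncorrelated across loci, so ``q`` induces the
    product distribution over genotypes.
    """

    formation: AllelicFormation
    per_locus: tuple

    def __post_init__(self):
        vecs = []
        for locus, pool, v in zip(
            self.formation.loci, self.formation.alleles, self.per_locus
        ):
            v = np.asarray(v, dtype=float)
            if v.shape != (len(pool),):
                raise DimensionMismatchError(
                    f"locus {locus!r} has {len(pool)} alleles but state vector "
                    f"of shape {v.shape}"
                )
            _check_simplex(v, f"allelic state at locus {locus!r}")
            vecs.append(v)
        if len(self.per_locus) != self.formation.n_loci:
            raise DimensionMismatchError("one vector per locus required")
        object.__setattr__(self, "per_locus", tuple(vecs))

    @classmethod
    def vertex(cls, formation: AllelicFormation, genotype: Genotype):
        """The pure (monomorphic) state at ``genotype``'s corner."""
        idx = formation.genotype_index(genotype)
        vecs = []
        for k, pool in zip(idx, formation.alleles):
            v = np.zeros(len(pool))
            v[k] = 1.0
            vecs.append(v)
        return cls(formation, tuple(vecs))

    @classmethod
    def uniform(cls, formation: AllelicFormation):
        return cls(
            formation,
            tuple(np.full(len(p), 1.0 / len(p)) for p in formation.alleles),
        )

    @classmethod
    def from_dict(cls, formation: AllelicFormation, freqs: Mapping):
        """Build from ``{locus: {allele: frequency}}``."""
        vecs = []
        for locus, pool in zip(formation.loci, formation.alleles):
            d = freqs[locus]
            vecs.append(np.array([d.get(a, 0.0) for a in pool], dtype=float))
        return cls(formation, tuple(vecs))

    def frequency(self, locus, allele) -> float:
        i = self.formation.locus_index(locus)
        j = self.formation.allele_index(locus, allele)
        return float(self.per_locus[i][j])

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.per_locus)

    @classmethod
    def from_concatenated(cls, formation: AllelicFormation, flat: np.ndarray):
        return cls(formation, tuple(_split(formation, flat)))

    def is_interior(self) -> bool:
        return all(np.all(v > 0) for v in self.per_locus)

    @property
    def leading_genotype(self) -> Genotype:
        return tuple(
            pool[int(np.argmax(v))]
            for pool, v in zip(self.formation.alleles, self.per_locus)
        )


def _split(formation: AllelicFormation, flat: np.ndarray) -> list:
    return _split_sizes(flat, formation.shape)


def _split_sizes(flat: np.ndarray, sizes) -> list:
    out, k = [], 0
    for n in sizes:
        out.append(np.asarray(flat[k : k + n], dtype=float))
        k += n
    return out


# -- fitness functionals ---------------------------------------------------


def mean_fitness_genotypic(game: CommonInterestsGame, p) -> float:
    """Mean population fitness ``w(p) = sum_g w_g p_g`` of a genotypic state."""
    weights = p.weights if isinstance(p, GenotypeState) else np.asarray(p, float)
    flat = game.tensor.ravel()
    if weights.shape != flat.shape:
        raise DimensionMismatchError(
            f"state length {weights.shape} != {flat.shape} genotypes"
        )
    return float(flat @ weights)


def _locus_vectors(game: CommonInterestsGame, q) -> list:
    if isinstance(q, AllelicState):
        if q.formation != game.formation:
            raise DimensionMismatchError("allelic state is for a different formation")
        return list(q.per_locus)
    vecs = [np.asarray(v, dtype=float) for v in q]
    for v, n in zip(vecs, game.formation.shape):
        if v.shape != (n,):
            raise DimensionMismatchError("per-locus vector length mismatch")
    if len(vecs) != game.formation.n_loci:
        raise DimensionMismatchError("one vector per locus required")
    return vecs


def _mean_fitness_raw(tensor: np.ndarray, vecs: Sequence[np.ndarray]) -> float:
    t = tensor
    for v in reversed(vecs):
        t = t @ v
    return float(t)


def _marginal_raw(tensor: np.ndarray, vecs: Sequence[np.ndarray], i: int) -> np.ndarray:
    """Contract every locus except ``i``; returns the marginal-fitness vector."""
    t = tensor
    for j in range(len(vecs) - 1, -1, -1):
        if j != i:
            t = np.tensordot(t, vecs[j], axes=([j], [0]))
    return np.asarray(t, dtype=float)


def _all_marginals(tensor: np.ndarray, vecs: Sequence[np.ndarray]) -> list:
    """Marginal-fitness vectors for every locus at once.

    Uses prefix/suffix outer products of the per-locus vectors so the whole
    family costs O(m) small matrix-vector contractions instead of m separate
    full contractions — this is the inner loop of the sexual dynamics.
    """
    m = len(vecs)
    if m == 1:
        return [np.asarray(tensor, dtype=float)]
    shape = tensor.shape
    pre = [np.ones(1)]
    for v in vecs[:-1]:
        pre.append(np.multiply.outer(pre[-1], v).ravel())
    suf = [np.ones(1)]
    for v in vecs[:0:-1]:
        suf.append(np.multiply.outer(v, suf[-1]).ravel())
    suf.reverse()  # suf[i] = flattened outer product of vecs[i+1:]
    out = []
    left = 1
    for i in range(m):
        n_i = shape[i]
        right = tensor.size // (left * n_i)
        block = tensor.reshape(left, n_i * right)
        t1 = pre[i] @ block
        out.append(t1.reshape(n_i, right) @ suf[i])
        left *= n_i
    return out


def mean_fitness_allelic(game: CommonInterestsGame, q) -> float:
    """Mean fitness ``w(q) = sum_g w_g prod_i q^i_{g_i}`` of an allelic state.

    Multilinear in the per-locus frequency vectors; equals the genotypic mean
    fitness of the product distribution induced by ``q``.
    """
    return _mean_fitness_raw(game.tensor, _locus_vectors(game, q))


def marginal_fitness_vector(game: CommonInterestsGame, q, locus) -> np.ndarray:
    """Marginal fitness of every allele at ``locus``: ``w_{-i}(q | a)``.

    Component ``a`` is the mean fitness of genotypes forced to carry ``a`` at
    ``locus``, with the other loci drawn from ``q``; equals the partial
    derivative of ``w(q)`` in the coordinate ``q^i_a``.
    """
    vecs = _locus_vectors(game, q)
    i = game.formation.locus_index(locus)
    return _marginal_raw(game.tensor, vecs, i)


def marginal_fitness(game: CommonInterestsGame, q, locus, allele) -> float:
    vec = marginal_fitness_vector(game, q, locus)
    return float(vec[game.formation.allele_index(locus, allele)])


def allelic_state_of(game_or_formation, p: GenotypeState) -> AllelicState:
    """The allelic marginals of a genotypic state.

    ``q^i_a`` is the total weight of genotypes carrying allele ``a`` at
    locus ``i``.
    """
    formation = (
        game_or_formation.formation
        if isinstance(game_or_formation, CommonInterestsGame)
        else game_or_formation
    )
    if p.formation != formation:
        raise DimensionMismatchError("genotype state is for a different formation")
    cube = p.weights.reshape(formation.shape)
    m = formation.n_loci
    vecs = tuple(
        np.asarray(cube.sum(axis=tuple(j for j in range(m) if j != i)), dtype=float)
        for i in range(m)
    )
    return AllelicState(formation, vecs)


# -- pure Nash equilibria --------------------------------------------------


def _nash_mask(tensor: np.ndarray, strict: bool) -> np.ndarray:
    mask = np.ones(tensor.shape, dtype=bool)
    for axis in range(tensor.ndim):
        line_max = tensor.max(axis=axis, keepdims=True)
        is_max = tensor == line_max
        if strict:
            unique = is_max.sum(axis=axis, keepdims=True) == 1
            mask &= is_max & unique
        else:
            mask &= is_max
    return mask


def pure_nash_equilibria(game: CommonInterestsGame, strict: bool = True) -> list:
    """All pure Nash genotypes, in lexicographic enumeration order.

    A genotype is a pure Nash equilibrium iff no single-locus allele
    substitution raises fitness (``strict``: every substitution strictly
    lowers it).  These are the local maxima of the fitness landscape under
    single-mutation moves, and — by the convergence theory of the potential
    dynamics — the only possible monomorphic limits of the sexual flow.
    """
    mask = _nash_mask(game.tensor, strict)
    genotypes = enumerate_genotypes(game.formation)
    flat = mask.ravel()
    return [g for g, ok in zip(genotypes, flat) if ok]
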