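"""Worked landscapes and scenarios, plus random generic games.

Four small two-locus landscapes (parameterised by a deleterious off-peak
fitness ``0 < delta < 1``) exercise the whole theory:

* ``matrix_game(1)`` — a 2x2 fitness valley: peaks at (a1,b1) with w=1 and
  (a2,b2) with w=2, separated by ``delta`` cells.
* ``matrix_game(2)`` — the valley game after a novel allele ``b3`` arrives
  at locus B.  (a1,b1) stops being a Nash equilibrium, so a sexual
  population near it crosses to (a2,b2) after a *single* mutation.  The
  (a1,b3) cell is 3/2 and (a2,b3) is 7/4.
* ``matrix_game(3)`` — the valley game after ``a3`` arrives at locus A
  instead; the population moves to (a3,b1) with w=3.
* ``matrix_game(4)`` — both novel alleles present (3x3); contains the
  fitness tie w(a1,b3) = w(a2,b3) = 3/2 that makes (a1,b3) a weak but not
  strict equilibrium.

``scenario(...)`` packages the three replayable stories (valley crossing,
blocked sweep, contingency) with their initial states, scripted mutations
and expected outcomes; ``random_game`` supplies generic instances for
property tests.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dynamics import DEFAULT_CONFIG, DynamicsConfig, integrate_to_equilibrium
from .formations import AlleleUniverse, expand_formation
from .games import (
    AllelicFormation,
    CommonInterestsGame,
    GameValidationError,
    Genotype,
    GenotypeState,
    allelic_state_of,
    enumerate_genotypes,
)
from .pdmp import classify_event, embed_genotype_state, embed_state

__all__ = [
    "matrix_game",
    "contingency_universe",
    "valley_universe",
    "standing_variation_state",
    "Scenario",
    "ScriptStep",
    "scenario",
    "ReplayResult",
    "replay_scenario",
    "random_game",
    "random_universe",
    "modular_universe",
    "rmf_modular_universe",
]

_A2 = ("a1", "a2")
_A3 = ("a1", "a2", "a3")
_B2 = ("b1", "b2")
_B3 = ("b1", "b2", "b3")


def _check_delta(delta: float):
    if not 0 < delta < 1:
        raise GameValidationError(
            "delta must lie in (0, 1): off-peak genotypes are deleterious but viable"
        )


def matrix_game(n: int, delta: float = 0.25) -> CommonInterestsGame:
    """One of the four worked two-locus landscapes (see module docstring)."""
    _check_delta(delta)
    d = float(delta)
    if n == 1:
        rows = [[1.0, d], [d, 2.0]]
        alleles = (_A2, _B2)
    elif n == 2:
        rows = [[1.0, d, 1.5], [d, 2.0, 1.75]]
        alleles = (_A2, _B3)
    elif n == 3:
        rows = [[1.0, d], [d, 2.0], [3.0, d]]
        alleles = (_A3, _B2)
    elif n == 4:
        rows = [[1.0, d, 1.5], [d, 2.0, 1.5], [3.0, d, d]]
        alleles = (_A3, _B3)
    else:
        raise ValueError("n must be 1, 2, 3 or 4")
    formation = AllelicFormation(("A", "B"), alleles)
    return CommonInterestsGame(formation, np.array(rows))


def valley_universe(delta: float = 0.25) -> AlleleUniverse:
    """Pools {a1,a2} x {b1,b2,b3}: the single-mutation valley-crossing world."""
    return AlleleUniverse(matrix_game(2, delta))


def contingency_universe(delta: float = 0.25) -> AlleleUniverse:
    """Pools {a1,a2,a3} x {b1,b2,b3} containing every worked landscape.

    The master keeps (a2,b3) = 7/4 so that restricting to {a1,a2} x
    {b1,b2,b3} reproduces ``matrix_game(2)`` exactly; the cell value plays
    no role in any equilibrium set or scenario outcome.
    """
    _check_delta(delta)
    d = float(delta)
    rows = [[1.0, d, 1.5], [d, 2.0, 1.75], [3.0, d, d]]
    formation = AllelicFormation(("A", "B"), (_A3, _B3))
    return AlleleUniverse(CommonInterestsGame(formation, np.array(rows)))


def standing_variation_state(
    formation: AllelicFormation, genotype: Genotype, eps: float = 0.01
) -> GenotypeState:
    """Weight ``1 - eps`` on ``genotype``, ``eps`` split over its one-step
    neighbours.

    The canonical near-monomorphic initial condition: a dominant type plus
    trace single-mutant variants (on a 2x2 formation these are exactly the
    two off-diagonal genotypes at ``eps/2`` each), and weight zero on the
    double mutant.
    """
    if not 0 < eps < 1:
        raise ValueError("eps must lie strictly between 0 and 1")
    neighbors = [
        g
        for g in enumerate_genotypes(formation)
        if sum(x != y for x, y in zip(g, genotype)) == 1
    ]
    weights = {genotype: 1.0 - eps}
    for g in neighbors:
        weights[g] = eps / len(neighbors)
    return GenotypeState.from_dict(formation, weights)


@dataclass(frozen=True)
class ScriptStep:
    """One scripted mutation: a novel allele or a non-novel genotype event."""

    kind: str  # "novel" or "non_novel"
    locus: Optional[object] = None
    allele: Optional[object] = None
    source: Optional[Genotype] = None  # genotype the mutating individual carried
    target: Optional[Genotype] = None  # genotype it mutates into


@dataclass
class Scenario:
    name: str
    universe: AlleleUniverse
    base_formation: AllelicFormation
    initial_state: GenotypeState
    script: tuple
    expected: dict  # qualitative outcome labels per mode

    def to_config(self) -> dict:
        """YAML-ready run configuration describing this scenario."""
        return {
            "name": self.name,
            "base_formation": {
                str(l): [str(a) for a in pool]
                for l, pool in zip(
                    self.base_formation.loci, self.base_formation.alleles
                )
            },
            "initial_weights": {
                ",".join(g): float(w)
                for g, w in zip(
                    enumerate_genotypes(self.base_formation),
                    self.initial_state.weights,
                )
                if w > 0
            },
            "script": [
                {
                    "kind": s.kind,
                    "locus": None if s.locus is None else str(s.locus),
                    "allele": None if s.allele is None else str(s.allele),
                    "source": list(s.source) if s.source else None,
                    "target": list(s.target) if s.target else None,
                }
                for s in self.script
            ],
            "expected": {m: list(g) for m, g in self.expected.items()},
        }

    def __post_init__(self):
        self.universe.validate(self.base_formation)
        f = self.base_formation
        for step in self.script:
            if step.kind == "novel":
                f = expand_formation(f, step.locus, step.allele)
            elif step.kind != "non_novel":
                raise ValueError(f"unknown script step kind {step.kind!r}")
        self.universe.validate(f)


def scenario(name: str, order: Optional[str] = None, delta: float = 0.25) -> Scenario:
    """A packaged replayable story.

    ``valley_crossing``
        One novel ``b3`` mutation on the 2x2 valley game.  Sexual outcome:
        the population crosses the valley to (a2,b2) while b3 itself goes
        extinct; asexual outcome: (a1,b3) takes over.
    ``blocked_sweep``
        A non-novel mutation creating an (a2,b2) individual on the same
        game.  Sexual outcome: nothing changes — recombination already
        maintained that genotype at small weight; asexual outcome: (a2,b2)
        sweeps to fixation.
    ``contingency``
        Both novel alleles in one of two orders (``order`` in
        {"b3_first", "a3_first"}); the final equilibrium depends on the
        order ((a2,b2) with w=2 versus (a3,b1) with w=3).
    """
    base = matrix_game(1, delta).formation
    p0 = standing_variation_state(base, ("a1", "b1"), eps=0.01)
    if name == "valley_crossing":
        return Scenario(
            name,
            valley_universe(delta),
            base,
            p0,
            (
                ScriptStep(
                    "novel", "B", "b3", source=("a1", "b1"), target=("a1", "b3")
                ),
            ),
            {"sexual": ("a2", "b2"), "asexual": ("a1", "b3")},
        )
    if name == "blocked_sweep":
        return Scenario(
            name,
            AlleleUniverse(matrix_game(1, delta)),
            base,
            p0,
            (ScriptStep("non_novel", source=("a2", "b1"), target=("a2", "b2")),),
            {"sexual": ("a1", "b1"), "asexual": ("a2", "b2")},
        )
    if name == "contingency":
        if order not in ("b3_first", "a3_first"):
            raise ValueError("contingency needs order='b3_first' or 'a3_first'")
        steps = [
            ScriptStep("novel", "B", "b3", source=("a1", "b1"), target=("a1", "b3")),
            ScriptStep("novel", "A", "a3", source=("a1", "b1"), target=("a3", "b1")),
        ]
        if order == "a3_first":
            steps.reverse()
        return Scenario(
            f"contingency_{order}",
            contingency_universe(delta),
            base,
            p0,
            tuple(steps),
            {"sexual": ("a2", "b2") if order == "b3_first" else ("a3", "b1")},
        )
    raise ValueError(f"unknown scenario {name!r}")


@dataclass
class ReplayResult:
    final_eq: Genotype
    final_fitness: float
    converged: bool
    event_log: list  # (step, classification or "non_novel")
    final_state: object


def replay_scenario(
    sc: Scenario,
    mode: str = "sexual",
    config: DynamicsConfig = DEFAULT_CONFIG,
    eps_mut: float = 1e-3,
    eps_non_novel: float = 1e-6,
) -> ReplayResult:
    """Run a scenario's scripted mutations to their final equilibrium.

    In sexual mode novel alleles are injected at frequency ``eps_mut`` into
    the allelic state and non-novel events change nothing (the product
    population already carries every genotype of the current formation).
    In asexual mode every event moves genotype weight from ``source`` to
    ``target`` (``eps_mut`` for novel mutants, ``eps_non_novel`` for the
    single mutating individual of a non-novel event).
    """
    formation = sc.base_formation
    game = sc.universe.restrict(formation)
    log = []
    if mode == "sexual":
        state = allelic_state_of(formation, sc.initial_state)
    elif mode == "asexual":
        state = sc.initial_state
    else:
        raise ValueError(f"unknown mode {mode!r}")
    # scripted mutations strike the described initial population directly:
    # settling first would erode the trace variants the stories rely on
    eq = state.leading_genotype
    traj = None
    for step in sc.script:
        if step.kind == "novel":
            new_formation = expand_formation(formation, step.locus, step.allele)
            new_game = sc.universe.restrict(new_formation)
            if mode == "sexual":
                log.append((step, classify_event(game, eq, new_game)))
                state = embed_state(state, new_formation, step.locus, step.allele, eps_mut)
            else:
                log.append((step, "novel"))
                state = embed_genotype_state(
                    state, new_formation, step.source, step.target, eps_mut
                )
            formation, game = new_formation, new_game
        else:  # non-novel: the sexual state already carries the genotype
            log.append((step, "non_novel"))
            if mode == "asexual":
                state = embed_genotype_state(
                    state, formation, step.source, step.target, eps_non_novel
                )
        traj = integrate_to_equilibrium(game, state, mode, config)
        state = traj.final_state
        eq = traj.limit
    if traj is None:  # scriptless scenario: just settle the initial state
        traj = integrate_to_equilibrium(game, state, mode, config)
        state = traj.final_state
        eq = traj.limit
    return ReplayResult(eq, game.fitness_of(eq), traj.converged, log, state)


# -- random generic instances ----------------------------------------------


def random_game(
    rng,
    shape: Sequence[int],
    low: float = 0.5,
    high: float = 2.5,
    loci: Optional[Sequence] = None,
) -> CommonInterestsGame:
    """A generic game: i.i.d. Uniform(low, high) fitness, all values distinct.

    Continuity makes ties a measure-zero event; the draw is repeated on the
    (numerically possible) tie so every returned game is generic — a unique
    global maximum and strict local maxima only.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise ValueError("every locus needs at least one allele")
    if loci is None:
        loci = tuple(string.ascii_uppercase[: len(shape)])
    alleles = tuple(
        tuple(f"{str(l).lower()}{j + 1}" for j in range(s)) for l, s in zip(loci, shape)
    )
    formation = AllelicFormation(tuple(loci), alleles)
    while True:
        tensor = rng.uniform(low, high, size=shape)
        if np.unique(tensor).size == tensor.size:
            return CommonInterestsGame(formation, tensor, require_generic=True)


def modular_universe(
    rng,
    n_modules: int,
    module_pool: Sequence[int] = (3, 3),
    module_start: Sequence[int] = (1, 1),
    low: float = 0.5,
    high: float = 1.5,
    value_law: str = "uniform",
    ancestral: str = "first",
) -> tuple:
    """A modular landscape: fitness is a sum of independent multi-locus
    modules.

    Each module is a block of loci with its own random fitness table; the
    total fitness of a genotype is the sum of its module fitnesses (no
    epistasis between modules, full epistasis within).  Modular
    architectures keep novel mutations informative for many steps — every
    module supports its own sequence of equilibrium changes — which makes
    them the natural testbed for statistics that accumulate variance over a
    long mutation path.

    ``value_law`` is either ``"uniform"`` (i.i.d. Uniform(low, high)) or
    ``"grid"`` (an evenly spaced grid over [low, high], randomly permuted:
    selection coefficients are then bounded away from zero and fitness
    jumps have comparable sizes).  ``ancestral`` places the starting
    alleles either at the ``"first"`` pool entries or at the module's
    ``"min"``-fitness cell — an unadapted ancestral configuration in which
    every module still has its whole adaptive walk ahead of it.

    Returns ``(universe, start_formation)``.
    """
    if n_modules < 1:
        raise ValueError("need at least one module")
    shapes = [tuple(int(s) for s in module_pool) for _ in range(n_modules)]
    tables = []
    for s in shapes:
        n_cells = int(np.prod(s))
        if value_law == "uniform":
            table = rng.uniform(low, high, size=s)
        elif value_law == "grid":
            vals = np.linspace(low, high, n_cells)
            table = rng.permutation(vals).reshape(s)
        else:
            raise ValueError(f"unknown value_law {value_law!r}")
        if ancestral == "min":
            # relabel alleles so the module minimum sits at the origin cell
            idx = np.unravel_index(int(np.argmin(table)), s)
            for axis, j in enumerate(idx):
                table = np.swapaxes(table, 0, axis)
                table[[0, j]] = table[[j, 0]]
                table = np.swapaxes(table, 0, axis)
        elif ancestral != "first":
            raise ValueError(f"unknown ancestral {ancestral!r}")
        tables.append(table)
    start_counts = [int(s) for _ in range(n_modules) for s in module_start]
    return _assemble_modules(shapes, tables, start_counts)


def _assemble_modules(shapes, tables, start_counts) -> tuple:
    """Sum per-module tables into one landscape over the concatenated loci."""
    full_shape = tuple(s for shape in shapes for s in shape)
    total = np.zeros(full_shape)
    axis = 0
    for shape, table in zip(shapes, tables):
        bshape = [1] * len(full_shape)
        bshape[axis : axis + len(shape)] = shape
        total = total + table.reshape(bshape)
        axis += len(shape)
    loci = []
    for b, shape in enumerate(shapes):
        for k in range(len(shape)):
            loci.append(f"{string.ascii_uppercase[k]}{b + 1}")
    alleles = tuple(
        tuple(f"{str(l).lower()}.{j + 1}" for j in range(s))
        for l, s in zip(loci, full_shape)
    )
    pools = AllelicFormation(tuple(loci), alleles)
    master = CommonInterestsGame(pools, total)
    start = AllelicFormation(
        pools.loci, tuple(pool[:k] for pool, k in zip(pools.alleles, start_counts))
    )
    return AlleleUniverse(master), start


def rmf_modular_universe(
    rng,
    n_modules: int,
    module_pool: Sequence[int] = (2, 2),
    base: float = 1.0,
    additive_effect: float = 0.6,
    jitter: float = 0.25,
) -> tuple:
    """Modules with rough-Mount-Fuji tables: additive effects plus noise.

    Within each module the cell for allele indices ``(i, j, ...)`` is
    ``base + additive_effect * (i + j + ...) + jitter * U(-1, 1)``: every
    derived allele carries a fixed benefit with idiosyncratic epistatic
    jitter.  Requiring ``additive_effect > 2 * jitter`` keeps every
    substitution beneficial and every selection coefficient bounded away
    from zero, so each novel arrival moves the equilibrium by a comparable,
    slightly random amount — fitness-walk variance accumulates in many
    equal-sized steps instead of a few early records.

    Starts at the all-ancestral (index-0) cell; returns
    ``(universe, start_formation)``.
    """
    if n_modules < 1:
        raise ValueError("need at least one module")
    if not additive_effect > 2 * jitter >= 0:
        raise ValueError("need additive_effect > 2*jitter >= 0")
    shapes = [tuple(int(s) for s in module_pool) for _ in range(n_modules)]
    tables = []
    for s in shapes:
        grid = np.indices(s).sum(axis=0).astype(float)
        table = base + additive_effect * grid + jitter * rng.uniform(-1, 1, size=s)
        if table.min() <= 0:
            raise ValueError("module table not strictly positive; raise base")
        tables.append(table)
    start_counts = [1 for _ in range(n_modules) for _ in module_pool]
    return _assemble_modules(shapes, tables, start_counts)


def random_universe(
    rng,
    pool_shape: Sequence[int],
    start_shape: Sequence[int],
    low: float = 0.5,
    high: float = 2.5,
) -> tuple:
    """A random master landscape plus a starting sub-formation.

    Returns ``(universe, start_formation)`` where the start formation keeps
    the first ``start_shape[i]`` alleles of each pool.
    """
    if len(pool_shape) != len(start_shape) or any(
        s > p or s < 1 for s, p in zip(start_shape, pool_shape)
    ):
        raise ValueError("start_shape must be componentwise within pool_shape")
    master = random_game(rng, pool_shape, low, high)
    pools = master.formation
    start = AllelicFormation(
        pools.loci, tuple(pool[:k] for pool, k in zip(pools.alleles, start_shape))
    )
    return AlleleUniverse(master), start
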