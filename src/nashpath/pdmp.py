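"""The mutation process: deterministic selection punctuated by novel alleles.

Mutations arrive on a Poisson clock with rate ``lam``.  Each arrival picks a
locus uniformly and an allele uniformly from that locus's universe pool.  If
the allele is already present the event is *non-novel* and nothing changes.
Otherwise the allelic formation expands by one allele — a *game-changing*
mutation — the population state is injected into the larger multi-simplex
with the new allele at trace frequency ``eps_mut``, and the flow resumes
under the expanded game.  If the previously occupied equilibrium is no
longer a pure Nash equilibrium of the new game the event is in addition
*Nash-changing*: the population must leave for a new, strictly fitter
equilibrium.  The resulting object is a piecewise-deterministic Markov
process whose state space grows in dimension at random times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dynamics import (
    DEFAULT_CONFIG,
    DynamicsConfig,
    Trajectory,
    integrate_for,
    integrate_to_equilibrium,
)
from .formations import AlleleUniverse, expand_formation
from .games import (
    AllelicFormation,
    AllelicState,
    CommonInterestsGame,
    GameValidationError,
    Genotype,
    GenotypeState,
    enumerate_genotypes,
    pure_nash_equilibria,
)

__all__ = [
    "NON_NOVEL",
    "GAME_CHANGING",
    "NASH_CHANGING",
    "MutationEvent",
    "Segment",
    "PDMPRun",
    "sample_next_event",
    "embed_state",
    "embed_genotype_state",
    "classify_event",
    "run_pdmp",
]

NON_NOVEL = "non_novel"
GAME_CHANGING = "game_changing"
NASH_CHANGING = "nash_changing"


@dataclass
class MutationEvent:
    """One clock arrival with its classification and equilibrium bookkeeping.

    ``pre_eq``/``pre_fitness`` describe the equilibrium occupied just before
    the arrival; ``post_eq``/``post_fitness`` the equilibrium the population
    settles at afterwards (filled once the following segment has run).
    """

    time: float
    locus: object
    allele: object
    classification: str
    pre_eq: Genotype
    pre_fitness: float
    post_eq: Optional[Genotype] = None
    post_fitness: Optional[float] = None


@dataclass
class Segment:
    """A deterministic stretch of flow under one fixed game."""

    game: CommonInterestsGame
    trajectory: Trajectory
    eq: Genotype  # nearest strict pure Nash at segment end
    eq_fitness: float


@dataclass
class PDMPRun:
    """Record of one simulated mutation path."""

    universe: AlleleUniverse
    seed: Optional[int]
    lam: float
    eps_mut: float
    quasi_static: bool
    config: DynamicsConfig
    segments: list = field(default_factory=list)
    events: list = field(default_factory=list)
    final_state: Optional[AllelicState] = None
    exhausted: bool = False

    @property
    def final_formation(self) -> AllelicFormation:
        return self.final_state.formation

    def equilibrium_fitness_series(self) -> list:
        """Equilibrium fitness at the end of every segment, in order."""
        return [s.eq_fitness for s in self.segments]

    def novel_events(self) -> list:
        return [e for e in self.events if e.classification != NON_NOVEL]


def sample_next_event(rng, lam: float, formation: AllelicFormation, universe: AlleleUniverse):
    """Draw the next clock arrival: ``(waiting_time, locus, allele)``.

    The waiting time is Exponential(lam); the locus is uniform over loci;
    the allele is uniform over that locus's full pool, so an already-present
    allele may be drawn (the caller classifies it non-novel).  Returns
    ``None`` once every pool is exhausted — no novel event can ever occur
    again, so the process has reached its terminal game.
    """
    if lam <= 0:
        raise ValueError("mutation rate lam must be positive")
    universe.validate(formation)
    if universe.exhausted(formation):
        return None
    wait = float(rng.exponential(1.0 / lam))
    pools = universe.pools
    eligible = [i for i, pool in enumerate(pools.alleles) if pool]
    i = eligible[int(rng.integers(len(eligible)))]
    pool = pools.alleles[i]
    allele = pool[int(rng.integers(len(pool)))]
    return wait, pools.loci[i], allele


def embed_state(
    q: AllelicState,
    new_formation: AllelicFormation,
    locus,
    allele,
    eps_mut: float,
) -> AllelicState:
    """Inject a new allele at trace frequency into the larger multi-simplex.

    At the mutated locus the new allele receives frequency ``eps_mut`` and
    the old frequencies are scaled by ``1 - eps_mut``; other loci are
    untouched.  The replicator flow cannot grow an allele from frequency
    exactly zero, so a strictly positive injection is what makes a novel
    mutation dynamically visible at all.
    """
    if not 0 < eps_mut < 1:
        raise ValueError("eps_mut must lie strictly between 0 and 1")
    expected = expand_formation(q.formation, locus, allele)
    if expected != new_formation:
        raise GameValidationError(
            "new formation is not the old one plus the given allele"
        )
    i = q.formation.locus_index(locus)
    vecs = []
    for j, v in enumerate(q.per_locus):
        if j == i:
            vecs.append(np.append(v * (1.0 - eps_mut), eps_mut))
        else:
            vecs.append(v.copy())
    return AllelicState(new_formation, tuple(vecs))


def embed_genotype_state(
    p: GenotypeState,
    new_formation: AllelicFormation,
    source: Genotype,
    target: Genotype,
    eps_mut: float,
) -> GenotypeState:
    """Asexual analogue of :func:`embed_state`: one individual mutates.

    Weight ``eps_mut`` moves from ``source`` to ``target`` after the old
    weights are carried (by genotype label) into the possibly larger
    genotype space of ``new_formation``.
    """
    if not 0 < eps_mut < 1:
        raise ValueError("eps_mut must lie strictly between 0 and 1")
    if not new_formation.contains(p.formation):
        raise GameValidationError("new formation must extend the state's formation")
    weights = {g: w for g, w in zip(enumerate_genotypes(p.formation), p.weights)}
    if weights.get(source, 0.0) < eps_mut:
        raise GameValidationError(
            f"source genotype {source} carries less than eps_mut weight"
        )
    weights[source] = weights.get(source, 0.0) - eps_mut
    weights[target] = weights.get(target, 0.0) + eps_mut
    return GenotypeState.from_dict(new_formation, weights)


def classify_event(
    old_game: CommonInterestsGame,
    occupied_eq: Genotype,
    new_game: CommonInterestsGame,
    strict: bool = True,
) -> str:
    """Classify a mutation by what it does to the occupied equilibrium.

    * identical games -> ``non_novel``;
    * occupied equilibrium still a pure Nash of the new game ->
      ``game_changing`` (the population stays put);
    * otherwise -> ``nash_changing`` (the population must move, and by the
      monotone-ascent property the new equilibrium is strictly fitter).
    """
    if occupied_eq not in pure_nash_equilibria(old_game, strict=strict):
        raise GameValidationError(
            f"{occupied_eq} is not a pure Nash equilibrium of the current game"
        )
    if old_game == new_game:
        return NON_NOVEL
    new_eqs = pure_nash_equilibria(new_game, strict=strict)
    return GAME_CHANGING if occupied_eq in new_eqs else NASH_CHANGING


def run_pdmp(
    universe: AlleleUniverse,
    initial_state: AllelicState,
    lam: float,
    rng=None,
    seed: Optional[int] = None,
    n_events: Optional[int] = 20,
    horizon: Optional[float] = None,
    eps_mut: float = 1e-3,
    config: DynamicsConfig = DEFAULT_CONFIG,
    quasi_static: bool = False,
) -> PDMPRun:
    """Simulate the mutation process from ``initial_state``.

    Alternates deterministic segments with sampled clock events until
    ``n_events`` arrivals have occurred, the time ``horizon`` is exceeded,
    or the allele universe is exhausted, then runs a final segment to full
    equilibrium.  With ``quasi_static=True`` every segment is integrated to
    equilibrium regardless of the sampled waiting time — the slow-mutation
    idealisation in which "occupied equilibrium" is exact; the default mode
    cuts each segment at its event time.

    Fixing ``seed`` (or passing an ``rng``) makes the run record
    bit-reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    formation = initial_state.formation
    game = universe.restrict(formation)
    state = initial_state
    run = PDMPRun(
        universe=universe,
        seed=seed,
        lam=lam,
        eps_mut=eps_mut,
        quasi_static=quasi_static,
        config=config,
    )
    t = 0.0
    pending: Optional[MutationEvent] = None

    def close_segment(traj: Trajectory) -> Segment:
        nonlocal pending
        eq = traj.limit
        seg = Segment(game, traj, eq, game.fitness_of(eq))
        run.segments.append(seg)
        if pending is not None:
            pending.post_eq = seg.eq
            pending.post_fitness = seg.eq_fitness
            pending = None
        return seg

    while n_events is None or len(run.events) < n_events:
        drawn = sample_next_event(rng, lam, formation, universe)
        if drawn is None:
            run.exhausted = True
            break
        wait, locus, allele = drawn
        if horizon is not None and t + wait > horizon:
            break
        if quasi_static:
            traj = integrate_to_equilibrium(game, state, "sexual", config)
        else:
            traj = integrate_for(game, state, wait, "sexual", config)
        seg = close_segment(traj)
        state = traj.final_state
        t += wait
        if formation.has_allele(locus, allele):
            ev = MutationEvent(
                t, locus, allele, NON_NOVEL, seg.eq, seg.eq_fitness,
                post_eq=None, post_fitness=None,
            )
        else:
            new_formation = expand_formation(formation, locus, allele)
            new_game = universe.restrict(new_formation)
            cls = classify_event(game, seg.eq, new_game)
            state = embed_state(state, new_formation, locus, allele, eps_mut)
            formation, game = new_formation, new_game
            ev = MutationEvent(
                t, locus, allele, cls, seg.eq, seg.eq_fitness,
                post_eq=None, post_fitness=None,
            )
        run.events.append(ev)
        pending = ev

    final_traj = integrate_to_equilibrium(game, state, "sexual", config)
    close_segment(final_traj)
    run.final_state = final_traj.final_state
    return run
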