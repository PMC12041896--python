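"""Derived statistics of the mutation process.

Four analyses built on the dynamics and the PDMP:

* arrival-order probabilities for competing novel mutations (closed form
  ``lam_a / (lam_a + lam_b)`` and a Monte Carlo check);
* fitness-valley detection on a landscape: two local maxima (strict pure
  Nash genotypes) at Hamming distance >= 2 with no intermediate local
  maximum on a shortest path;
* evolutionary contingency: replaying the same set of mutations in two
  orders and comparing the final equilibria;
* the centered fitness random walk over novel arrivals and its stopped,
  variance-normalised endpoint, whose distribution approaches a standard
  normal as the variance budget grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dynamics import DEFAULT_CONFIG, DynamicsConfig, integrate_to_equilibrium
from .formations import AlleleUniverse, expand_formation
from .games import (
    AllelicFormation,
    AllelicState,
    CommonInterestsGame,
    GameValidationError,
    Genotype,
    pure_nash_equilibria,
)
from .pdmp import (
    NASH_CHANGING,
    PDMPRun,
    classify_event,
    embed_state,
)

__all__ = [
    "arrival_order_probability",
    "hamming_distance",
    "ValleyPair",
    "find_fitness_valleys",
    "ContingencyReport",
    "OrderResult",
    "compare_contingency",
    "near_vertex_state",
    "FitnessWalk",
    "fitness_walk_statistics",
    "ensemble_endpoints",
]


# -- arrival order ---------------------------------------------------------


def arrival_order_probability(
    lam_a: float,
    lam_b: float,
    method: str = "closed_form",
    n: Optional[int] = None,
    rng=None,
) -> float:
    """Probability that the rate-``lam_a`` mutation arrives first.

    For independent exponential clocks, ``Pr(tau_a < tau_b) =
    lam_a / (lam_a + lam_b)``; ``method="monte_carlo"`` instead draws ``n``
    independent pairs and returns the empirical frequency.
    """
    if lam_a <= 0 or lam_b <= 0:
        raise ValueError("arrival rates must be positive")
    if method == "closed_form":
        return lam_a / (lam_a + lam_b)
    if method == "monte_carlo":
        if n is None or n < 1:
            raise ValueError("monte_carlo requires n >= 1")
        if rng is None:
            rng = np.random.default_rng()
        ta = rng.exponential(1.0 / lam_a, size=n)
        tb = rng.exponential(1.0 / lam_b, size=n)
        return float(np.mean(ta < tb))
    raise ValueError(f"unknown method {method!r}")


def hamming_distance(g1: Genotype, g2: Genotype) -> int:
    """Number of loci at which two genotypes differ."""
    if len(g1) != len(g2):
        raise GameValidationError("genotypes have different numbers of loci")
    return sum(a != b for a, b in zip(g1, g2))


# -- fitness valleys -------------------------------------------------------


@dataclass(frozen=True)
class ValleyPair:
    """Two local maxima separated by a fitness valley.

    ``g2`` is the fitter peak; it cannot be reached from ``g1`` by single
    beneficial substitutions because every shortest Hamming path passes
    through strictly lower ground.
    """

    g1: Genotype
    g2: Genotype
    w_g1: float
    w_g2: float
    hamming: int

    def __post_init__(self):
        if not self.w_g2 > self.w_g1:
            raise GameValidationError("valley pair must have w_g2 > w_g1")
        if self.hamming < 2:
            raise GameValidationError("valley pair must be at Hamming distance >= 2")


def find_fitness_valleys(game: CommonInterestsGame) -> list:
    """All fitness valleys of the landscape, in deterministic order.

    Local maxima are the strict pure Nash genotypes.  A pair ``(g1, g2)``
    qualifies when (a) ``w_g2 > w_g1``, (b) their Hamming distance is at
    least 2, and (c) no third local maximum ``g3`` lies on a shortest
    Hamming path, i.e. ``d(g1,g3) + d(g3,g2) = d(g1,g2)``.  Pairs are
    ordered by the genotype enumeration of the lower peak, then the higher.
    """
    maxima = pure_nash_equilibria(game, strict=True)
    out = []
    for g1 in maxima:
        for g2 in maxima:
            w1, w2 = game.fitness_of(g1), game.fitness_of(g2)
            if not w2 > w1:
                continue
            d = hamming_distance(g1, g2)
            if d < 2:
                continue
            blocked = any(
                g3 not in (g1, g2)
                and hamming_distance(g1, g3) + hamming_distance(g3, g2) == d
                for g3 in maxima
            )
            if not blocked:
                out.append(ValleyPair(g1, g2, w1, w2, d))
    return out


# -- evolutionary contingency ---------------------------------------------


def near_vertex_state(
    formation: AllelicFormation, genotype: Genotype, eta: float = 0.01
) -> AllelicState:
    """An interior state concentrated near a genotype's vertex.

    Each locus vector is ``(1 - eta)`` at the genotype's allele plus a
    uniform share of ``eta`` over all alleles of the locus — the standing
    variation a real near-monomorphic population carries.  Interior starts
    are what the convergence theory covers.
    """
    if not 0 < eta < 1:
        raise ValueError("eta must lie strictly between 0 and 1")
    idx = formation.genotype_index(genotype)
    vecs = []
    for j, pool in zip(idx, formation.alleles):
        v = np.full(len(pool), eta / len(pool))
        v[j] += 1.0 - eta
        vecs.append(v)
    return AllelicState(formation, tuple(vecs))


@dataclass
class OrderResult:
    """Outcome of one mutation order: the chain of equilibria it visits."""

    order: tuple
    final_eq: Genotype
    final_fitness: float
    events: list  # (locus, allele, classification, post_eq, post_fitness)


@dataclass
class ContingencyReport:
    result_a: OrderResult
    result_b: OrderResult
    divergent: bool

    def to_dict(self) -> dict:
        def enc(r: OrderResult) -> dict:
            return {
                "order": [[str(l), str(a)] for l, a in r.order],
                "final_eq": list(r.final_eq),
                "final_fitness": r.final_fitness,
                "events": [
                    {
                        "locus": str(l),
                        "allele": str(a),
                        "class": c,
                        "post_eq": list(g),
                        "post_fitness": w,
                    }
                    for l, a, c, g, w in r.events
                ],
            }

        return {
            "order_a": enc(self.result_a),
            "order_b": enc(self.result_b),
            "divergent": self.divergent,
        }


def _replay_order(
    universe: AlleleUniverse,
    formation: AllelicFormation,
    occupied_eq: Genotype,
    order: Sequence,
    eta: float,
    eps_mut: float,
    config: DynamicsConfig,
) -> OrderResult:
    game = universe.restrict(formation)
    if occupied_eq not in pure_nash_equilibria(game, strict=True):
        raise GameValidationError(
            f"{occupied_eq} is not a strict pure Nash equilibrium of the base game"
        )
    state = near_vertex_state(formation, occupied_eq, eta)
    traj = integrate_to_equilibrium(game, state, "sexual", config)
    eq, state = traj.limit, traj.final_state
    events = []
    for locus, allele in order:
        new_formation = expand_formation(formation, locus, allele)
        new_game = universe.restrict(new_formation)
        cls = classify_event(game, eq, new_game)
        state = embed_state(state, new_formation, locus, allele, eps_mut)
        formation, game = new_formation, new_game
        traj = integrate_to_equilibrium(game, state, "sexual", config)
        eq, state = traj.limit, traj.final_state
        events.append((locus, allele, cls, eq, game.fitness_of(eq)))
    return OrderResult(tuple(tuple(s) for s in order), eq, game.fitness_of(eq), events)


def compare_contingency(
    universe: AlleleUniverse,
    base_formation: AllelicFormation,
    occupied_eq: Genotype,
    order_a: Sequence,
    order_b: Sequence,
    eta: float = 0.01,
    eps_mut: float = 1e-3,
    config: DynamicsConfig = DEFAULT_CONFIG,
) -> ContingencyReport:
    """Replay the same mutations in two orders and compare the outcomes.

    Both orders must be permutations of the same ``(locus, allele)``
    multiset, each step a valid expansion along its own path.  The chain is
    fully deterministic (converge, expand, embed, converge), so the report
    is seed-free and idempotent.  ``divergent`` is set when the two final
    equilibrium genotypes differ — the signature of historical contingency.
    """
    if sorted(map(tuple, order_a)) != sorted(map(tuple, order_b)):
        raise GameValidationError(
            "orders must be permutations of the same mutation multiset"
        )
    ra = _replay_order(universe, base_formation, occupied_eq, order_a, eta, eps_mut, config)
    rb = _replay_order(universe, base_formation, occupied_eq, order_b, eta, eps_mut, config)
    return ContingencyReport(ra, rb, divergent=ra.final_eq != rb.final_eq)


# -- the fitness walk and its stopped endpoint -----------------------------


@dataclass
class FitnessWalk:
    """The centered fitness walk of one run.

    ``Y[k]`` is the equilibrium fitness just before the (k+1)-th novel
    arrival; ``Z`` is the cumulative sum of ``Y`` minus its one-step
    conditional expectation (a martingale); ``sigma2[k]`` is the conditional
    variance of ``Y[k]`` given the history — the variance of the (k+1)-th
    martingale increment, so ``sum(sigma2[:k])`` is the predictable
    quadratic variation of ``Z_k``.  ``kappa_v`` is the first index at which
    that accumulated variance reaches the budget ``v``, and ``F`` the
    endpoint ``Z[kappa_v] / sqrt(v)``, which is approximately standard
    normal for large ``v``.
    """

    Y: np.ndarray
    Z: np.ndarray
    sigma2: np.ndarray
    v: float
    kappa_v: Optional[int]
    F: Optional[float]
    excluded: bool
    max_jump: float


def _novel_candidate_distribution(
    universe: AlleleUniverse, formation: AllelicFormation
) -> tuple:
    """Novel ``(locus, allele)`` candidates with their conditional weights.

    The clock picks a locus uniformly and an allele uniformly from that
    locus's pool; conditioning on the event being novel renormalises the
    weights over the candidates that are not yet present.
    """
    pools = universe.pools
    cands, weights = [], []
    m = pools.n_loci
    for locus, pool, have in zip(pools.loci, pools.alleles, formation.alleles):
        for a in pool:
            if a not in have:
                cands.append((locus, a))
                weights.append((1.0 / m) * (1.0 / len(pool)))
    w = np.asarray(weights, dtype=float)
    return cands, w / w.sum() if len(w) else w


def _candidate_outcomes(
    universe: AlleleUniverse,
    game: CommonInterestsGame,
    state: AllelicState,
    eq: Genotype,
    eq_fitness: float,
    eps_mut: float,
    config: DynamicsConfig,
    taken=None,
) -> tuple:
    """Post-settlement equilibrium fitness for every possible novel mutation.

    Game-changing candidates leave the occupied equilibrium (hence its
    fitness) in place, so only Nash-changing candidates require an actual
    converge run from the embedded state.  ``taken``, when given as
    ``(locus, allele, fitness)``, supplies the already-simulated outcome of
    the mutation the run actually realised.
    """
    cands, probs = _novel_candidate_distribution(universe, game.formation)
    outcomes = np.empty(len(cands))
    for k, (locus, allele) in enumerate(cands):
        if taken is not None and (locus, allele) == (taken[0], taken[1]):
            outcomes[k] = taken[2]
            continue
        new_formation = expand_formation(game.formation, locus, allele)
        new_game = universe.restrict(new_formation)
        cls = classify_event(game, eq, new_game)
        if cls == NASH_CHANGING:
            q = embed_state(state, new_formation, locus, allele, eps_mut)
            traj = integrate_to_equilibrium(new_game, q, "sexual", config)
            outcomes[k] = new_game.fitness_of(traj.limit)
        else:
            outcomes[k] = eq_fitness
    return probs, outcomes


def _conditional_moments(
    probs: np.ndarray,
    outcomes: np.ndarray,
    estimator: str,
    B: int,
    rng,
) -> tuple:
    if estimator == "exact":
        mu = float(probs @ outcomes)
        var = float(probs @ (outcomes - mu) ** 2)
        return mu, var
    if estimator == "branching":
        if B < 2:
            raise ValueError("branching estimator needs B >= 2 siblings")
        draws = outcomes[rng.choice(len(outcomes), size=B, p=probs)]
        return float(np.mean(draws)), float(np.var(draws, ddof=1))
    raise ValueError(f"unknown estimator {estimator!r}")


def fitness_walk_statistics(
    runs: Sequence[PDMPRun],
    v: float,
    c: Optional[float] = None,
    estimator: str = "branching",
    B: int = 20,
    rng=None,
) -> list:
    """Build the centered fitness walk and stopped endpoint for each run.

    The one-step conditional mean and variance of the next pre-arrival
    equilibrium fitness are estimated at each visited state, either exactly
    (enumerating the novel-candidate distribution; feasible because pools
    are finite) or by branching replication with ``B`` sibling continuations
    drawn from the same distribution.  A run whose accumulated conditional
    variance never reaches the budget ``v`` is excluded with a warning.

    The ensemble of ``F`` endpoints is the object the normal limit speaks
    about: mean 0, variance 1 as ``v`` grows.
    """
    if len(runs) < 2:
        raise ValueError("need an ensemble of at least 2 runs")
    if v < 0:
        raise ValueError("variance budget v must be nonnegative")
    if rng is None:
        rng = np.random.default_rng()
    walks = []
    for run in runs:
        walks.append(_walk_one(run, v, c, estimator, B, rng))
    n_exc = sum(w.excluded for w in walks)
    if n_exc:
        warnings.warn(
            f"{n_exc} of {len(runs)} runs never accumulated conditional "
            f"variance {v}; excluded from the endpoint ensemble"
        )
    return walks


def _walk_one(run: PDMPRun, v, c, estimator, B, rng) -> FitnessWalk:
    # states visited just before each novel arrival, and after the last one
    pre_states = []  # (game, state, eq, eq_fitness, event)
    novel_idx = [
        i for i, e in enumerate(run.events) if e.classification != "non_novel"
    ]
    for i in novel_idx:
        seg = run.segments[i]
        pre_states.append(
            (seg.game, seg.trajectory.final_state, seg.eq, seg.eq_fitness,
             run.events[i])
        )
    last = run.segments[-1]
    pre_states.append(
        (last.game, last.trajectory.final_state, last.eq, last.eq_fitness, None)
    )

    Y = np.array([s[3] for s in pre_states])  # Y_1 .. Y_{K+1}
    K = len(novel_idx)
    # Z_0 = 0 and the first increment is zero (the initial equilibrium is
    # deterministic given the starting condition); afterwards increment k is
    # Y_k minus its conditional expectation given the history.  sigma2[k] is
    # the conditional variance of Y[k] given the history — the variance of
    # the (k+1)-th increment — so the running sum of sigma2 is the
    # predictable quadratic variation of Z.  Moments are only evaluated
    # until that sum crosses the budget: later steps cannot move kappa_v.
    increments = [0.0]
    sigma2 = [0.0]
    kappa = None
    for j in range(K):
        game, state, eq, eq_fit, event = pre_states[j]
        taken = (event.locus, event.allele, Y[j + 1])
        probs, outcomes = _candidate_outcomes(
            run.universe, game, state, eq, eq_fit, run.eps_mut, run.config,
            taken=taken,
        )
        mu, var = _conditional_moments(probs, outcomes, estimator, B, rng)
        sigma2.append(var)
        increments.append(Y[j + 1] - mu)
        if v > 0 and kappa is None and sum(sigma2) >= v:
            kappa = j + 2  # kappa_v = min{k : sum_{i<=k} sigma_i^2 >= v}
            break
    n = len(increments)
    Z = np.concatenate([[0.0], np.cumsum(increments)])
    Y = Y[:n]
    sigma2 = np.asarray(sigma2)
    max_jump = float(np.max(np.abs(increments)))
    if c is not None and max_jump > c:
        warnings.warn(f"fitness jump {max_jump:.3g} exceeds the configured bound {c}")
    if v == 0:
        return FitnessWalk(Y, Z, sigma2, v, 0, 0.0, False, max_jump)
    if kappa is None:
        return FitnessWalk(Y, Z, sigma2, v, None, None, True, max_jump)
    F = float(Z[kappa] / np.sqrt(v))
    return FitnessWalk(Y, Z, sigma2, v, kappa, F, False, max_jump)


def ensemble_endpoints(walks: Sequence[FitnessWalk]) -> np.ndarray:
    """The ``F`` values of all non-excluded walks."""
    return np.array([w.F for w in walks if not w.excluded])
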