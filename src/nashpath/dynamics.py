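"""Deterministic selection flows between mutation events.

Two mean-field dynamics on a fixed game:

* **asexual** — the genotypic replicator equation
  ``dp_g/dt = p_g (w_g - w(p))`` on the genotype simplex;
* **sexual** — the allelic multi-replicator equation
  ``dq^i_j/dt = q^i_j (w^i_j(q) - w(q))`` on the multi-simplex, one
  replicator per locus coupled through the marginal fitnesses.  This is the
  mean-field limit of random mating with free recombination, under the
  linkage-equilibrium assumption.

Both are gradient flows of the mean fitness under the Shahshahani metric
(the simplex metric weighting direction ``j`` by ``1/q_j``), so mean fitness
is non-decreasing along every trajectory and interior orbits converge to
pure Nash equilibria of the common-interests game — the single fitness-
maximal genotype in the asexual case, any strict pure Nash in the sexual
case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from ._kernels import sexual_field_factory
from .games import (
    AllelicState,
    CommonInterestsGame,
    DimensionMismatchError,
    GenotypeState,
    Genotype,
    _all_marginals,
    _mean_fitness_raw,
    _split,
    enumerate_genotypes,
    pure_nash_equilibria,
)

__all__ = [
    "DynamicsConfig",
    "Trajectory",
    "replicator_field",
    "multireplicator_field",
    "integrate_to_equilibrium",
    "integrate_for",
    "distance_to_nash",
    "shahshahani_residual",
]


@dataclass(frozen=True)
class DynamicsConfig:
    """Integrator and convergence settings shared across the package.

    ``tol_v`` is the max-norm velocity threshold declaring a fixed point;
    ``tol_m`` stops integration once some genotype (or, per locus, some
    allele) holds mass ``1 - tol_m``; ``horizon`` caps integration time.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    tol_v: float = 1e-9
    tol_m: float = 1e-6
    horizon: float = 1e4
    max_samples: int = 256


DEFAULT_CONFIG = DynamicsConfig()


@dataclass
class Trajectory:
    """A sampled deterministic orbit with its mean-fitness series."""

    mode: str  # "sexual" or "asexual"
    game: CommonInterestsGame
    times: np.ndarray
    states: np.ndarray  # one row per time; concatenated coordinates
    mean_fitness: np.ndarray
    converged: bool
    limit: Optional[Genotype]
    interior_start: bool

    def __post_init__(self):
        if len(self.times) != len(self.states) or len(self.times) != len(
            self.mean_fitness
        ):
            raise ValueError("times, states and fitness series must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def final_state(self) -> Union[GenotypeState, AllelicState]:
        return self.state_at(-1)

    def state_at(self, k: int) -> Union[GenotypeState, AllelicState]:
        row = self.states[k]
        if self.mode == "asexual":
            return GenotypeState(self.game.formation, row)
        return AllelicState.from_concatenated(self.game.formation, row)

    @property
    def final_mean_fitness(self) -> float:
        return float(self.mean_fitness[-1])

    def column_labels(self) -> list:
        if self.mode == "asexual":
            return ["|".join(g) for g in enumerate_genotypes(self.game.formation)]
        f = self.game.formation
        return [f"{l}:{a}" for l, pool in zip(f.loci, f.alleles) for a in pool]


# -- vector fields ---------------------------------------------------------


def replicator_field(game: CommonInterestsGame, p) -> np.ndarray:
    """Genotypic replicator velocity; components sum to zero."""
    weights = p.weights if isinstance(p, GenotypeState) else np.asarray(p, float)
    flat = game.tensor.ravel()
    if weights.shape != flat.shape:
        raise DimensionMismatchError("state length does not match genotype count")
    return weights * (flat - flat @ weights)


def multireplicator_field(game: CommonInterestsGame, q) -> tuple:
    """Multi-replicator velocity, one vector per locus; each sums to zero.

    Returned as a tuple of per-locus arrays aligned with the formation.
    """
    vecs = (
        list(q.per_locus) if isinstance(q, AllelicState) else [np.asarray(v, float) for v in q]
    )
    if isinstance(q, AllelicState) and q.formation != game.formation:
        raise DimensionMismatchError("allelic state is for a different formation")
    if len(vecs) != game.formation.n_loci or any(
        v.shape != (n,) for v, n in zip(vecs, game.formation.shape)
    ):
        raise DimensionMismatchError("per-locus vector length mismatch")
    margs = _all_marginals(game.tensor, vecs)
    out = []
    for v, marg in zip(vecs, margs):
        w = float(marg @ v)
        out.append(v * (marg - w))
    return tuple(out)


def _rhs_asexual(tensor_flat: np.ndarray):
    def rhs(t, y):
        return y * (tensor_flat - tensor_flat @ y)

    return rhs


def _rhs_sexual(game: CommonInterestsGame):
    field = sexual_field_factory(game.tensor, game.formation.shape)

    def rhs(t, y):
        return field(y)

    return rhs


# -- integration -----------------------------------------------------------


def _normalize(mode: str, game: CommonInterestsGame, y: np.ndarray) -> np.ndarray:
    """Project back onto the (multi-)simplex, clipping integrator dust."""
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite state during integration")
    if np.any(y < -1e-9):
        raise FloatingPointError("state left the simplex during integration")
    y = np.clip(y, 0.0, None)
    if mode == "asexual":
        return y / y.sum()
    parts = _split(game.formation, y)
    return np.concatenate([v / v.sum() for v in parts])


def _leading_mass(mode: str, game: CommonInterestsGame, y: np.ndarray) -> float:
    if mode == "asexual":
        return float(y.max())
    return min(float(v.max()) for v in _split(game.formation, y))


def _leading_genotype(mode: str, game: CommonInterestsGame, y: np.ndarray) -> Genotype:
    if mode == "asexual":
        return enumerate_genotypes(game.formation)[int(np.argmax(y))]
    f = game.formation
    return tuple(
        pool[int(np.argmax(v))] for pool, v in zip(f.alleles, _split(f, y))
    )


def _mean_fitness(mode: str, game: CommonInterestsGame, y: np.ndarray) -> float:
    if mode == "asexual":
        return float(game.tensor.ravel() @ y)
    return _mean_fitness_raw(game.tensor, _split(game.formation, y))


def _as_vector(mode: str, game: CommonInterestsGame, state) -> tuple:
    if mode == "asexual":
        if isinstance(state, GenotypeState):
            if state.formation != game.formation:
                raise DimensionMismatchError("state is for a different formation")
            y, interior = state.weights.copy(), bool(np.all(state.weights > 0))
        else:
            y = np.asarray(state, float).copy()
            interior = bool(np.all(y > 0))
        return y, interior
    if isinstance(state, AllelicState):
        if state.formation != game.formation:
            raise DimensionMismatchError("state is for a different formation")
        return state.concatenated(), state.is_interior()
    y = np.asarray(state, float).copy()
    return y, bool(np.all(y > 0))


def _attribute_limit(mode: str, game: CommonInterestsGame, y: np.ndarray) -> Genotype:
    """Nearest pure-Nash genotype label for a (near-)converged state."""
    if mode == "asexual":
        return enumerate_genotypes(game.formation)[int(np.argmax(y))]
    q = AllelicState.from_concatenated(game.formation, y)
    nash = pure_nash_equilibria(game, strict=True) or pure_nash_equilibria(
        game, strict=False
    )
    dists = [_l1_to_vertex(game, q, g) for g in nash]
    return nash[int(np.argmin(dists))]


def _integrate(
    game: CommonInterestsGame,
    state,
    mode: str,
    duration: float,
    config: DynamicsConfig,
    stop_on_convergence: bool = True,
    hold_tail: bool = False,
) -> Trajectory:
    """Workhorse: chunked adaptive RK45 with convergence detection.

    Integrates for at most ``duration`` time units, renormalising after each
    chunk.  If the flow converges first and ``hold_tail`` is set, the final
    value is held constant so the trajectory still spans ``duration`` (used
    for fixed-length inter-mutation segments).
    """
    if mode not in ("sexual", "asexual"):
        raise ValueError(f"unknown mode {mode!r}")
    y, interior = _as_vector(mode, game, state)
    rhs = (
        _rhs_asexual(game.tensor.ravel()) if mode == "asexual" else _rhs_sexual(game)
    )
    ts = [0.0]
    ys = [y.copy()]
    t = 0.0
    chunk = min(16.0, duration) if duration > 0 else 0.0
    converged = False
    # Every vertex of the multi-simplex is a fixed point of the flow, so a
    # small-velocity or dominant-mass test alone can mistake a saddle corner
    # for the limit while trace frequencies are still regrowing.  In sexual
    # mode the stop is therefore gated on the dominant genotype actually
    # being a strict pure Nash equilibrium (the only attracting vertices).
    if mode == "sexual":
        attracting = set(pure_nash_equilibria(game, strict=True))
    else:
        attracting = None
    while t < duration:
        t_end = min(t + chunk, duration)
        sol = solve_ivp(
            rhs,
            (t, t_end),
            y,
            method="RK45",
            rtol=config.rtol,
            atol=config.atol,
        )
        if not sol.success:
            raise FloatingPointError(f"integration failed: {sol.message}")
        for tk, yk in zip(sol.t[1:], sol.y.T[1:]):
            ts.append(float(tk))
            ys.append(yk)
        y = _normalize(mode, game, sol.y[:, -1])
        ys[-1] = y.copy()
        t = float(sol.t[-1])
        vel = float(np.max(np.abs(rhs(t, y))))
        if vel < config.tol_v or _leading_mass(mode, game, y) > 1 - config.tol_m:
            if (
                attracting is None
                or not attracting
                or _leading_genotype(mode, game, y) in attracting
            ):
                converged = True
                if stop_on_convergence:
                    break
        # cap the check interval: overshooting the stopping time keeps
        # eroding trace alleles exponentially, which a later Nash-changing
        # transition may need to regrow
        chunk = min(chunk * 2.0, 64.0)
    if hold_tail and t < duration:
        ts.append(duration)
        ys.append(y.copy())
        t = duration
    times = np.asarray(ts)
    states = np.asarray(ys)
    keep = _sample_indices(len(times), config.max_samples)
    times, states = times[keep], states[keep]
    states = np.array([_normalize(mode, game, row) for row in states])
    fitness = np.array([_mean_fitness(mode, game, row) for row in states])
    return Trajectory(
        mode=mode,
        game=game,
        times=times,
        states=states,
        mean_fitness=fitness,
        converged=converged,
        limit=_attribute_limit(mode, game, states[-1]),
        interior_start=interior,
    )


def _sample_indices(n: int, max_samples: int) -> np.ndarray:
    if n <= max_samples:
        return np.arange(n)
    # keep endpoints and the tail dense; subsample the interior
    idx = np.unique(
        np.concatenate(
            [
                np.linspace(0, n - 1, max_samples - 8).astype(int),
                np.arange(max(0, n - 8), n),
            ]
        )
    )
    return idx


def integrate_to_equilibrium(
    game: CommonInterestsGame,
    state,
    mode: str = "sexual",
    config: DynamicsConfig = DEFAULT_CONFIG,
    horizon: Optional[float] = None,
) -> Trajectory:
    """Integrate the selection flow until it settles (or the horizon ends).

    Stops when the velocity max-norm drops below ``config.tol_v`` or the
    leading genotype/allele mass exceeds ``1 - config.tol_m``.  The returned
    trajectory carries a ``converged`` flag and the nearest pure-Nash
    genotype as its ``limit`` label.  Convergence to a Nash limit is
    guaranteed from strictly interior starts; boundary starts are legal but
    flagged via ``interior_start`` (coordinates at exactly zero stay zero
    under both flows).
    """
    h = config.horizon if horizon is None else horizon
    return _integrate(game, state, mode, h, config, stop_on_convergence=True)


def integrate_for(
    game: CommonInterestsGame,
    state,
    duration: float,
    mode: str = "sexual",
    config: DynamicsConfig = DEFAULT_CONFIG,
) -> Trajectory:
    """Integrate for exactly ``duration`` time units (one PDMP segment).

    If the flow reaches a fixed point early the state is held there for the
    remainder, which is exact: fixed points of the replicator flows are
    stationary.
    """
    return _integrate(
        game, state, mode, duration, config, stop_on_convergence=True, hold_tail=True
    )


# -- distances and gradient checks ----------------------------------------


def _l1_to_vertex(game: CommonInterestsGame, q: AllelicState, g: Genotype) -> float:
    idx = game.formation.genotype_index(g)
    total = 0.0
    for v, j in zip(q.per_locus, idx):
        # |v - e_j|_1 = 2 (1 - v_j) for v on the simplex
        total += 2.0 * (1.0 - float(v[j]))
    return total


def distance_to_nash(
    game: CommonInterestsGame, state: AllelicState, strict: bool = True
) -> float:
    """L1 distance from ``state`` to the nearest pure-Nash vertex.

    The distance is summed over the locus simplices; it is zero exactly at a
    pure Nash vertex and at most ``2 m``.  Finite common-interests games
    always have a pure Nash equilibrium (the fitness maximum), so the set is
    never empty.
    """
    nash = pure_nash_equilibria(game, strict=strict)
    if not nash and strict:
        nash = pure_nash_equilibria(game, strict=False)
    assert nash, "a finite common-interests game always has a pure Nash point"
    return min(_l1_to_vertex(game, state, g) for g in nash)


def shahshahani_residual(
    game: CommonInterestsGame, q: AllelicState, h: float = 1e-5
) -> float:
    """Max-norm gap between the multi-replicator field and the metric gradient.

    The mean fitness is differentiated by central finite differences in each
    allelic coordinate; the Shahshahani gradient on each locus simplex is
    then ``q_j (d_j - sum_k q_k d_k)``, i.e. the direction of steepest mean-
    fitness ascent under the ``1/q_j``-weighted inner product, projected onto
    the simplex tangent space.  A small residual certifies numerically that
    the flow is that gradient.  Requires a strictly interior state (the
    metric degenerates on the boundary).
    """
    if not q.is_interior():
        raise ValueError("Shahshahani metric degenerates on the simplex boundary")
    vecs = list(q.per_locus)
    field = multireplicator_field(game, q)
    resid = 0.0
    for i, v in enumerate(vecs):
        d = np.empty_like(v)
        for j in range(v.size):
            up = [x.copy() for x in vecs]
            dn = [x.copy() for x in vecs]
            up[i][j] += h
            dn[i][j] -= h
            d[j] = (
                _mean_fitness_raw(game.tensor, up) - _mean_fitness_raw(game.tensor, dn)
            ) / (2 * h)
        grad = v * (d - float(v @ d))
        resid = max(resid, float(np.max(np.abs(field[i] - grad))))
    return resid
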