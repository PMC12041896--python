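# Methods

## Model

A haploid genome has m loci; locus i currently carries a finite allele set
Aᵢ drawn from a larger pool of potentially available alleles. Fitness
w_g > 0 is a property of the genotype g alone (no frequency dependence, no
environmental change). Treating loci as players with alleles as actions
and w_g as the common payoff makes mean fitness a potential function, and
the pure Nash equilibria of the game are exactly the single-substitution
local maxima of the fitness landscape.

Two deterministic dynamics are implemented:

* the genotypic replicator equation ṗ_g = p_g (w_g − w̄(p)) for asexual
  reproduction, and
* the allelic multi-replicator equation q̇ⁱ_j = qⁱ_j (wⁱ_j(q) − w̄(q)) for
  sexual reproduction under random mating and free recombination, where
  the marginal fitness wⁱ_j(q) = ∂w̄/∂qⁱ_j is the mean fitness of
  genotypes forced to carry allele j at locus i.

The sexual dynamics assumes linkage equilibrium: the population state is
one frequency vector per locus and genotype frequencies are the product of
allele frequencies. This is the mean-field description of the offspring
rule in which each child allele is drawn from either parent with equal
probability; individual-based mating is not simulated.

Both flows are gradient flows of w̄ under the Shahshahani metric (the
simplex metric weighting direction j at frequency q_j by 1/q_j), which
gives the two structural facts the package tests lean on: mean fitness is
non-decreasing along every orbit, and interior orbits converge to pure
Nash equilibria — the unique fitness maximum (asexual) or any strict pure
Nash (sexual). `shahshahani_residual` certifies the gradient identity
numerically by comparing the field against a central-finite-difference
gradient of w̄ projected onto each simplex tangent space with the 1/q
weighting.

Mutations arrive on a Poisson clock with rate λ; each arrival picks a
locus uniformly and an allele uniformly from that locus's pool. The
uniform law is a modelling choice isolated behind the sampler interface.
An already-present allele is a non-novel event and changes nothing; a new
allele expands the formation (game-changing) and is injected at trace
frequency ε_mut (default 1e-3, configurable) with the resident locus
frequencies scaled by 1 − ε_mut. The injection must be strictly positive:
replicator dynamics cannot grow an allele from frequency zero. An event is
Nash-changing when the occupied equilibrium is no longer a (strict) pure
Nash equilibrium of the expanded game. Fitness values for newly reachable
genotypes come from a master landscape over the full pools
(`AlleleUniverse`); the game being played is always its restriction to the
current formation. When every pool is exhausted no novel event can occur
again and the run ends cleanly.

## Numerical choices

* Integration: adaptive RK45 (`scipy.integrate.solve_ivp`), defaults
  rtol 1e-8, atol 1e-10, in chunks whose length doubles from 16 up to a cap
  of 64 time units; after each chunk the state is renormalised per simplex
  (negative dust below ~1e-9 clipped to zero, anything worse aborts with a
  diagnostic). The chunk cap bounds overshoot past the stopping time:
  overshoot decays trace alleles exponentially, and a later Nash-changing
  transition may need to regrow them.
* Stopping: velocity max-norm < tol_v (default 1e-9) or leading mass per
  simplex > 1 − tol_m (default 1e-6), horizon 1e4 time units. In sexual
  mode the stop is additionally gated on the dominant genotype being a
  strict pure Nash: every vertex of the multi-simplex is a fixed point, and
  ungated criteria mistake saddle corners for limits (the valley-crossing
  orbit passes arbitrarily close to the non-equilibrium (a2,b3) corner).
* Limit attribution: nearest pure-Nash vertex in the summed per-locus L1
  distance (`distance_to_nash`; the metric is a package choice). Asexual
  limits are attributed to the heaviest genotype.
* Boundary starts are legal but flagged; coordinates at exactly zero stay
  zero (replicator invariance), and the convergence guarantees quoted above
  hold for interior starts only.
* The multi-replicator right-hand side is a prefix/suffix tensor
  contraction compiled with numba when available; a pure-numpy
  implementation of the same contraction is the reference path and a test
  pins their agreement.
* The PDMP has two modes. The default cuts each deterministic segment at
  its event time (the literal process). `quasi_static=True` integrates
  every segment to equilibrium regardless of the sampled waiting time —
  the slow-mutation idealisation under which "occupied equilibrium" is
  exact. Statements about the equilibrium-fitness ladder (weak monotonicity,
  strict increase exactly at Nash-changing events) are statements about
  that idealisation and are tested there; the finite-λ mode is used for the
  near-equilibrium occupancy check.

## Fitness-walk statistics

For novel-arrival times τ₁ < τ₂ < …, Y_k is the equilibrium mean fitness
just before the k-th arrival and

Z_k = Z_{k−1} + Y_k − E[Y_k | history],  Z₀ = 0.

Conditional moments are taken over the distribution of the next novel
mutation (locus uniform, allele uniform in the pool, conditioned on
novelty). Two estimators are provided behind one interface: branching
replication (B sibling continuations, default 20) and exact enumeration of
the candidate set, which is feasible because pools are finite; candidates
classified game-changing contribute the current fitness without
integration, so only Nash-changing candidates cost a converge run. σ²_k is
defined as Var(Y_k | history) — the conditional variance of the k-th
increment — so the running sum of σ² is the predictable quadratic
variation of Z and the stopped variable Z_{κ_v}, with
κ_v = min{k : Σ_{i≤k} σ²ᵢ ≥ v}, has variance ≥ v by construction. The
endpoint is normalised as F = Z_{κ_v}/√v; the 1/v normalisation sometimes
written for this statistic would degenerate to zero and cannot have a
unit-variance limit. Runs whose accumulated conditional variance never
reaches v are excluded with a warning; exclusions must be rare for the
ensemble moments to be unbiased, which constrains the study design below.

## What the synthetic generators emulate

* `matrix_game(1..4)` are the worked two-locus landscapes (valley,
  expanded valley, alternative expansion, both expansions) with the
  deleterious off-peak fitness δ exposed as a parameter, validated to
  0 < δ < 1 — the range in which the printed equilibrium pattern holds.
  The 2×3 game's unspecified (a1,b3) cell is set to 3/2, consistent with
  the 3×3 table; the 3×3 table's (a1,b3)=(a2,b3)=3/2 tie is kept as the
  canonical weak-but-not-strict equilibrium example.
* `random_game` draws i.i.d. Uniform(0.5, 2.5) fitness; continuity makes
  all values distinct with probability one (the draw is repeated on exact
  float ties), so random games are generic: unique global maximum, strict
  local maxima only.
* `modular_universe` / `rmf_modular_universe` build landscapes that are
  sums of independent modules (no epistasis between modules, full epistasis
  within). The rough-Mount-Fuji variant gives every derived allele a fixed
  additive benefit plus bounded idiosyncratic jitter, with the constraint
  additive_effect > 2·jitter keeping every substitution beneficial and all
  selection coefficients bounded away from zero.

None of the generators emulate drift, finite population size, linkage, de
novo allele loss, or frequency-dependent selection; passing tests certify
the mean-field model's own claims, not those of real finite populations.

## Study designs used in the test suite

Problem sizes were chosen so the full suite runs comfortably on one CPU.

* Convergence suite: 20 random generic games (2–3 loci, 2–3 alleles per
  locus) × 100 interior Dirichlet(1) starts, both dynamics.
* Mutation-path suite: 50 seeded quasi-static runs on random 2-locus
  universes (pools 4+4, start 2+2).
* Near-equilibrium occupancy: λ = 0.01; inter-event intervals accumulated
  across runs until ≥200; the state must be within 0.05 of the Nash set
  (L1) throughout the last 5% of at least 95% of intervals. The
  slow-mutation regime presumes relaxation times small against 1/λ, so
  this study runs on additive-with-jitter landscapes (6 loci, 3 alleles
  per pool, effect 3.0, jitter 0.4), whose selection coefficients are
  bounded below and whose transitions are single-locus sweeps. Generic
  i.i.d. landscapes do not satisfy the premise: a near-tied pair of cells
  makes relaxation arbitrarily slow, and epistatic cascades can depend on
  deeply decayed trace alleles. At λ = 0.01 a Nash-changing sweep still
  occasionally outlasts a short exponential interval — the finite-λ effect
  the theory averages away — but most events are non-novel, game-changing,
  or already-settled, keeping the empirical rate near 0.99.
* Fitness-walk moments: 500 quasi-static runs on 10-locus additive
  landscapes with effect 1.2 and jitter U(−0.15, 0.15) per substitution,
  budget v = 0.035, exact estimator. The design is deliberate: a single
  generic landscape concentrates all conditional variance in the first
  couple of record-like jumps, which is the opposite of the v → ∞ regime
  the normal limit describes. Independent additive loci keep variance
  flowing in ~10 comparable increments; v is about half the median
  accumulated variance, so the stopping time is typically crossed after
  4–5 steps (per-step variance ≪ v bounds the overshoot that inflates
  Var(F)) while fewer than ~5% of runs are excluded (exclusion correlates
  with path history and would bias the ensemble mean). The ensemble is
  checked for mean(F) ∈ ±0.1 and Var(F) ∈ [0.7, 1.3] — moment checks, not
  a distributional test; a Q-Q-ready dump of the endpoints is available
  from the `clt` CLI command for inspection.

## Known limitations

* Convergence detection is heuristic (velocity/mass thresholds plus the
  strict-Nash gate); orbits converging to weak, tied equilibria run to the
  horizon and are reported unconverged rather than misattributed.
* Long runs can erode unused trace alleles to ~1e-100 or below; the chunk
  cap bounds this per segment, but extremely long paths on landscapes with
  near-neutral alleles could underflow a frequency to exact zero, after
  which that allele cannot be recovered within the run.
* The exact walk estimator conditions on the full process history (the
  visited states), the natural filtration for the martingale construction;
  conditioning on the fitness values alone is coarser and is not
  implemented.
* The formation graph only grows: allele loss, and the asymptotics of
  unbounded-dimension paths, are out of scope.
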