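# nashpath

Evolution of a haploid, sexually reproducing population modelled as a path
through a graph of common-interests games.

## The model

Each locus *i* of a haploid genome is a player whose pure actions are the
alleles currently available at that locus; the tuple of available allele
sets **A** = (A₁, …, A_m) is the *allelic formation*. A genotype
g = (a₁, …, a_m) is a joint action profile, and every player receives the
same payoff — the genotype's fitness w_g > 0. Because interests coincide,
mean population fitness is a potential function of the game.

Two mean-field selection dynamics act on a fixed formation:

* **asexual** — the genotypic replicator equation
  ṗ_g = p_g (w_g − w̄(p)) on the simplex Δ(Γ);
* **sexual** — the allelic multi-replicator equation
  q̇ⁱ_j = qⁱ_j (wⁱ_j(q) − w̄(q)) on the multi-simplex ∏ᵢ Δ(Aᵢ), where
  wⁱ_j(q) is the marginal fitness of allele j at locus i under linkage
  equilibrium (random mating, free recombination).

Both flows are Shahshahani gradient ascent of w̄, so mean fitness is
non-decreasing and interior orbits converge to pure Nash equilibria of the
game: the global fitness maximum in the asexual case, any strict pure Nash
(a local landscape peak) in the sexual case.

Novel mutations arrive on a Poisson clock with rate λ and append one new
allele to one locus — a *game-changing* mutation, one directed edge in the
graph of formations. If the previously occupied equilibrium is no longer a
pure Nash equilibrium of the expanded game the mutation is in addition
*Nash-changing*: the population must move, and it moves to a strictly
fitter equilibrium. The resulting process — deterministic flow punctuated
by dimension-raising jumps — is a piecewise-deterministic Markov process
whose equilibrium-fitness ladder is weakly increasing, strictly at
Nash-changing events.

The package implements the games, the formation graph, both dynamics, the
mutation process, and the derived statistics: fitness-valley detection,
mutation-order (contingency) comparisons, arrival-order probabilities
λ_a/(λ_a+λ_b), and the centered fitness random walk
Z_k = Z_{k−1} + Y_k − E[Y_k | history] with its variance-stopped,
√v-normalised endpoint (approximately standard normal for large budgets v).

## Worked example

The 2×2 landscape with peaks w(a1,b1) = 1 and w(a2,b2) = 2 separated by
cells of fitness δ = 1/4 is a fitness valley: no single substitution from
(a1,b1) is beneficial. One novel allele b3 with w(a1,b3) = 3/2,
w(a2,b3) = 7/4 destroys the (a1,b1) equilibrium, and the sexual population
crosses the valley:

```bash
$ nashpath example --name valley_crossing --mode sexual
valley_crossing [sexual]: final=a2,b2 w=2 (expected a2,b2)
$ nashpath example --name valley_crossing --mode asexual
valley_crossing [asexual]: final=a1,b3 w=1.5 (expected a1,b3)
```

The sexual population ends monomorphic at (a2,b2) with mean fitness 2 —
and the allele b3 that triggered the crossing is itself extinct in the
final state. The asexual population, unable to recombine toward (a2,b2),
instead fixes the mutant lineage (a1,b3) at fitness 3/2.

Mutation order matters (evolutionary contingency):

```bash
$ nashpath contingency
b3 first: final=a2,b2 w=2
a3 first: final=a3,b1 w=3
divergent=True
```

Other subcommands: `nash` (equilibria of a game), `simulate` (one flow),
`pdmp` (the full mutation process, seeded and reproducible), `valleys`,
`order-prob`, `clt`, `randgame`. Games are plain JSON
(`{"loci": …, "alleles": …, "fitness": {"a1,b1": 1.0, …}}`); trajectories
are CSV; run records are JSON keyed by seed and configuration.

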