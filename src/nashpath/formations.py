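"""The directed graph of allelic formations.

Nodes are allelic formations; there is an edge from ``f`` to ``f'`` exactly
when ``f'`` adds one new allele to one locus of ``f``.  A novel mutation is
a single step along such an edge, so an evolutionary history is a directed
path through this graph.  The graph is never materialised — formations grow
combinatorially — and edges are generated lazily.

An :class:`AlleleUniverse` bounds the walk: it fixes finite per-locus pools
of potentially available alleles together with a master fitness landscape
over the full product space, of which every reachable game is a restriction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .games import (
    AllelicFormation,
    CommonInterestsGame,
    GameValidationError,
)

__all__ = [
    "NonNovelAlleleError",
    "expand_formation",
    "is_expansion_edge",
    "formation_dimension",
    "AlleleUniverse",
    "neighborhood_dot",
]


class NonNovelAlleleError(GameValidationError):
    """The allele is already present at the locus: not a novel mutation."""


def expand_formation(f: AllelicFormation, locus, allele) -> AllelicFormation:
    """Append one new allele at one locus; the original is unmodified.

    Raises :class:`NonNovelAlleleError` if the allele is already present —
    callers use this to classify an event as non-novel.
    """
    i = f.locus_index(locus)
    if allele in f.alleles[i]:
        raise NonNovelAlleleError(
            f"allele {allele!r} already present at locus {locus!r}"
        )
    alleles = tuple(
        pool + (allele,) if j == i else pool for j, pool in enumerate(f.alleles)
    )
    return AllelicFormation(f.loci, alleles)


def is_expansion_edge(f1: AllelicFormation, f2: AllelicFormation):
    """Whether ``f2`` extends ``f1`` by exactly one allele at one locus.

    Returns ``(True, (locus, allele))`` or ``(False, None)``.  Existing
    alleles must keep their order (the new allele is appended), matching
    how :func:`expand_formation` builds edges.
    """
    if f1.loci != f2.loci:
        return False, None
    found = None
    for locus, a1, a2 in zip(f1.loci, f1.alleles, f2.alleles):
        if a1 == a2:
            continue
        if len(a2) == len(a1) + 1 and a2[: len(a1)] == a1:
            if found is not None:  # two loci changed: not a single step
                return False, None
            found = (locus, a2[-1])
        else:
            return False, None
    if found is None:
        return False, None
    return True, found


def formation_dimension(f: AllelicFormation) -> int:
    """Dimension of the genotype simplex Δ(Γ): ``prod |A_i| - 1``.

    Strictly increases along every expansion edge.
    """
    return int(np.prod(f.shape)) - 1


@dataclass(frozen=True)
class AlleleUniverse:
    """Finite per-locus allele pools plus the fitness of every pool genotype.

    ``master`` is a game over the full pools; the game actually being played
    at any moment is its restriction to the current formation.  A formation
    whose allele sets equal the pools is *exhausted*: no further novel
    mutation is possible.
    """

    master: CommonInterestsGame

    @property
    def pools(self) -> AllelicFormation:
        return self.master.formation

    def validate(self, formation: AllelicFormation):
        if not self.pools.contains(formation):
            raise GameValidationError(
                "formation is not a sub-formation of the universe pools"
            )

    def restrict(self, formation: AllelicFormation) -> CommonInterestsGame:
        """The game induced on ``formation`` by the master landscape."""
        self.validate(formation)
        idx = tuple(
            [self.pools.allele_index(locus, a) for a in pool]
            for locus, pool in zip(formation.loci, formation.alleles)
        )
        return CommonInterestsGame(formation, self.master.tensor[np.ix_(*idx)])

    def novel_candidates(self, formation: AllelicFormation) -> list:
        """All ``(locus, allele)`` additions the pools still allow, in order."""
        self.validate(formation)
        out = []
        for locus, pool, have in zip(
            self.pools.loci, self.pools.alleles, formation.alleles
        ):
            out.extend((locus, a) for a in pool if a not in have)
        return out

    def exhausted(self, formation: AllelicFormation) -> bool:
        return not self.novel_candidates(formation)


def neighborhood_dot(
    universe: AlleleUniverse,
    formation: AllelicFormation,
    depth: int = 1,
    max_nodes: int = 64,
) -> str:
    """DOT text for the bounded out-neighbourhood of ``formation``.

    Intended for documentation figures only; the full graph is exponential.
    """

    def label(f: AllelicFormation) -> str:
        return " | ".join(",".join(p) for p in f.alleles)

    nodes = {label(formation): formation}
    edges = []
    frontier = [formation]
    for _ in range(depth):
        nxt = []
        for f in frontier:
            for locus, allele in universe.novel_candidates(f):
                g = expand_formation(f, locus, allele)
                edges.append((label(f), label(g), f"{locus}+{allele}"))
                if label(g) not in nodes and len(nodes) < max_nodes:
                    nodes[label(g)] = g
                    nxt.append(g)
        frontier = nxt
    lines = ["digraph formations {", '  rankdir="BT";']
    for name in nodes:
        lines.append(f'  "{name}";')
    for a, b, e in edges:
        if a in nodes and b in nodes:
            lines.append(f'  "{a}" -> "{b}" [label="{e}"];')
    lines.append("}")
    return "\n".join(lines)
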