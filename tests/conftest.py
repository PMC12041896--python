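import itertools

import numpy as np
import pytest

from nashpath import matrix_game
from nashpath.games import CommonInterestsGame, enumerate_genotypes


@pytest.fixture
def m1():
    return matrix_game(1, 0.25)


@pytest.fixture
def m2():
    return matrix_game(2, 0.25)


@pytest.fixture
def m3():
    return matrix_game(3, 0.25)


@pytest.fixture
def m4():
    return matrix_game(4, 0.25)


def nash_scan(game: CommonInterestsGame, strict: bool = True):
    """Independent brute-force deviation scan used as the Nash oracle.

    Deliberately written against the genotype dictionary, not the tensor,
    so it shares no code path with the implementation.
    """
    fitness = game.to_dict()
    formation = game.formation
    out = []
    for g in enumerate_genotypes(formation):
        ok = True
        for i, locus in enumerate(formation.loci):
            for a in formation.alleles_at(locus):
                if a == g[i]:
                    continue
                dev = tuple(a if j == i else g[j] for j in range(len(g)))
                if strict:
                    if fitness[dev] >= fitness[g]:
                        ok = False
                else:
                    if fitness[dev] > fitness[g]:
                        ok = False
        if ok:
            out.append(g)
    return out


def product_state(q_vectors):
    """Genotype distribution induced by independent per-locus frequencies."""
    out = []
    for combo in itertools.product(*[range(len(v)) for v in q_vectors]):
        p = 1.0
        for v, j in zip(q_vectors, combo):
            p *= v[j]
        out.append(p)
    return np.array(out)
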