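"""Readers and writers: game JSON, trajectory CSV, run records, configs.

The game JSON contract::

    {"loci": ["A", "B"],
     "alleles": {"A": ["a1", "a2"], "B": ["b1", "b2"]},
     "fitness": {"a1,b1": 1.0, "a1,b2": 0.25, ...}}

Fitness keys are allele labels comma-joined in locus order; the loader is
strict (every genotype exactly once, all values positive).
"""

from __future__ import annotations

import csv
import hashlib
import json
from typing import Optional

import yaml

from .dynamics import Trajectory
from .games import (
    AllelicFormation,
    CommonInterestsGame,
    GameValidationError,
    enumerate_genotypes,
)
from .pdmp import PDMPRun

__all__ = [
    "game_to_dict",
    "game_from_dict",
    "read_game",
    "write_game",
    "game_hash",
    "write_trajectory_csv",
    "run_record",
    "write_run_record",
    "load_config",
]


def game_to_dict(game: CommonInterestsGame) -> dict:
    f = game.formation
    return {
        "loci": [str(l) for l in f.loci],
        "alleles": {str(l): [str(a) for a in f.alleles_at(l)] for l in f.loci},
        "fitness": {
            ",".join(g): game.fitness_of(g) for g in enumerate_genotypes(f)
        },
    }


def game_from_dict(data: dict) -> CommonInterestsGame:
    for key in ("loci", "alleles", "fitness"):
        if key not in data:
            raise GameValidationError(f"game JSON is missing the {key!r} section")
    loci = data["loci"]
    alleles = data["alleles"]
    unknown = set(alleles) - set(loci)
    if unknown:
        raise GameValidationError(
            f"alleles given for unknown locus {sorted(unknown)[0]!r}"
        )
    try:
        formation = AllelicFormation.from_dict(loci, alleles)
    except KeyError as e:
        raise GameValidationError(f"no alleles listed for locus {e.args[0]!r}") from None
    genotypes = enumerate_genotypes(formation)
    expected = {",".join(g): g for g in genotypes}
    fitness = {}
    for key, value in data["fitness"].items():
        if key not in expected:
            raise GameValidationError(
                f"fitness key {key!r} does not name a genotype of this formation"
            )
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise GameValidationError(f"fitness of {key!r} is not a number")
        if value <= 0:
            raise GameValidationError(
                f"fitness of {key!r} must be strictly positive, got {value}"
            )
        fitness[expected[key]] = float(value)
    missing = [k for k, g in expected.items() if g not in fitness]
    if missing:
        raise GameValidationError(f"missing fitness for genotype {missing[0]!r}")
    return CommonInterestsGame(formation, fitness)


def read_game(path) -> CommonInterestsGame:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as e:
            raise GameValidationError(f"{path}: not valid JSON ({e})") from None
    return game_from_dict(data)


def write_game(game: CommonInterestsGame, path):
    with open(path, "w") as fh:
        json.dump(game_to_dict(game), fh, indent=1, sort_keys=False)
        fh.write("\n")


def game_hash(game: CommonInterestsGame) -> str:
    """Stable short hash of the canonical game JSON."""
    blob = json.dumps(game_to_dict(game), sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def write_trajectory_csv(traj: Trajectory, path):
    """One row per sample: t, per-coordinate frequencies, mean_fitness.

    The leading comment line records the game hash and the dynamics mode so
    a trajectory file is self-identifying.
    """
    with open(path, "w", newline="") as fh:
        fh.write(f"# game={game_hash(traj.game)} mode={traj.mode}\n")
        writer = csv.writer(fh)
        writer.writerow(["t", *traj.column_labels(), "mean_fitness"])
        for t, row, w in zip(traj.times, traj.states, traj.mean_fitness):
            writer.writerow(
                [f"{t:.10g}", *(f"{x:.12g}" for x in row), f"{w:.12g}"]
            )


def run_record(run: PDMPRun, trajectory_files: Optional[list] = None) -> dict:
    """JSON-serialisable record of one mutation-process run."""
    rec = {
        "seed": run.seed,
        "lambda": run.lam,
        "eps_mut": run.eps_mut,
        "quasi_static": run.quasi_static,
        "exhausted": run.exhausted,
        "universe_hash": game_hash(run.universe.master),
        "events": [
            {
                "t": e.time,
                "locus": str(e.locus),
                "allele": str(e.allele),
                "class": e.classification,
                "pre_eq": list(e.pre_eq),
                "post_eq": list(e.post_eq) if e.post_eq else None,
                "pre_w": e.pre_fitness,
                "post_w": e.post_fitness,
            }
            for e in run.events
        ],
        "equilibrium_fitness": run.equilibrium_fitness_series(),
        "final_eq": list(run.segments[-1].eq),
        "final_fitness": run.segments[-1].eq_fitness,
    }
    if trajectory_files is not None:
        rec["segments"] = [str(p) for p in trajectory_files]
    return rec


def write_run_record(run: PDMPRun, path, trajectory_files: Optional[list] = None):
    with open(path, "w") as fh:
        json.dump(run_record(run, trajectory_files), fh, indent=1)
        fh.write("\n")


def load_config(path) -> dict:
    """Load a YAML run configuration; returns a plain dict of options."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise GameValidationError(f"{path}: config must be a YAML mapping")
    return data
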