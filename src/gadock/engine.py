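"""Run orchestration for the docking search algorithms.

Three algorithms share one loop skeleton, one evaluation budget and one seeded
RNG stream:

``ga``   plain genetic algorithm: rank selection, two-point crossover,
         Cauchy mutation, fitness evaluation.
``lga``  Lamarckian GA: ``ga`` plus Solis–Wets local search whose improved
         genomes are written back into the population.
``hga``  history-guided Lamarckian GA: elite-parent-preserving (CE)
         crossover, history-difference (ED) mutation, a BSP-tree
         non-revisiting archive consulted before every fitness evaluation,
         then local search — the full running-history loop.

A run terminates on whichever of the generation cap or the energy-evaluation
cap is reached first.  All randomness flows through one
``numpy.random.Generator`` seeded from the config and consumed in a fixed
order (selection, crossover cuts, mutation, archive redirects, local search),
so identical config + seed reproduces a bit-identical result.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np
import yaml

from .bsp import BSPTree
from .genome import GenomeSpace
from .operators import (
    HistoryArchive,
    Individual,
    cauchy_mutation,
    ce_crossover,
    ed_mutation,
    proportional_selection,
    solis_wets_search,
    two_point_crossover,
)
from .scoring import ObjectiveFunction

__all__ = ["RunConfig", "RunResult", "run", "run_batch", "ALGORITHMS"]

logger = logging.getLogger("gadock.engine")

ALGORITHMS = ("ga", "lga", "hga")

#: Default per-gene archive cell sizes for pose genomes: 0.25 Å translations,
#: 1/64 quaternion components, 2 degrees torsions.
POSE_ARCHIVE_RESOLUTION = {"translation": 0.25, "orientation": 1.0 / 64.0,
                           "torsion": 2.0}
#: Landscape genes default to 1/128 of the bound width per cell.
LANDSCAPE_ARCHIVE_CELLS = 128


@dataclass
class RunConfig:
    """Everything a run needs besides the objective itself.

    Defaults mirror the standard docking protocol (population 50, 27,000
    generations, 1.5e6 energy evaluations); tests and desk-scale experiments
    pass smaller caps.
    """

    algorithm: str = "hga"
    population_size: int = 50
    max_generations: int = 27_000
    max_evaluations: int = 1_500_000
    elite_fraction: float = 0.1
    beta: float = 0.1
    mutation_rate: float = 0.02
    mutation_scale: float = 0.05
    ls_fraction: float = 0.06
    ls_max_steps: int = 300
    ls_rho: float = 1.0
    ls_selection: str = "random"  # "random" (search-frequency) or "top"
    archive_enabled: bool = True
    archive_resolution: float | list[float] | None = None
    archive_local_search: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_generations <= 0 or self.max_evaluations <= 0:
            raise ValueError("both budget caps must be positive")

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs) -> "RunConfig":
        d = self.to_dict()
        d.update(kwargs)
        return RunConfig(**d)


@dataclass
class RunResult:
    """Outcome of one seeded run.

    ``trace`` holds the best-so-far energy at the end of each generation
    (monotone non-increasing; its last entry equals ``best_energy``).
    """

    algorithm: str
    seed: int
    best_genome: np.ndarray
    best_energy: float
    trace: list[float]
    evaluations: int
    generations: int
    redirects: int
    wall_time: float

    def to_dict(self, include_timing: bool = False) -> dict:
        d = {
            "algorithm": self.algorithm,
            "seed": self.seed,
            "best_genome": [float(v) for v in self.best_genome],
            "best_energy": float(self.best_energy),
            "trace": [float(v) for v in self.trace],
            "evaluations": int(self.evaluations),
            "generations": int(self.generations),
            "redirects": int(self.redirects),
        }
        if include_timing:
            d["wall_time"] = self.wall_time
        return d

    def to_json(self, include_timing: bool = False) -> str:
        """Canonical JSON (timing excluded by default so equal-seed runs are
        byte-identical)."""
        return json.dumps(self.to_dict(include_timing), sort_keys=True)


def default_archive_resolution(space: GenomeSpace) -> np.ndarray:
    """Per-gene cell sizes: pose-aware when the space carries pose structure."""
    widths = space.bounds.widths
    res = widths / LANDSCAPE_ARCHIVE_CELLS
    if space.quaternion is not None or space.torsions is not None:
        res = res.copy()
        pose_slices = {
            "translation": slice(0, 3),
            "orientation": space.quaternion,
            "torsion": space.torsions,
        }
        for kind, sl in pose_slices.items():
            if sl is not None:
                res[sl] = POSE_ARCHIVE_RESOLUTION[kind]
    return res


class _Budget:
    """Evaluation-budget bookkeeping shared across the loop phases."""

    def __init__(self, cap: int):
        self.cap = cap
        self.used = 0

    @property
    def remaining(self) -> int:
        return self.cap - self.used

    @property
    def exhausted(self) -> bool:
        return self.used >= self.cap


def run(config: RunConfig, objective: ObjectiveFunction,
        observer: Callable[[dict], None] | None = None) -> RunResult:
    """Execute one seeded optimization run.

    ``observer``, when given, is called once per generation with a snapshot
    dict (generation index, population genomes, elite records, best-so-far);
    it exists for audits and diagnostics and does not influence the run.
    """
    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    space = objective.space
    n = config.population_size
    budget = _Budget(config.max_evaluations)
    archive = HistoryArchive()
    counter_start = objective.n_evals

    tree: BSPTree | None = None
    if config.algorithm == "hga" and config.archive_enabled:
        res = (default_archive_resolution(space)
               if config.archive_resolution is None
               else np.broadcast_to(
                   np.asarray(config.archive_resolution, dtype=float),
                   (space.n_genes,)).copy())
        tree = BSPTree(space.bounds, res)

    def evaluate(ind: Individual) -> bool:
        """Score one individual; False when the budget ran out first."""
        if ind.fitness is not None:
            return True
        if budget.exhausted:
            return False
        ind.fitness = objective(ind.genome)
        budget.used += 1
        archive.observe(ind.genome, ind.fitness)
        return True

    def archive_filter(ind: Individual) -> None:
        if tree is None:
            return
        redirected, flag = tree.query_insert(ind.genome, rng)
        if flag:
            ind.genome = space.repair(redirected)
            ind.father = ind.mother = None

    ls_pre_eval = None
    if tree is not None and config.archive_local_search:
        def ls_pre_eval(vec: np.ndarray) -> np.ndarray:  # noqa: F811
            out, _ = tree.query_insert(vec, rng)
            return space.repair(out)

    # generation 0: random population
    population = [Individual(space.sample(rng)) for _ in range(n)]
    if tree is not None:
        for ind in population:
            archive_filter(ind)
    for ind in population:
        evaluate(ind)
    population = [ind for ind in population if ind.fitness is not None]

    trace: list[float] = [archive.best_fitness]
    generation = 0
    n_ls = max(1, math.ceil(config.ls_fraction * n))

    while (generation < config.max_generations and not budget.exhausted
           and population):
        generation += 1
        if config.algorithm == "hga":
            population = ce_crossover(population, archive,
                                      config.elite_fraction, rng,
                                      generation=generation)
            if observer is not None:
                observer({
                    "phase": "ce_crossover",
                    "generation": generation,
                    "population": [ind.genome.copy() for ind in population],
                    "elites": [r for r in archive.elites
                               if r.generation == generation],
                })
            for ind in population:
                ind.genome = ed_mutation(ind.genome, archive, space.bounds,
                                         config.beta, rng,
                                         rate=config.mutation_rate,
                                         space=space)
                ind.fitness = None
            for ind in population:
                archive_filter(ind)
                ind.fitness = None
        else:
            picks = proportional_selection(population, rng)
            children: list[Individual] = []
            for i in range(0, len(picks) - 1, 2):
                pa = population[picks[i]].genome
                pb = population[picks[i + 1]].genome
                ca, cb = two_point_crossover(pa, pb, rng)
                children.append(Individual(ca))
                children.append(Individual(cb))
            if len(picks) % 2 == 1:
                children.append(population[picks[-1]].copy())
            for ind in children:
                ind.genome = cauchy_mutation(ind.genome, space.bounds, rng,
                                             rate=config.mutation_rate,
                                             scale=config.mutation_scale,
                                             space=space)
                ind.fitness = None
            population = children[:n]

        for ind in population:
            if not evaluate(ind):
                break
        evaluated = [ind for ind in population if ind.fitness is not None]

        if config.algorithm in ("lga", "hga") and evaluated and not budget.exhausted:
            if config.ls_selection == "top":
                evaluated.sort(key=lambda ind: ind.fitness)
                chosen = evaluated[:n_ls]
            else:  # random subset, the AutoDock search-frequency convention
                idx = rng.choice(len(evaluated),
                                 size=min(n_ls, len(evaluated)), replace=False)
                chosen = [evaluated[j] for j in idx]
            for ind in chosen:
                if budget.exhausted:
                    break
                new_genome, new_fit, used = solis_wets_search(
                    ind.genome, objective, rng,
                    max_steps=config.ls_max_steps, rho=config.ls_rho,
                    f0=ind.fitness, max_evals=budget.remaining,
                    pre_eval=ls_pre_eval)
                budget.used += used
                if new_fit < ind.fitness:  # Lamarckian writeback
                    ind.genome = new_genome
                    ind.fitness = new_fit
                    ind.father = ind.mother = None
                    archive.observe(new_genome, new_fit)

        trace.append(archive.best_fitness)
        population = [ind for ind in population if ind.fitness is not None]
        if logger.isEnabledFor(logging.DEBUG) and population:
            fits = [ind.fitness for ind in population]
            logger.debug(
                "gen=%d best=%.6g mean=%.6g evals=%d redirects=%d",
                generation, archive.best_fitness, float(np.mean(fits)),
                budget.used, 0 if tree is None else tree.redirects)
        if observer is not None:
            observer({"phase": "generation_end", "generation": generation,
                      "best": archive.best_fitness, "evals": budget.used})

    assert objective.n_evals - counter_start == budget.used, \
        "objective counter drifted from engine accounting"
    return RunResult(
        algorithm=config.algorithm,
        seed=config.seed,
        best_genome=(archive.best if archive.best is not None
                     else population[0].genome if population
                     else np.zeros(space.n_genes)),
        best_energy=archive.best_fitness,
        trace=trace,
        evaluations=budget.used,
        generations=generation,
        redirects=0 if tree is None else tree.redirects,
        wall_time=time.perf_counter() - t0,
    )


def run_batch(config: RunConfig, objective: ObjectiveFunction,
              seeds: list[int]) -> list[RunResult]:
    """Independent seeded runs (fresh evaluation counter each), in seed order."""
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    results = []
    for s in seeds:
        obj = objective.fresh()
        results.append(run(config.replace(seed=int(s)), obj))
    return results
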