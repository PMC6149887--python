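"""Genetic and local-search operators.

Two operators carry the running-history idea:

* :func:`ce_crossover` — two-point crossover over a rank-selected mating pool,
  with the twist that the parents of each elite individual are preserved into
  the next population alongside the elite itself, so genomes that produced a
  top solution get further chances to recombine.
* :func:`ed_mutation` — per-gene mutation steered by the historic best
  (``M_opt``) and second-best (``M_sub``) solutions: with probability ``beta``
  a gene is resampled from its bounds (exploration), otherwise it moves by
  ``theta * (M_opt - M_sub) + delta * (M_opt - m)`` — a vector-addition step
  toward, and along, the historically good direction.

The module also carries the plain baselines (two-point crossover, Cauchy
mutation, rank-proportional selection) and the Solis–Wets adaptive local
search used for the Lamarckian writeback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .genome import GeneBounds, GenomeSpace

__all__ = [
    "Individual",
    "EliteRecord",
    "HistoryArchive",
    "two_point_crossover",
    "ce_crossover",
    "ed_mutation",
    "cauchy_mutation",
    "proportional_selection",
    "solis_wets_search",
]


@dataclass
class Individual:
    """A population member: genome, cached fitness, and crossover provenance."""

    genome: np.ndarray
    fitness: float | None = None
    father: np.ndarray | None = None
    mother: np.ndarray | None = None

    def copy(self) -> "Individual":
        return Individual(
            self.genome.copy(),
            self.fitness,
            None if self.father is None else self.father.copy(),
            None if self.mother is None else self.mother.copy(),
        )


@dataclass
class EliteRecord:
    """An elite individual with the parent genomes whose crossover made it.

    When an elite was never produced by crossover (e.g. it survived from the
    random initial population), both parents are recorded as copies of the
    elite itself.
    """

    genome: np.ndarray
    fitness: float
    father: np.ndarray
    mother: np.ndarray
    generation: int


class HistoryArchive:
    """Online record of the historic best and second-best distinct solutions.

    Updated once per energy evaluation; ``best`` is the lowest-energy genome
    ever evaluated, ``sub`` the lowest-energy genome distinct from it.  Elite
    records are appended per generation by the engine.
    """

    def __init__(self) -> None:
        self.best: np.ndarray | None = None
        self.best_fitness: float = math.inf
        self.sub: np.ndarray | None = None
        self.sub_fitness: float = math.inf
        self.elites: list[EliteRecord] = []

    @property
    def ready(self) -> bool:
        """True once both historic solutions exist (ED branch 2 is usable)."""
        return self.best is not None and self.sub is not None

    def observe(self, genome: np.ndarray, fitness: float) -> None:
        if fitness < self.best_fitness or self.best is None:
            if self.best is not None and not np.array_equal(genome, self.best):
                self.sub = self.best
                self.sub_fitness = self.best_fitness
            self.best = genome.copy()
            self.best_fitness = float(fitness)
        elif fitness < self.sub_fitness and not np.array_equal(genome, self.best):
            self.sub = genome.copy()
            self.sub_fitness = float(fitness)


def two_point_crossover(parent_a: np.ndarray, parent_b: np.ndarray,
                        rng: np.random.Generator,
                        cuts: tuple[int, int] | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Swap the gene segment between two cut points.

    Cut points are drawn from ``0..n`` inclusive, so ``(0, n)`` exchanges the
    whole genome.  The per-locus multiset of gene values across the pair is
    conserved.
    """
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parents must have equal genome lengths")
    n = a.size
    if cuts is None:
        c1, c2 = sorted(rng.integers(0, n + 1, size=2))
    else:
        c1, c2 = sorted(cuts)
    child_a = a.copy()
    child_b = b.copy()
    child_a[c1:c2] = b[c1:c2]
    child_b[c1:c2] = a[c1:c2]
    return child_a, child_b


def proportional_selection(population: list[Individual],
                           rng: np.random.Generator,
                           n_picks: int | None = None) -> list[int]:
    """Fitness-proportional mating selection via linear ranking.

    Lower energy is fitter.  Raw energies are mapped to weights through their
    rank (best rank -> weight ``n``, worst -> ``1``, ties averaged), which
    keeps selection pressure well defined for negative or badly scaled
    energies.  Returns selected indices.
    """
    n = len(population)
    if n == 0:
        raise ValueError("empty population")
    fitnesses = np.array([ind.fitness for ind in population], dtype=float)
    if np.any(np.isnan(fitnesses)):
        raise ValueError("selection requires evaluated individuals")
    ranks = rankdata(fitnesses, method="average")  # 1 = lowest energy = best
    weights = n - ranks + 1.0
    p = weights / weights.sum()
    k = n if n_picks is None else n_picks
    return list(rng.choice(n, size=k, p=p))


def ce_crossover(population: list[Individual], archive: HistoryArchive,
                 elite_fraction: float, rng: np.random.Generator,
                 generation: int = 0) -> list[Individual]:
    """Elite-parent-preserving crossover.

    Rank-selects a mating pool, applies pairwise two-point crossover, then
    guarantees that each of the ``ceil(elite_fraction * n)`` best current
    individuals enters the next population together with the two parent
    genomes whose crossover produced it.  Population size is restored to
    ``n`` by trimming surplus (unevaluated) crossover children.  Elite records
    are appended to ``archive.elites``.
    """
    n = len(population)
    if n < 2:
        raise ValueError("ce_crossover needs a population of at least 2")
    if not 0.0 < elite_fraction <= 0.5:
        raise ValueError("elite_fraction must lie in (0, 0.5]")

    n_elites = math.ceil(elite_fraction * n)
    order = sorted(range(n), key=lambda i: (population[i].fitness, i))
    elite_block: list[Individual] = []
    for i in order[:n_elites]:
        e = population[i]
        father = e.father if e.father is not None else e.genome
        mother = e.mother if e.mother is not None else e.genome
        archive.elites.append(
            EliteRecord(e.genome.copy(), float(e.fitness), father.copy(),
                        mother.copy(), generation)
        )
        elite_block.append(Individual(e.genome.copy(), e.fitness,
                                      e.father, e.mother))
        elite_block.append(Individual(father.copy()))
        elite_block.append(Individual(mother.copy()))

    picks = proportional_selection(population, rng)
    children: list[Individual] = []
    for i in range(0, n - 1, 2):
        pa = population[picks[i]].genome
        pb = population[picks[i + 1]].genome
        ca, cb = two_point_crossover(pa, pb, rng)
        children.append(Individual(ca, father=pa.copy(), mother=pb.copy()))
        children.append(Individual(cb, father=pa.copy(), mother=pb.copy()))
    if len(picks) % 2 == 1:  # odd n: last pick passes through unchanged
        children.append(population[picks[-1]].copy())

    next_pop = elite_block + children
    return next_pop[:n] if len(next_pop) >= n else next_pop + children[: n - len(next_pop)]


def ed_mutation(genome: np.ndarray, archive: HistoryArchive, bounds: GeneBounds,
                beta: float, rng: np.random.Generator,
                rate: float = 1.0,
                space: GenomeSpace | None = None,
                theta: np.ndarray | None = None,
                delta: np.ndarray | None = None) -> np.ndarray:
    """History-difference mutation, applied per gene.

    Each gene mutates with probability ``rate`` (1 = the bare operator; the
    engine passes the standard per-gene mutation rate, so the history update
    replaces the baseline mutation kernel rather than rewriting every gene
    each generation).  A mutating gene draws ``theta, delta ~ U(0,1)``: if
    ``theta < beta`` the gene is resampled as ``lower + theta * (upper -
    lower)`` (with ``beta = 1`` this is exact uniform reinitialization),
    otherwise it moves by ``theta * (M_opt - M_sub) + delta * (M_opt - m)`` —
    along the historic-improvement vector and toward the historic best.
    While the archive holds fewer than two distinct solutions (first
    generation), every mutating gene takes the resampling branch.  The result
    is clipped to bounds and, when a ``space`` is given, repaired (quaternion
    renormalized, torsions wrapped).

    ``theta``/``delta`` may be injected (arrays broadcastable to the genome)
    for deterministic verification; both are always drawn/consumed so the RNG
    stream does not depend on the branch taken.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    m = np.asarray(genome, dtype=float)
    d = m.size
    hit = np.ones(d, dtype=bool) if rate >= 1.0 else rng.uniform(size=d) < rate
    th = rng.uniform(size=d) if theta is None else np.broadcast_to(
        np.asarray(theta, dtype=float), (d,)).copy()
    de = rng.uniform(size=d) if delta is None else np.broadcast_to(
        np.asarray(delta, dtype=float), (d,)).copy()

    resample = bounds.lower + th * (bounds.upper - bounds.lower)
    if archive.ready:
        step = m + th * (archive.best - archive.sub) + de * (archive.best - m)
        out = np.where(th < beta, resample, step)
    else:
        out = resample
    out = np.where(hit, out, m)
    if space is not None:
        return space.repair(out)
    return bounds.clip(out)


def cauchy_mutation(genome: np.ndarray, bounds: GeneBounds,
                    rng: np.random.Generator, rate: float = 0.02,
                    scale: float = 0.05,
                    space: GenomeSpace | None = None) -> np.ndarray:
    """Baseline GA/LGA mutation: per-gene Cauchy kicks.

    Each gene mutates with probability ``rate``; the kick is a standard
    Cauchy deviate scaled by ``scale`` times the gene's bound width (heavy
    tails give occasional long jumps, the AutoDock LGA convention).
    """
    m = np.asarray(genome, dtype=float).copy()
    d = m.size
    hit = rng.uniform(size=d) < rate
    kicks = rng.standard_cauchy(size=d) * scale * bounds.widths
    m[hit] += kicks[hit]
    if space is not None:
        return space.repair(m)
    return bounds.clip(m)


def solis_wets_search(genome: np.ndarray, objective, rng: np.random.Generator,
                      max_steps: int = 300, rho: float = 1.0,
                      rho_lower: float = 1e-3,
                      success_limit: int = 4, failure_limit: int = 4,
                      step_scale: float = 0.05,
                      f0: float | None = None,
                      max_evals: int | None = None,
                      pre_eval=None) -> tuple[np.ndarray, float, int]:
    """Solis–Wets adaptive random local search with Lamarckian writeback.

    Trial moves are Gaussian with per-gene deviation ``rho * step_scale *
    bound width`` plus an exponentially smoothed bias toward recent successes;
    a failed move is retried in the opposite direction.  ``rho`` doubles after
    ``success_limit`` consecutive successes and halves after ``failure_limit``
    consecutive failures; the search stops when ``rho`` underflows
    ``rho_lower``, the step cap or the evaluation cap is hit.

    Returns ``(best genome, best energy, evaluations used)``; the returned
    energy never exceeds the starting energy (moves are accepted only on
    strict improvement).  ``pre_eval`` optionally transforms each candidate
    before evaluation (used to route probes through the non-revisiting
    archive).
    """
    space: GenomeSpace = objective.space
    x = space.repair(np.asarray(genome, dtype=float))
    used = 0
    if f0 is None:
        if max_evals is not None and max_evals < 1:
            return x, math.inf, 0
        fx = objective(x)
        used += 1
    else:
        fx = float(f0)
    if max_steps <= 0:
        return x, fx, used

    sigma = step_scale * space.bounds.widths
    bias = np.zeros_like(x)
    successes = failures = 0
    for _ in range(max_steps):
        if max_evals is not None and used >= max_evals:
            break
        dx = rng.normal(size=x.size) * rho * sigma
        cand = space.repair(x + bias + dx)
        if pre_eval is not None:
            cand = pre_eval(cand)
        fc = objective(cand)
        used += 1
        if fc < fx:
            x, fx = cand, fc
            bias = 0.2 * bias + 0.4 * dx
            successes += 1
            failures = 0
        else:
            accepted = False
            if max_evals is None or used < max_evals:
                cand2 = space.repair(x - bias - dx)
                if pre_eval is not None:
                    cand2 = pre_eval(cand2)
                fc2 = objective(cand2)
                used += 1
                if fc2 < fx:
                    x, fx = cand2, fc2
                    bias = bias - 0.4 * dx
                    successes += 1
                    failures = 0
                    accepted = True
            if not accepted:
                failures += 1
                successes = 0
                bias *= 0.5
        if successes >= success_limit:
            rho *= 2.0
            successes = 0
        elif failures >= failure_limit:
            rho *= 0.5
            failures = 0
        if rho < rho_lower:
            break
    return x, fx, used
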