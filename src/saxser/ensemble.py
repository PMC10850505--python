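"""Ensemble selection against a SAXS curve (the EOM step of the refinement).

Given a pool of conformers with cached profiles on the experimental q grid,
find the subset of ``n_es`` distinct members whose average profile minimizes
the scale-fitted reduced χ².  Small problems are solved exhaustively; larger
ones by a seeded genetic algorithm over distinct-index chromosomes whose
fitness is −χ² with the scale μ optimized analytically inside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

from .model_io import ConformerModel, ScatteringCurve
from .saxs import FitResult, SaxsError, chi2, compute_profile, ensemble_profile

__all__ = [
    "ConformerPool",
    "EnsembleSelection",
    "GaConfig",
    "pool_profiles",
    "select_ensemble_exhaustive",
    "select_ensemble_ga",
]

EXHAUSTIVE_CAP = 2_000_000


class SelectionError(ValueError):
    pass


@dataclass
class ConformerPool:
    """Conformers plus per-member profiles cached on one q grid."""

    members: list[ConformerModel]
    profiles: list[ScatteringCurve] | None = None

    def __post_init__(self) -> None:
        # a prefix cache (pool grown since profiling) is allowed; an excess is not
        if self.profiles is not None and len(self.profiles) > len(self.members):
            raise SelectionError("more cached profiles than members")

    def __len__(self) -> int:
        return len(self.members)

    def profile_matrix(self) -> np.ndarray:
        if self.profiles is None or len(self.profiles) != len(self.members):
            raise SelectionError("profiles not cached; call pool_profiles first")
        return np.stack([p.I for p in self.profiles])


@dataclass
class EnsembleSelection:
    """A distinct-index sub-ensemble with uniform weights and its fit."""

    indices: tuple[int, ...]
    fit: FitResult

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise SelectionError("ensemble indices must be distinct")
        self.indices = tuple(sorted(self.indices))

    @property
    def N(self) -> int:
        return len(self.indices)

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.N, 1.0 / self.N)


@dataclass
class GaConfig:
    """Genetic-algorithm hyperparameters; the seed is mandatory."""

    seed: int
    population: int = 100
    generations: int = 200
    crossover_rate: float = 0.5
    mutation_rate: float = 0.1
    elite: int = 10

    def __post_init__(self) -> None:
        if self.population <= 0 or self.generations <= 0 or self.elite <= 0:
            raise SelectionError("population, generations and elite must be positive")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise SelectionError("rates must lie in [0, 1]")


def pool_profiles(pool: ConformerPool, q_grid: np.ndarray) -> ConformerPool:
    """Cache (idempotently) each member's Debye profile on ``q_grid``."""
    if not pool.members:
        raise SelectionError("empty pool")
    q = np.asarray(q_grid, float)
    if pool.profiles is not None and np.array_equal(pool.profiles[0].q, q):
        if len(pool.profiles) == len(pool.members):
            return pool
        cached = pool.profiles
    else:
        cached = []
    profiles = list(cached) + [
        compute_profile(m, q) for m in pool.members[len(cached):]
    ]
    pool.profiles = profiles
    return pool


def _score_subsets(
    P: np.ndarray, idx: np.ndarray, exp: ScatteringCurve
) -> tuple[np.ndarray, np.ndarray]:
    """χ² and μ for each row of subset indices, vectorized.

    ``P`` is the (M, K) profile matrix, ``idx`` an (S, n_es) index array.
    """
    I_calc = P[idx].mean(axis=1)  # (S, K)
    inv_var = 1.0 / exp.sigma**2
    mu = (I_calc * exp.I * inv_var).sum(axis=1) / (I_calc**2 * inv_var).sum(axis=1)
    resid = (mu[:, None] * I_calc - exp.I) / exp.sigma
    K = len(exp.q)
    return (resid**2).sum(axis=1) / (K - 1), mu


def _selection_from_indices(
    pool: ConformerPool, exp: ScatteringCurve, indices: tuple[int, ...]
) -> EnsembleSelection:
    avg = ensemble_profile([pool.profiles[i] for i in indices])
    return EnsembleSelection(indices=indices, fit=chi2(avg, exp))


def select_ensemble_exhaustive(
    pool: ConformerPool, exp: ScatteringCurve, n_es: int, cap: int = EXHAUSTIVE_CAP
) -> EnsembleSelection:
    """Global χ² minimum over all distinct-index subsets of size ``n_es``.

    Ties are broken toward the lexicographically smallest sorted index list.
    """
    M = len(pool)
    if not 1 <= n_es <= M:
        raise SelectionError(f"n_es={n_es} outside [1, {M}]")
    if exp.sigma is None:
        raise SaxsError("experimental curve must carry uncertainties")
    n_subsets = comb(M, n_es)
    if n_subsets > cap:
        raise SelectionError(
            f"C({M},{n_es}) = {n_subsets} exceeds the exhaustive cap {cap}; "
            "use select_ensemble_ga"
        )
    pool = pool_profiles(pool, exp.q)
    P = pool.profile_matrix()
    best_chi2 = np.inf
    best_idx: tuple[int, ...] | None = None
    chunk = 4096
    it = itertools.combinations(range(M), n_es)
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        scores, _ = _score_subsets(P, np.array(block), exp)
        k = int(np.argmin(scores))
        # combinations() emits lexicographic order, so strict < keeps the
        # lexicographically smallest subset on ties
        if scores[k] < best_chi2:
            best_chi2 = float(scores[k])
            best_idx = block[k]
    return _selection_from_indices(pool, exp, best_idx)


def _repair(child: np.ndarray, M: int, rng: np.random.Generator) -> np.ndarray:
    """Replace duplicate genes with random unused indices."""
    seen: set[int] = set()
    dupes: list[int] = []
    for pos, g in enumerate(child):
        if g in seen:
            dupes.append(pos)
        seen.add(int(g))
    if dupes:
        unused = np.setdiff1d(np.arange(M), child, assume_unique=False)
        repl = rng.choice(unused, size=len(dupes), replace=False)
        child[dupes] = repl
    return child


def select_ensemble_ga(
    pool: ConformerPool,
    exp: ScatteringCurve,
    n_es: int,
    cfg: GaConfig,
    seed_chromosomes: list[tuple[int, ...]] | None = None,
) -> EnsembleSelection:
    """Genetic-algorithm minimization of χ² over distinct-index subsets.

    Elitism makes the per-generation best fitness non-decreasing, and the
    run is a pure function of ``cfg.seed``.  ``seed_chromosomes`` may inject
    known-good subsets into the initial population (e.g. the previous
    refinement cycle's winner).
    """
    M = len(pool)
    if n_es > M:
        raise SelectionError(f"n_es={n_es} exceeds pool size {M}")
    if exp.sigma is None:
        raise SaxsError("experimental curve must carry uncertainties")
    pool = pool_profiles(pool, exp.q)
    P = pool.profile_matrix()
    rng = np.random.default_rng(cfg.seed)

    popsize = cfg.population
    population = np.stack(
        [rng.choice(M, size=n_es, replace=False) for _ in range(popsize)]
    )
    if seed_chromosomes:
        for row, chrom in enumerate(seed_chromosomes[:popsize]):
            if len(chrom) == n_es and len(set(chrom)) == n_es and max(chrom) < M:
                population[row] = np.array(chrom)

    def ranked(pop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        scores, _ = _score_subsets(P, pop, exp)
        # deterministic tie-break: sort by (score, sorted index tuple)
        keys = [tuple(sorted(map(int, row))) for row in pop]
        order = sorted(range(len(pop)), key=lambda i: (scores[i], keys[i]))
        return pop[order], scores[np.array(order)]

    population, scores = ranked(population)
    for _ in range(cfg.generations):
        elite = population[: cfg.elite].copy()
        children = []
        while len(children) < popsize - cfg.elite:
            i, j = rng.integers(0, popsize, size=2)
            pa, pb = population[i], population[j]
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(n_es) < 0.5
                child = np.where(mask, pa, pb).copy()
                child = _repair(child, M, rng)
            else:
                child = pa.copy()
            mut = rng.random(n_es) < cfg.mutation_rate
            if mut.any():
                unused = np.setdiff1d(np.arange(M), child)
                n_mut = min(int(mut.sum()), len(unused))
                if n_mut:
                    positions = np.flatnonzero(mut)[:n_mut]
                    child[positions] = rng.choice(unused, size=n_mut, replace=False)
            children.append(child)
        population = np.vstack([elite, np.stack(children)])
        population, scores = ranked(population)

    best = tuple(sorted(int(g) for g in population[0]))
    return _selection_from_indices(pool, exp, best)
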