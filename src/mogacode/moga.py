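"""NSGA-II over the restrictive genetic-code space.

The optimiser evolves a population of amino-acid permutations (restrictive
codes) under two or more minimised objectives.  Each generation, offspring
are produced by tournament selection under the crowded comparison followed
by a probabilistic swap mutation (no crossover), and the next population is
the best whole dominance layers of parents plus offspring, with the final
layer truncated by crowding distance — the standard elitist mu+lambda
environmental selection.  Independent runs are merged into a single
nondominated front.

Populations are carried internally as (M, 20) integer arrays so that
evaluation, nondominated sorting and selection are vectorised; a full run
at the reference settings (population 100, 1000 generations) takes a few
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .codespace import GeneticCode, random_codes
from .scoring import ObjectiveSpec, evaluate_many

__all__ = [
    "Individual",
    "GAConfig",
    "ParetoFront",
    "dominates",
    "fast_nondominated_sort",
    "nondominated_layers",
    "crowding_distance",
    "tournament_select",
    "swap_mutate",
    "nsga2_run",
    "optimize",
    "merge_fronts",
]


@dataclass(frozen=True)
class Individual:
    """One evaluated code; rank/crowding are valid only after sorting."""

    code: GeneticCode
    objectives: tuple[float, ...]
    rank: int | None = None
    crowding: float | None = None
    run_id: int | None = None
    generation: int | None = None


@dataclass(frozen=True)
class GAConfig:
    """NSGA-II run configuration.

    Defaults are the reference experimental settings: population 100,
    1000 generations, swap probability 0.5 per individual per generation,
    tournament pool 3% of the population (minimum 2), 10 independent runs.
    """

    specs: tuple[ObjectiveSpec, ...]
    population_size: int = 100
    generations: int = 1000
    swap_probability: float = 0.5
    tournament_fraction: float = 0.03
    runs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if not 0.0 <= self.swap_probability <= 1.0:
            raise ValueError("swap_probability must be in [0, 1]")
        if self.generations < 0 or self.runs < 1:
            raise ValueError("generations must be >= 0 and runs >= 1")
        if not self.specs:
            raise ValueError("at least one objective is required")

    @property
    def tournament_size(self) -> int:
        return max(2, round(self.tournament_fraction * self.population_size))

    def run_seed(self, run_index: int) -> int:
        """Deterministic sub-seed for one run, derived from the master seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(run_index,))
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ParetoFront:
    """A mutually nondominated set of evaluated codes with provenance."""

    members: tuple[Individual, ...]
    specs: tuple[ObjectiveSpec, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        objs = [m.objectives for m in self.members]
        for i, a in enumerate(objs):
            for b in objs[i + 1:]:
                if dominates(a, b) or dominates(b, a):
                    raise ValueError("front members must be mutually nondominated")

    def __len__(self) -> int:
        return len(self.members)

    def objective_matrix(self) -> np.ndarray:
        return np.array([m.objectives for m in self.members], dtype=float)


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Pareto dominance for minimisation: a <= b everywhere, < somewhere."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("objective vectors must have equal length")
    return bool(np.all(a <= b) and np.any(a < b))


def nondominated_layers(objectives: np.ndarray) -> list[np.ndarray]:
    """Partition row indices of an (n, k) objective matrix into dominance layers.

    Layer 0 holds the rows dominated by nobody; layer r holds rows dominated
    only by earlier layers.  Vectorised via the full n x n domination matrix.
    """
    F = np.asarray(objectives, dtype=float)
    n = F.shape[0]
    if n == 0:
        return []
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    dom = le & lt  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    assigned = np.zeros(n, dtype=bool)
    layers: list[np.ndarray] = []
    while not assigned.all():
        current = (n_dominators == 0) & ~assigned
        idx = np.flatnonzero(current)
        layers.append(idx)
        assigned[idx] = True
        n_dominators = n_dominators - dom[idx].sum(axis=0)
    return layers


def fast_nondominated_sort(population: Sequence[Individual]) -> list[list[Individual]]:
    """Sort individuals into dominance layers, assigning 1-based ranks."""
    F = np.array([ind.objectives for ind in population], dtype=float)
    out: list[list[Individual]] = []
    for rank0, idx in enumerate(nondominated_layers(F)):
        out.append([replace(population[i], rank=rank0 + 1) for i in idx])
    return out


def crowding_distance(objectives: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distances for one layer's (m, k) objective matrix.

    Per objective the layer is sorted, both extremes get +inf, and each
    interior member accrues the gap between its neighbours normalised by
    the objective's span within the layer.
    """
    F = np.atleast_2d(np.asarray(objectives, dtype=float))
    m = F.shape[0]
    if m == 0:
        raise ValueError("crowding_distance needs a nonempty layer")
    dist = np.zeros(m)
    if m <= 2:
        return np.full(m, np.inf)
    for j in range(F.shape[1]):
        order = np.argsort(F[:, j], kind="stable")
        col = F[order, j]
        span = col[-1] - col[0]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            dist[order[1:-1]] += (col[2:] - col[:-2]) / span
    return dist


def _crowded_winner(
    ranks: np.ndarray,
    crowds: np.ndarray,
    pools: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Winner of each row of ``pools`` under (rank asc, crowding desc, random)."""
    r = ranks[pools].astype(float)
    c = crowds[pools]
    tie = rng.random(pools.shape)
    best_r = r == r.min(axis=1, keepdims=True)
    key2 = np.where(best_r, -c, np.inf)
    best_c = key2 == key2.min(axis=1, keepdims=True)
    key3 = np.where(best_c, tie, np.inf)
    return pools[np.arange(pools.shape[0]), key3.argmin(axis=1)]


def tournament_select(
    population: Sequence[Individual],
    rng: np.random.Generator,
    pool_size: int = 2,
) -> Individual:
    """One tournament under the crowded comparison.

    Draws ``pool_size`` distinct individuals uniformly; lower rank wins,
    ties go to larger crowding distance, remaining ties are broken
    uniformly at random.  Requires ranks and crowding to be assigned.
    """
    if pool_size > len(population):
        raise ValueError("tournament pool larger than population")
    ranks = np.array(
        [np.nan if ind.rank is None else ind.rank for ind in population], dtype=float
    )
    crowds = np.array(
        [np.nan if ind.crowding is None else ind.crowding for ind in population],
        dtype=float,
    )
    if np.isnan(ranks).any() or np.isnan(crowds).any():
        raise ValueError("population must be sorted (ranks and crowding set)")
    pool = rng.choice(len(population), size=pool_size, replace=False)
    winner = _crowded_winner(ranks, crowds, pool[None, :], rng)[0]
    return population[int(winner)]


def swap_mutate(code: GeneticCode, rng: np.random.Generator) -> GeneticCode:
    """Exchange the amino acids of two uniformly chosen distinct blocks."""
    i = int(rng.integers(20))
    j = int(rng.integers(19))
    if j >= i:
        j += 1
    return code.swap(i, j)


def _rank_and_crowd(F: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    layers = nondominated_layers(F)
    ranks = np.empty(F.shape[0], dtype=np.int64)
    crowds = np.empty(F.shape[0])
    for rank0, idx in enumerate(layers):
        ranks[idx] = rank0 + 1
        crowds[idx] = crowding_distance(F[idx])
    return ranks, crowds, layers


def _environmental_selection(
    F: np.ndarray, target: int
) -> np.ndarray:
    """Indices of the survivors of mu+lambda truncation on objectives ``F``."""
    layers = nondominated_layers(F)
    chosen: list[np.ndarray] = []
    room = target
    for idx in layers:
        if len(idx) <= room:
            chosen.append(idx)
            room -= len(idx)
            if room == 0:
                break
        else:
            crowd = crowding_distance(F[idx])
            # stable deterministic truncation: crowding desc, then
            # objective-lexicographic, then index
            obj_keys = tuple(F[idx, j] for j in reversed(range(F.shape[1])))
            order = np.lexsort(obj_keys + (-crowd,))
            chosen.append(idx[order[:room]])
            break
    return np.concatenate(chosen)


def nsga2_run(config: GAConfig, run_index: int = 0) -> ParetoFront:
    """One NSGA-II run; returns the final population's first layer.

    Fully reproducible from ``config.seed`` and ``run_index``.  With
    ``generations=0`` the front is simply the nondominated subset of the
    random initial population.
    """
    rng = np.random.default_rng(config.run_seed(run_index))
    M = config.population_size
    P = random_codes(M, rng)
    F = evaluate_many(P, config.specs)
    born = np.zeros(M, dtype=np.int64)

    for gen in range(config.generations):
        ranks, crowds, _ = _rank_and_crowd(F)
        # parent selection: M tournaments, pools drawn without replacement
        pools = rng.permuted(np.tile(np.arange(M), (M, 1)), axis=1)[
            :, : config.tournament_size
        ]
        parents = _crowded_winner(ranks, crowds, pools, rng)
        Q = P[parents].copy()
        q_born = born[parents].copy()
        # swap mutation, at most once per offspring
        mutate = rng.random(M) < config.swap_probability
        i = rng.integers(0, 20, size=M)
        j = rng.integers(0, 19, size=M)
        j = np.where(j >= i, j + 1, j)
        rows = np.flatnonzero(mutate)
        Q[rows, i[rows]], Q[rows, j[rows]] = Q[rows, j[rows]], Q[rows, i[rows]]
        q_born[rows] = gen + 1
        FQ = evaluate_many(Q, config.specs)

        R = np.vstack([P, Q])
        FR = np.vstack([F, FQ])
        r_born = np.concatenate([born, q_born])
        survivors = _environmental_selection(FR, M)
        new_best = FR[survivors].min(axis=0)
        old_best = F.min(axis=0)
        # elitism: per-objective bests can never regress under mu+lambda
        assert np.all(new_best <= old_best + 1e-12)
        P, F, born = R[survivors], FR[survivors], r_born[survivors]

    first_layer = nondominated_layers(F)[0]
    members: list[Individual] = []
    seen: set[tuple[int, ...]] = set()
    for idx in first_layer:
        key = tuple(int(v) for v in P[idx])
        if key in seen:
            continue
        seen.add(key)
        members.append(
            Individual(
                code=GeneticCode.from_indices(P[idx]),
                objectives=tuple(float(v) for v in F[idx]),
                rank=1,
                crowding=None,
                run_id=run_index,
                generation=int(born[idx]),
            )
        )
    members.sort(key=lambda m: m.objectives)
    return ParetoFront(tuple(members), config.specs)


def optimize(config: GAConfig) -> ParetoFront:
    """Run ``config.runs`` independent NSGA-II runs and merge their fronts."""
    fronts = [nsga2_run(config, r) for r in range(config.runs)]
    return merge_fronts(fronts)


def merge_fronts(fronts: Iterable[ParetoFront]) -> ParetoFront:
    """Union of fronts, duplicates removed, filtered to the nondominated set.

    All fronts must share the same objective specs; the result is ordered
    lexicographically by objective values.
    """
    fronts = list(fronts)
    if not fronts:
        raise ValueError("no fronts to merge")
    specs = fronts[0].specs
    if any(f.specs != specs for f in fronts):
        raise ValueError("cannot merge fronts evaluated under different objectives")
    pool: list[Individual] = []
    seen: set[tuple[str, ...]] = set()
    for front in fronts:
        for member in front.members:
            key = member.code.assignment
            if key not in seen:
                seen.add(key)
                pool.append(member)
    F = np.array([m.objectives for m in pool], dtype=float)
    keep = nondominated_layers(F)[0]
    members = sorted((pool[i] for i in keep), key=lambda m: m.objectives)
    return ParetoFront(tuple(members), specs)
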