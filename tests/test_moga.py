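"""NSGA-II machinery: dominance, sorting, crowding, selection, runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mogacode import (
    GAConfig,
    GeneticCode,
    Individual,
    ParetoFront,
    canonical_code,
    crowding_distance,
    dominates,
    fast_nondominated_sort,
    merge_fronts,
    nsga2_run,
    parse_objectives,
    random_code,
    swap_mutate,
    tournament_select,
)
from mogacode.codespace import AMINO_ACIDS, random_codes
from mogacode.moga import nondominated_layers
from mogacode.scoring import evaluate_many


def naive_peeling_layers(F):
    """Oracle: repeatedly remove the nondominated subset."""
    remaining = list(range(len(F)))
    layers = []
    while remaining:
        layer = [
            i
            for i in remaining
            if not any(dominates(F[j], F[i]) for j in remaining if j != i)
        ]
        layers.append(sorted(layer))
        remaining = [i for i in remaining if i not in layer]
    return layers


def crowding_oracle_2d(F):
    """Direct reimplementation of two-objective crowding distance."""
    m = len(F)
    if m <= 2:
        return np.full(m, np.inf)
    d = np.zeros(m)
    for j in range(2):
        order = sorted(range(m), key=lambda i: F[i][j])
        span = F[order[-1]][j] - F[order[0]][j]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0:
            for pos in range(1, m - 1):
                d[order[pos]] += (F[order[pos + 1]][j] - F[order[pos - 1]][j]) / span
    return d


class TestDominance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((1, 2), (2, 3), True), ((2, 3), (1, 2), False),
         ((1, 3), (3, 1), False), ((3, 1), (1, 3), False),
         ((1, 2), (1, 2), False), ((1, 2), (1, 3), True),
         # a front member that trades volume for polarity does not
         # dominate the canonical (5.19, 2266.13) point
         ((5.380, 1550.0), (5.19, 2266.13), False)],
    )
    def test_definition(self, a, b, expected):
        assert dominates(a, b) is expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dominates((1, 2), (1, 2, 3))

    @given(
        a=st.tuples(st.integers(0, 5), st.integers(0, 5)),
        b=st.tuples(st.integers(0, 5), st.integers(0, 5)),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, a, b):
        assert not (dominates(a, b) and dominates(b, a))


class TestNondominatedSort:
    def test_identical_vectors_single_layer(self):
        F = np.ones((7, 2))
        layers = nondominated_layers(F)
        assert len(layers) == 1 and len(layers[0]) == 7

    def test_strict_chain_gives_singleton_layers(self):
        F = np.array([[k, k] for k in range(5)], dtype=float)
        layers = nondominated_layers(F)
        assert [list(l) for l in layers] == [[0], [1], [2], [3], [4]]

    def test_matches_peeling_oracle(self, rng):
        for n in (10, 60, 200):
            F = rng.integers(0, 12, size=(n, 2)).astype(float)
            got = [sorted(l) for l in nondominated_layers(F)]
            assert got == naive_peeling_layers(F)

    def test_individual_wrapper_assigns_ranks(self, rng):
        pop = [
            Individual(code=random_code(rng), objectives=(float(i % 3), float(i % 5)))
            for i in range(20)
        ]
        layers = fast_nondominated_sort(pop)
        for rank0, layer in enumerate(layers):
            assert all(ind.rank == rank0 + 1 for ind in layer)
        assert sum(len(l) for l in layers) == 20


class TestCrowding:
    def test_tiny_layers_all_infinite(self):
        assert np.isinf(crowding_distance(np.array([[1.0, 2.0]]))).all()
        assert np.isinf(crowding_distance(np.array([[1.0, 2.0], [2.0, 1.0]]))).all()

    def test_identical_vectors_interior_zero(self):
        d = crowding_distance(np.ones((5, 2)))
        assert np.isinf(d).sum() >= 2
        assert (d[~np.isinf(d)] == 0).all()

    def test_matches_direct_reimplementation(self, rng):
        F = rng.random((50, 2))
        assert np.allclose(crowding_distance(F), crowding_oracle_2d(F))


class TestTournament:
    def _sorted_population(self, rng, ranks_crowds):
        return [
            Individual(
                code=random_code(rng),
                objectives=(float(r), float(r)),
                rank=r,
                crowding=c,
            )
            for r, c in ranks_crowds
        ]

    def test_lower_rank_wins(self, rng):
        pop = self._sorted_population(rng, [(1, 0.5), (3, np.inf)])
        winner = tournament_select(pop, rng, pool_size=2)
        assert winner.rank == 1

    def test_crowding_breaks_rank_ties(self, rng):
        pop = self._sorted_population(rng, [(1, np.inf), (1, 0.2)])
        winner = tournament_select(pop, rng, pool_size=2)
        assert winner.crowding == np.inf

    def test_pool_larger_than_population_rejected(self, rng):
        pop = self._sorted_population(rng, [(1, np.inf)])
        with pytest.raises(ValueError):
            tournament_select(pop, rng, pool_size=2)

    def test_unsorted_population_rejected(self, rng):
        pop = [Individual(code=random_code(rng), objectives=(1.0, 1.0))]
        with pytest.raises(ValueError):
            tournament_select(pop, rng, pool_size=1)

    def test_selection_pressure(self, rng):
        """Layer-1 members win more often than their population share."""
        pop = self._sorted_population(
            rng, [(1, np.inf)] * 5 + [(2, np.inf)] * 15
        )
        wins = sum(
            tournament_select(pop, rng, pool_size=3).rank == 1 for _ in range(2000)
        )
        assert wins / 2000 > 5 / 20


class TestSwap:
    def test_swap_is_involution(self, canonical):
        assert canonical.swap(3, 11).swap(3, 11) == canonical

    def test_mutation_changes_exactly_two_positions(self, canonical, rng):
        for _ in range(50):
            mutant = swap_mutate(canonical, rng)
            diffs = sum(
                a != b for a, b in zip(mutant.assignment, canonical.assignment)
            )
            assert diffs == 2
            assert sorted(mutant.assignment) == sorted(AMINO_ACIDS)

    def test_pair_choice_uniform(self, canonical, rng):
        """All 190 unordered block pairs occur at ~ equal frequency."""
        from scipy.stats import chisquare

        counts: dict[tuple[int, int], int] = {}
        for _ in range(10_000):
            mutant = swap_mutate(canonical, rng)
            changed = tuple(
                k
                for k in range(20)
                if mutant.assignment[k] != canonical.assignment[k]
            )
            counts[changed] = counts.get(changed, 0) + 1
        assert len(counts) == 190
        assert chisquare(list(counts.values())).pvalue > 1e-4


class TestRuns:
    CFG = dict(specs=parse_objectives("ms:pr,ms:hi"), population_size=40)

    def test_zero_generations_returns_initial_nondominated_subset(self):
        config = GAConfig(generations=0, seed=5, **self.CFG)
        front = nsga2_run(config, run_index=0)
        # reconstruct the same initial population from the run sub-seed
        gen = np.random.default_rng(config.run_seed(0))
        P = random_codes(40, gen)
        F = evaluate_many(P, config.specs)
        expected = {tuple(np.round(F[i], 10)) for i in nondominated_layers(F)[0]}
        got = {tuple(np.round(m.objectives, 10)) for m in front.members}
        assert got == expected

    def test_reproducible_from_seed(self):
        config = GAConfig(generations=25, seed=11, **self.CFG)
        a = nsga2_run(config, run_index=2)
        b = nsga2_run(config, run_index=2)
        assert [m.code for m in a.members] == [m.code for m in b.members]
        assert [m.objectives for m in a.members] == [m.objectives for m in b.members]

    def test_different_runs_differ(self):
        config = GAConfig(generations=25, seed=11, **self.CFG)
        a = nsga2_run(config, run_index=0)
        b = nsga2_run(config, run_index=1)
        assert a.objective_matrix().tolist() != b.objective_matrix().tolist()

    def test_front_valid_and_bounded(self):
        config = GAConfig(generations=40, seed=3, **self.CFG)
        front = nsga2_run(config)
        assert 1 <= len(front) <= config.population_size
        for m in front.members:
            assert sorted(m.code.assignment) == sorted(AMINO_ACIDS)

    def test_elitism_improves_on_initial_population(self):
        config = GAConfig(generations=60, seed=9, **self.CFG)
        gen = np.random.default_rng(config.run_seed(0))
        F0 = evaluate_many(random_codes(40, gen), config.specs)
        front = nsga2_run(config, run_index=0)
        assert (front.objective_matrix().min(0) <= F0.min(0)).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(specs=(), population_size=10)
        with pytest.raises(ValueError):
            GAConfig(specs=parse_objectives("ms:pr"), population_size=1)
        with pytest.raises(ValueError):
            GAConfig(specs=parse_objectives("ms:pr"), swap_probability=1.5)

    def test_tournament_pool_size_rule(self):
        cfg = GAConfig(specs=parse_objectives("ms:pr"), population_size=100)
        assert cfg.tournament_size == 3
        small = GAConfig(specs=parse_objectives("ms:pr"), population_size=20)
        assert small.tournament_size == 2


def _front_from_vectors(vectors, specs, rng):
    seen = set()
    members = []
    for v in vectors:
        while True:
            code = random_code(rng)
            if code.assignment not in seen:
                seen.add(code.assignment)
                break
        members.append(Individual(code=code, objectives=tuple(map(float, v))))
    return ParetoFront(tuple(members), specs)


class TestMergeFronts:
    SPECS = parse_objectives("ms:pr,ms:hi")

    def test_idempotent(self, rng):
        front = _front_from_vectors([(1, 3), (2, 2)], self.SPECS, rng)
        merged = merge_fronts([front, front])
        assert sorted(m.objectives for m in merged.members) == [(1, 3), (2, 2)]

    def test_mutually_nondominated_fronts_union(self, rng):
        a = _front_from_vectors([(1, 3)], self.SPECS, rng)
        b = _front_from_vectors([(3, 1)], self.SPECS, rng)
        merged = merge_fronts([a, b])
        assert sorted(m.objectives for m in merged.members) == [(1, 3), (3, 1)]

    def test_dominated_members_filtered(self, rng):
        a = _front_from_vectors([(1, 3), (2, 2)], self.SPECS, rng)
        b = _front_from_vectors([(1, 2)], self.SPECS, rng)
        merged = merge_fronts([a, b])
        assert [m.objectives for m in merged.members] == [(1.0, 2.0)]

    def test_mixed_specs_rejected(self, rng):
        a = _front_from_vectors([(1, 3)], self.SPECS, rng)
        b = _front_from_vectors([(3, 1)], parse_objectives("ms:pr,ms:mv"), rng)
        with pytest.raises(ValueError):
            merge_fronts([a, b])

    def test_front_invariant_enforced(self, rng):
        with pytest.raises(ValueError):
            _front_from_vectors([(1, 1), (2, 2)], self.SPECS, rng)
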