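import itertools
import random

import numpy as np
import pytest

from mapanchor.colinearity import best_configuration_bruteforce, score_configuration
from mapanchor.map_model import ScaffoldConfiguration
from mapanchor.ordering import (
    DistanceMatrix,
    GAParams,
    OrientationMatrix,
    build_distance_matrix,
    build_orientation_matrix,
    flip_pass,
    ga_refine,
    initial_order,
    orient_by_eigenvector,
    orientation_score,
    pairwise_distance,
)

from .conftest import make_collection


def random_instance(seed, n_scaffolds=4, n_maps=2, markers_per_scaffold=2):
    """Small random anchoring instance with distinct map positions."""
    rng = random.Random(seed)
    markers = []
    sids = [f"s{i}" for i in range(n_scaffolds)]
    for sid in sids:
        for map_name in [f"M{j}" for j in range(n_maps)]:
            for k in range(markers_per_scaffold):
                markers.append(
                    (sid, k * 10, map_name, "1", round(rng.random() * 20, 3))
                )
    return sids, make_collection(markers)


class TestOrientationScore:
    def test_same_orientation_positive(self, two_scaffold_collection):
        # LMS(a||b) = 4, LMS(a||-b) = LMS([1,2,4,3]) = 3 -> o = +1
        assert orientation_score("a", "b", two_scaffold_collection) == 1.0

    def test_single_markers_undetermined(self):
        collection = make_collection(
            [("a", 0, "M", "1", 1.0), ("b", 0, "M", "1", 2.0)]
        )
        assert orientation_score("a", "b", collection) == 0.0

    def test_disjoint_maps_zero(self):
        collection = make_collection(
            [("a", 0, "A", "1", 1.0), ("a", 5, "A", "1", 2.0),
             ("b", 0, "B", "1", 1.0), ("b", 5, "B", "1", 2.0)]
        )
        assert orientation_score("a", "b", collection) == 0.0

    def test_matrix_symmetric_zero_diagonal(self):
        sids, collection = random_instance(0, n_scaffolds=5)
        from mapanchor.ordering import _as_problem

        matrix = build_orientation_matrix(_as_problem(collection, sids))
        assert np.allclose(matrix.M, matrix.M.T)
        assert np.all(np.diag(matrix.M) == 0)


class TestOrientByEigenvector:
    def test_agreement(self):
        m = OrientationMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert list(orient_by_eigenvector(m)) == [1, 1]

    def test_disagreement(self):
        m = OrientationMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))
        assert list(orient_by_eigenvector(m)) == [1, -1]

    def test_all_zero(self):
        m = OrientationMatrix(["a", "b"], np.zeros((2, 2)))
        assert list(orient_by_eigenvector(m)) == [0, 0]

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_signs_recovered(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.choice([-1, 1], size=5)
        M = np.outer(s, s).astype(float)
        np.fill_diagonal(M, 0.0)
        got = orient_by_eigenvector(OrientationMatrix(list("abcde"), M))
        assert np.array_equal(got, s) or np.array_equal(got, -s)
        # cross-check: the planted signs maximize s' M s over all sign vectors
        best = max(
            (np.array(c) @ M @ np.array(c), c)
            for c in itertools.product((-1, 1), repeat=5)
        )[1]
        assert np.array_equal(np.abs(best), np.abs(s))


class TestPairwiseDistance:
    def test_closest_markers(self):
        collection = make_collection(
            [("a", 0, "M", "1", 1.0), ("a", 5, "M", "1", 2.0),
             ("b", 0, "M", "1", 2.5), ("b", 5, "M", "1", 9.0)]
        )
        assert pairwise_distance("a", "b", collection) == 0.5

    def test_self_distance_zero(self, two_scaffold_collection):
        assert pairwise_distance("a", "a", two_scaffold_collection) == 0.0

    def test_weighted_sum_over_maps(self):
        markers = [
            ("a", 0, "A", "1", 1.0), ("b", 0, "A", "1", 1.5),
            ("a", 0, "B", "1", 3.0), ("b", 0, "B", "1", 4.0),
        ]
        collection = make_collection(markers, weights={"A": 2, "B": 1})
        assert pairwise_distance("a", "b", collection) == 2 * 0.5 + 1 * 1.0

    def test_missing_map_penalized_by_span(self):
        markers = [
            ("a", 0, "A", "1", 0.0), ("b", 0, "A", "1", 1.0),
            ("a", 0, "B", "1", 0.0), ("c", 0, "B", "1", 10.0),
        ]
        collection = make_collection(markers)
        # b has no markers on B: penalty is B's span (10)
        assert pairwise_distance("a", "b", collection) == 1.0 + 10.0


class TestInitialOrder:
    def test_single_scaffold(self):
        d = DistanceMatrix(["a"], np.zeros((1, 1)))
        assert initial_order(d) == [0]

    def test_line_graph(self):
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        order = initial_order(DistanceMatrix(list("abc"), D))
        assert order in ([0, 1, 2], [2, 1, 0])

    def test_near_optimal_on_random_instances(self):
        rng = np.random.default_rng(12)
        worst_ratio = 1.0
        for _ in range(100):
            n = int(rng.integers(4, 8))
            D = rng.uniform(0.1, 10.0, size=(n, n))
            D = (D + D.T) / 2.0
            np.fill_diagonal(D, 0.0)
            order = initial_order(DistanceMatrix([str(i) for i in range(n)], D))
            cost = sum(D[a, b] for a, b in zip(order, order[1:]))
            best = min(
                sum(D[a, b] for a, b in zip(p, p[1:]))
                for p in itertools.permutations(range(n))
            )
            worst_ratio = max(worst_ratio, cost / best)
        assert worst_ratio <= 1.05

    def test_external_solver_hook(self):
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])

        def solver(full):
            return [3, 0, 1, 2]

        order = initial_order(DistanceMatrix(list("abc"), D), tsp_solver=solver)
        assert order == [0, 1, 2]

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        D = rng.uniform(0, 5, size=(6, 6))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        matrix = DistanceMatrix([str(i) for i in range(6)], D)
        assert initial_order(matrix) == initial_order(matrix)


class TestFlipPass:
    def test_already_optimal_unchanged(self, two_scaffold_collection):
        config = ScaffoldConfiguration("chr", [("a", 1), ("b", 1)])
        assert flip_pass(config, two_scaffold_collection).entries == config.entries

    def test_planted_reversal_fixed(self):
        markers = []
        for i, sid in enumerate("abc"):
            for k in range(3):
                markers.append((sid, k * 10, "M", "1", i * 3 + k + 0.0))
        collection = make_collection(markers)
        config = ScaffoldConfiguration("chr", [("a", 1), ("b", -1), ("c", 1)])
        fixed = flip_pass(config, collection)
        assert fixed.entries == [("a", 1), ("b", 1), ("c", 1)]
        assert (
            score_configuration(fixed, collection).total
            > score_configuration(config, collection).total
        )

    def test_single_marker_scaffold_never_flipped(self):
        markers = [("a", 0, "M", "1", 1.0), ("a", 5, "M", "1", 2.0),
                   ("b", 0, "M", "1", 3.0)]
        collection = make_collection(markers)
        config = ScaffoldConfiguration("chr", [("a", 1), ("b", 1)])
        assert flip_pass(config, collection).entries == config.entries


class TestGARefine:
    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            GAParams(p_mut=1.5)

    def test_never_below_initial(self):
        for seed in range(10):
            sids, collection = random_instance(seed, n_scaffolds=5)
            initial = ScaffoldConfiguration("chr", [(s, 1) for s in sids])
            init_score = score_configuration(initial, collection).total
            refined = ga_refine(
                initial, collection, GAParams(npop=20, window=15, seed=seed)
            )
            assert score_configuration(refined, collection).total >= init_score

    def test_optimal_input_keeps_score(self):
        sids, collection = random_instance(3, n_scaffolds=4)
        best = best_configuration_bruteforce(sids, collection)
        best_score = score_configuration(best, collection).total
        refined = ga_refine(best, collection, GAParams(npop=20, window=15, seed=0))
        assert score_configuration(refined, collection).total == best_score

    def test_deterministic_under_seed(self):
        sids, collection = random_instance(8, n_scaffolds=6)
        initial = ScaffoldConfiguration("chr", [(s, 1) for s in sids])
        params = GAParams(npop=20, window=15, seed=123)
        a = ga_refine(initial, collection, params)
        b = ga_refine(initial, collection, params)
        assert a.entries == b.entries

    def test_global_reversal_scores_equal(self):
        sids, collection = random_instance(4, n_scaffolds=5)
        initial = ScaffoldConfiguration("chr", [(s, 1) for s in sids])
        refined = ga_refine(initial, collection, GAParams(npop=20, window=15, seed=1))
        assert (
            score_configuration(refined, collection).total
            == score_configuration(refined.reversed_(), collection).total
        )


class TestPMX:
    def test_children_are_permutations(self):
        from mapanchor.ordering import _pmx

        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 12))
            p1 = list(rng.permutation(n))
            p2 = list(rng.permutation(n))
            c1, c2 = _pmx(p1, p2, rng)
            assert sorted(c1) == list(range(n))
            assert sorted(c2) == list(range(n))

    def test_mutation_preserves_permutation(self):
        from mapanchor.ordering import _mutate

        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(2, 12))
            p = list(rng.permutation(n))
            signs = [1] * n
            _mutate(p, signs, rng)
            assert sorted(p) == list(range(n))
            assert all(s in (-1, 1) for s in signs)
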