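"""Environmental-space indices: partitioning, Jaccard, extrapolation distance."""

import numpy as np
import pytest

import nicheval as nv
from nicheval.espace import EnvSpace


def make_space(geometry, scores):
    """An EnvSpace with given background scores on all cells of a grid."""
    n = geometry.n_rows * geometry.n_cols
    scores = np.asarray(scores, float)
    assert scores.shape[0] == n
    d = scores.shape[1]
    return EnvSpace(
        geometry=geometry,
        cell_ids=np.arange(n),
        scores=scores,
        loadings=np.zeros((d, d)) + np.eye(d),
        means=np.zeros(d),
        scales=np.ones(d),
        explained=np.ones(d) / d,
        layer_names=[f"L{i}" for i in range(d)],
    )


def binary(geometry, suitable_flat):
    suitable = np.zeros(geometry.shape, bool)
    suitable.ravel()[list(suitable_flat)] = True
    return nv.BinaryMap(geometry, suitable, np.zeros(geometry.shape, bool), 0.5, 0.0)


class TestUniqueEnvPoints:
    def test_duplicate_environments_counted_once(self, small_grid):
        scores = np.zeros((100, 2))
        scores[1] = [1.0, 2.0]  # cells 0 and 2 share an environment
        space = make_space(small_grid, scores)
        pts = nv.unique_env_points(binary(small_grid, [0, 1, 2]), space)
        assert pts.shape == (2, 2)

    def test_all_unsuitable_gives_empty_set(self, small_grid):
        space = make_space(small_grid, np.random.default_rng(0).random((100, 2)))
        assert nv.unique_env_points(binary(small_grid, []), space).shape[0] == 0

    def test_distinct_environments_all_kept(self, small_grid):
        rng = np.random.default_rng(1)
        space = make_space(small_grid, rng.random((100, 3)))
        pts = nv.unique_env_points(binary(small_grid, range(7)), space)
        assert pts.shape == (7, 3)


class TestIndexI:
    def test_counts_split_verified_cell_by_cell(self, small_grid):
        rng = np.random.default_rng(2)
        scores = rng.standard_normal((100, 2))
        space = make_space(small_grid, scores)
        ball = nv.Ellipsoid(np.zeros(2), np.eye(2))
        bm = binary(small_grid, range(100))  # everything suitable
        n_in, n_out = nv.espace_index_I(bm, space, ball)
        uniq = np.unique(np.round(scores, 6), axis=0)
        brute_in = int(sum(1 for p in uniq if p @ p <= 1 + 1e-9))
        assert (n_in, n_out) == (brute_in, uniq.shape[0] - brute_in)

    def test_all_inside_and_empty_cases(self, small_grid):
        scores = np.full((100, 2), 0.1)
        space = make_space(small_grid, scores)
        ball = nv.Ellipsoid(np.zeros(2), np.eye(2))
        assert nv.espace_index_I(binary(small_grid, range(10)), space, ball) == (1, 0)
        assert nv.espace_index_I(binary(small_grid, []), space, ball) == (0, 0)

    def test_dimension_mismatch_raises(self, small_grid):
        space = make_space(small_grid, np.random.default_rng(3).random((100, 2)))
        with pytest.raises(ValueError):
            nv.espace_index_I(binary(small_grid, [0]), space, nv.Ellipsoid(np.zeros(3), np.eye(3)))


class TestJaccard:
    def test_identical_ellipsoids_give_one(self):
        e = nv.Ellipsoid(np.array([1.0, 2.0, 3.0]), np.diag([1.0, 0.5, 2.0]))
        j = nv.jaccard_similarity(e, e, mc_samples=100_000, seed=0)
        assert j == pytest.approx(1.0, abs=0.005)

    def test_disjoint_ellipsoids_give_zero(self):
        a = nv.Ellipsoid(np.zeros(2), np.eye(2))
        b = nv.Ellipsoid(np.array([10.0, 0.0]), np.eye(2))
        assert nv.jaccard_similarity(a, b, mc_samples=20_000, seed=1) == 0.0

    def test_concentric_balls_nested_volume_ratio(self):
        # balls radius 1 and 2 in 3-D: intersection = small ball, J = 1/8
        small = nv.Ellipsoid(np.zeros(3), np.eye(3))
        big = nv.Ellipsoid(np.zeros(3), np.eye(3) / 4.0)
        j = nv.jaccard_similarity(small, big, mc_samples=100_000, seed=2)
        assert j == pytest.approx(0.125, abs=0.01)

    def test_symmetry_within_mc_error(self):
        a = nv.Ellipsoid(np.zeros(2), np.eye(2))
        b = nv.Ellipsoid(np.array([0.8, 0.0]), np.diag([2.0, 0.7]))
        j1 = nv.jaccard_similarity(a, b, mc_samples=200_000, seed=3)
        j2 = nv.jaccard_similarity(b, a, mc_samples=200_000, seed=4)
        assert j1 == pytest.approx(j2, abs=0.01)
        assert 0.0 <= j1 <= 1.0

    def test_discrete_mode_self_similarity_exact(self):
        rng = np.random.default_rng(5)
        bg = rng.standard_normal((500, 2)) * 2
        ball = nv.Ellipsoid(np.zeros(2), np.eye(2))
        inside = bg[np.asarray(ball.contains(bg))]
        j = nv.jaccard_similarity(inside, ball, mode="discrete_cells", background=bg)
        assert j == 1.0

    def test_discrete_mode_counts(self):
        bg = np.array([[0.0, 0.0], [0.5, 0.0], [3.0, 0.0], [4.0, 0.0]])
        ball = nv.Ellipsoid(np.zeros(2), np.eye(2))  # contains first two
        modeled = bg[[1, 2]]  # one shared with inside-set, one outside
        j = nv.jaccard_similarity(modeled, ball, mode="discrete_cells", background=bg)
        assert j == pytest.approx(1 / 3)

    def test_mc_error_shrinks_with_sample_size(self):
        a = nv.Ellipsoid(np.zeros(3), np.eye(3))
        b = nv.Ellipsoid(np.array([0.7, 0.0, 0.0]), np.eye(3))

        def se(samples):
            js = [
                nv.jaccard_similarity(a, b, mc_samples=samples, seed=s)
                for s in range(12)
            ]
            return np.std(js)

        # quadrupling the sample size should roughly halve the spread
        ratio = se(4_000) / se(16_000)
        assert 1.2 < ratio < 3.5


class TestExtrapolationDistance:
    def test_zero_when_nothing_outside(self, small_grid):
        space = make_space(small_grid, np.full((100, 2), 0.2))
        ball = nv.Ellipsoid(np.zeros(2), np.eye(2))
        assert nv.extrapolation_distance(binary(small_grid, range(20)), space, ball) == 0.0

    def test_single_outside_point_distance(self, small_grid):
        scores = np.full((100, 2), 0.1)
        scores[7] = [3.7, 0.0]
        space = make_space(small_grid, scores)
        ball = nv.Ellipsoid(np.zeros(2), np.eye(2))
        d = nv.extrapolation_distance(binary(small_grid, [5, 7]), space, ball)
        assert d == pytest.approx(3.7)

    def test_matches_brute_force_max(self, small_grid):
        rng = np.random.default_rng(6)
        scores = rng.standard_normal((100, 2)) * 2
        space = make_space(small_grid, scores)
        ball = nv.Ellipsoid(np.array([0.3, -0.2]), np.eye(2))
        suitable = list(range(0, 100, 3))
        d = nv.extrapolation_distance(binary(small_grid, suitable), space, ball)
        uniq = np.unique(np.round(scores[suitable], 6), axis=0)
        out = [p for p in uniq if p @ np.eye(2) @ p is not None and not ball.contains(p)]
        brute = max(np.linalg.norm(p - ball.center) for p in out)
        assert d == pytest.approx(brute)

    def test_monotone_under_farther_suitable_point(self, small_grid):
        scores = np.full((100, 2), 0.1)
        scores[7] = [2.0, 0.0]
        scores[8] = [5.0, 0.0]
        space = make_space(small_grid, scores)
        ball = nv.Ellipsoid(np.zeros(2), np.eye(2))
        d1 = nv.extrapolation_distance(binary(small_grid, [7]), space, ball)
        d2 = nv.extrapolation_distance(binary(small_grid, [7, 8]), space, ball)
        assert d2 >= d1


class TestESpaceReport:
    def test_partition_identity_and_zero_distance_iff_no_extrapolation(self, small_grid):
        rng = np.random.default_rng(8)
        space = make_space(small_grid, rng.standard_normal((100, 2)))
        ball = nv.Ellipsoid(np.zeros(2), 0.5 * np.eye(2))
        rep = nv.espace_report(binary(small_grid, range(0, 100, 2)), space, ball, mc_samples=5_000)
        assert rep.n_interpolation + rep.n_extrapolation == rep.n_unique_suitable
        assert (rep.extrapolation_distance == 0.0) == (rep.n_extrapolation == 0)

    def test_self_model_scores_perfectly(self, small_grid):
        """A model that predicts exactly the observed-niche interior has
        Jaccard ~ 1 and no extrapolation."""
        rng = np.random.default_rng(9)
        scores = rng.standard_normal((100, 2))
        space = make_space(small_grid, scores)
        observed = nv.fit_mve(scores[:50])
        inside = np.asarray(observed.contains(scores))
        rep = nv.espace_report(
            binary(small_grid, np.flatnonzero(inside)), space, observed,
            jaccard_mode="discrete_cells",
        )
        assert rep.jaccard == 1.0
        assert rep.extrapolation_distance == 0.0

    def test_fallback_to_discrete_mode_when_mve_degenerate(self, small_grid):
        scores = np.full((100, 2), 0.1)  # a single unique suitable point
        space = make_space(small_grid, scores)
        ball = nv.Ellipsoid(np.zeros(2), np.eye(2))
        rep = nv.espace_report(binary(small_grid, range(5)), space, ball)
        assert rep.jaccard_mode == "discrete_cells"
        assert rep.n_unique_suitable == 1
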