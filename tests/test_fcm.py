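"""FCM core: update formulas, convergence, initialization, consensus."""

import numpy as np
import pytest

import softparc as sp
from softparc.fcm import (
    DEFAULT_SEED_ROIS,
    cube_average,
    fcm_objective,
    init_random,
    init_seeded,
    match_permutation,
    run_fcm,
    update_centroids,
    update_memberships,
    xie_beni,
)


class TestMembershipUpdate:
    def test_one_dimensional_worked_example(self):
        # point at 0.25 between centroids 0 and 1 with M=2:
        # u1 = 1/(1+(0.25/0.75)^2) = 0.9
        X = np.array([[0.25]])
        V = np.array([[0.0], [1.0]])
        U = update_memberships(X, V, fuzzifier=2.0)
        assert U[:, 0] == pytest.approx([0.9, 0.1], abs=1e-12)

    def test_coincident_point_gets_crisp_membership(self):
        X = np.array([[1.0, 1.0]])
        V = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        U = update_memberships(X, V, fuzzifier=1.2)
        assert np.array_equal(U[:, 0], [0.0, 1.0, 0.0])

    def test_equidistant_point_uniform(self):
        X = np.array([[0.0, 0.0]])
        V = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        U = update_memberships(X, V, fuzzifier=1.2)
        assert np.allclose(U[:, 0], 0.25)

    def test_columns_sum_to_one_on_random_inputs(self, rng):
        for _ in range(10):
            X = rng.standard_normal((30, 4))
            V = rng.standard_normal((5, 4))
            U = update_memberships(X, V, fuzzifier=1.2)
            assert np.allclose(U.sum(axis=0), 1.0, atol=1e-9)
            assert np.all((U >= 0) & (U <= 1))

    def test_fuzzifier_must_exceed_one(self):
        with pytest.raises(ValueError):
            update_memberships(np.ones((2, 2)), np.eye(2), fuzzifier=1.0)


class TestCentroidUpdate:
    def test_crisp_membership_gives_class_means(self, rng):
        X = rng.standard_normal((6, 3))
        U = np.zeros((2, 6))
        U[0, :3] = 1.0
        U[1, 3:] = 1.0
        V = update_centroids(X, U, fuzzifier=1.2)
        assert np.allclose(V[0], X[:3].mean(axis=0))
        assert np.allclose(V[1], X[3:].mean(axis=0))

    def test_uniform_membership_gives_grand_mean(self, rng):
        X = rng.standard_normal((8, 4))
        U = np.full((3, 8), 1 / 3)
        V = update_centroids(X, U, fuzzifier=1.2)
        assert np.allclose(V, np.tile(X.mean(axis=0), (3, 1)))

    def test_matches_direct_weighted_mean(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        U = np.array([[0.8, 0.5, 0.1], [0.2, 0.5, 0.9]])
        M = 1.2
        V = update_centroids(X, U, M)
        W = U**M
        expected = (W @ X) / W.sum(axis=1, keepdims=True)
        assert np.allclose(V, expected, atol=1e-12)

    def test_zero_weight_cluster_rejected(self):
        U = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match=r"\[1\]"):
            update_centroids(np.ones((2, 2)), U, 1.2)


class TestXieBeni:
    def test_zero_for_points_on_their_centroids(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        V = X.copy()
        U = np.eye(2)
        assert xie_beni(X, U, V, 1.2) == 0.0

    def test_scale_invariance(self, rng):
        X = rng.standard_normal((12, 3))
        V = rng.standard_normal((3, 3))
        U = update_memberships(X, V, 1.2)
        xb = xie_beni(X, U, V, 1.2)
        assert xie_beni(3.7 * X, U, 3.7 * V, 1.2) == pytest.approx(xb, rel=1e-12)

    def test_matches_hand_computed_toy_value(self):
        # 4 points on a line, 2 centroids, crisp memberships
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        V = np.array([[0.5], [10.5]])
        U = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]])
        # numerator: 4 * 0.25 = 1; separation: 100; n = 4
        assert xie_beni(X, U, V, 2.0) == pytest.approx(1.0 / 400.0, abs=1e-15)

    def test_coincident_centroids_rejected(self):
        V = np.array([[1.0], [1.0]])
        with pytest.raises(ValueError, match="coincident"):
            xie_beni(np.array([[0.0]]), np.array([[0.5], [0.5]]), V, 1.2)


def grid_search_fcm_1d(points, grid, fuzzifier):
    """Brute-force FCM oracle: best (U, V) over all centroid pairs."""
    best = (np.inf, None)
    X = points.reshape(-1, 1)
    for i, v1 in enumerate(grid):
        for v2 in grid[i + 1 :]:
            V = np.array([[v1], [v2]])
            U = update_memberships(X, V, fuzzifier)
            J = fcm_objective(X, U, V, fuzzifier)
            if J < best[0]:
                best = (J, V)
    return best


class TestRunFcm:
    def test_separable_groups_recovered_exactly(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))]
        )
        init = np.array([[0.2, 0.2], [4.5, 4.5]])
        sol = run_fcm(X, init)
        assert sol.converged
        labels = sol.hard_labels()
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_objective_non_increasing(self, rng):
        X = rng.standard_normal((40, 3))
        init = X[rng.choice(40, 3, replace=False)]
        sol = run_fcm(X, init)
        diffs = np.diff(sol.objective_trace)
        assert np.all(diffs <= 1e-9)

    def test_matches_grid_search_on_five_points(self):
        points = np.array([0.0, 0.1, 0.25, 0.9, 1.0])
        grid = np.linspace(-0.1, 1.1, 121)
        J_best, _ = grid_search_fcm_1d(points, grid, fuzzifier=1.2)
        sol = run_fcm(points.reshape(-1, 1), np.array([[0.3], [0.7]]))
        J_sol = sol.objective_trace[-1]
        assert J_sol <= J_best + 1e-3

    def test_nonconvergence_flagged(self, rng):
        X = rng.standard_normal((30, 2))
        init = X[:4]
        sol = run_fcm(X, init, max_iter=2)
        assert not sol.converged
        assert sol.n_iter == 2

    def test_trace_recorded(self, rng):
        X = rng.standard_normal((20, 2))
        sol = run_fcm(X, X[:2])
        assert len(sol.xie_beni_trace) == sol.n_iter
        assert len(sol.objective_trace) == sol.n_iter


class TestInitialization:
    def test_cube_with_single_voxel_returns_its_row(self, rng):
        X = rng.standard_normal((3, 5))
        coords = np.array([[0, 0, 0], [10, 10, 10], [20, 20, 20]])
        out = cube_average(X, 1, cube_edge=3, voxel_coords=coords)
        assert np.array_equal(out, X[1])

    def test_cube_of_three_voxels_is_their_mean(self, rng):
        X = rng.standard_normal((4, 6))
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [9, 9, 9]])
        out = cube_average(X, 0, cube_edge=3, voxel_coords=coords)
        assert np.allclose(out, X[:3].mean(axis=0))

    def test_fixed_seed_reproducible(self, small_dataset):
        _, _, _, cmap = small_dataset
        a = init_random(cmap, 4, rng=42)
        b = init_random(cmap, 4, rng=42)
        assert np.array_equal(a, b)

    def test_naive_mode_draws_distinct_centroids(self, small_dataset):
        _, _, _, cmap = small_dataset
        V = init_random(cmap, 4, rng=0, refine="none")
        assert np.unique(V, axis=0).shape[0] == 4

    def test_more_clusters_than_voxels_rejected(self, rng):
        X = rng.standard_normal((3, 3))
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError):
            init_random(X, 5, rng=0, voxel_coords=coords)

    def test_seeded_lone_voxel_roi(self, rng):
        X = rng.standard_normal((3, 4))
        coords = np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        roi = sp.SeedROI("only", (5.0, 0.0, 0.0), radius=2.0)
        V, records = init_seeded(X, [roi], voxel_coords=coords, affine=np.eye(4))
        assert np.array_equal(V[0], X[1])
        assert records[0]["n_voxels"] == 1

    def test_seeded_empty_sphere_names_roi(self, rng):
        X = rng.standard_normal((2, 4))
        coords = np.array([[0, 0, 0], [1, 0, 0]])
        roi = sp.SeedROI("nowhere", (99.0, 99.0, 99.0), radius=1.0)
        with pytest.raises(ValueError, match="nowhere"):
            init_seeded(X, [roi], voxel_coords=coords, affine=np.eye(4))

    def test_seven_canonical_rois_echoed(self, default_dataset):
        _, ts, _, cmap = default_dataset
        # stretch the synthetic grid over stereotaxic space and widen the
        # spheres so every canonical seed finds in-mask voxels
        affine = np.diag([25.0, 33.0, 2.5, 1.0])
        affine[:3, 3] = [-55, -95, -5]
        rois = [
            sp.SeedROI(r.name, r.coord, radius=30.0) for r in DEFAULT_SEED_ROIS
        ]
        V, records = init_seeded(
            cmap.features,
            rois,
            voxel_coords=cmap.voxel_coords,
            affine=affine,
        )
        assert [r["name"] for r in records] == [
            "DMN", "FPC", "LAN", "VAN", "SMN", "VIS", "DAN",
        ]
        assert [tuple(r["coord"]) for r in records] == [
            tuple(roi.coord) for roi in DEFAULT_SEED_ROIS
        ]
        assert V.shape == (7, cmap.n)

    def test_seeded_separates_disjoint_networks(self):
        spec = sp.HierarchySpec(
            n_networks=2,
            voxels_per_network=50,
            fuzzy_fraction=0.0,
            noise_sd=0.05,
            n_frames=400,
            seed=6,
        )
        ts, gt = sp.simulate_bold(spec)
        cmap = sp.correlation_map(ts)
        world = ts.world_coords()
        rois = [
            sp.SeedROI("net0", tuple(world[10]), radius=4.0),
            sp.SeedROI("net1", tuple(world[60]), radius=4.0),
        ]
        V, _ = init_seeded(cmap, rois)
        within = sp.temporal_similarity(V[0], cmap.features[5])
        between = sp.temporal_similarity(V[0], V[1])
        assert between < within


class TestConsensus:
    def test_single_run_equals_run_fcm(self, small_dataset):
        _, _, _, cmap = small_dataset
        sol = sp.consensus_runs(cmap, 3, n_runs=1, rng_seed=5)
        rng = np.random.default_rng(5)
        init = init_random(cmap, 3, rng)
        direct = run_fcm(cmap.features, init)
        assert np.allclose(sol.membership, direct.membership)

    def test_matching_undoes_cluster_permutation(self, rng):
        U = rng.dirichlet(np.ones(4), size=50).T  # (4, 50) column-stochastic
        perm = np.array([2, 0, 3, 1])
        recovered = match_permutation(U[perm], U)
        assert np.array_equal(U[perm][recovered], U)

    def test_fixed_seed_bit_reproducible(self, small_dataset):
        _, _, _, cmap = small_dataset
        a = sp.consensus_runs(cmap, 3, n_runs=4, rng_seed=9)
        b = sp.consensus_runs(cmap, 3, n_runs=4, rng_seed=9)
        assert np.array_equal(a.membership, b.membership)
        assert np.array_equal(a.centroids, b.centroids)

    def test_consensus_columns_sum_to_one(self, consensus7):
        sol, _ = consensus7
        assert np.allclose(sol.membership.sum(axis=0), 1.0, atol=1e-9)

    def test_all_runs_failing_raises(self, small_dataset):
        _, _, _, cmap = small_dataset
        with pytest.raises(RuntimeError, match="failed to converge"):
            sp.consensus_runs(cmap, 3, n_runs=3, rng_seed=2, max_iter=1)


class TestInvariants:
    def test_permutation_equivariance(self, rng):
        X = rng.standard_normal((25, 6))
        V = rng.standard_normal((3, 6))
        U = update_memberships(X, V, 1.2)
        perm = rng.permutation(25)
        U_perm = update_memberships(X[perm], V, 1.2)
        assert np.allclose(U_perm, U[:, perm])
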