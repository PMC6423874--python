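"""System assembly, the sparse solve, and the registration loop."""

import numpy as np
import pytest
from scipy import sparse

from anricp import (
    ConfigError,
    LandmarkSet,
    NoiseModel,
    PointCloud,
    RegistrationConfig,
    TransformStack,
    assemble_D,
    assemble_DL,
    assemble_system,
    build_grid_topology,
    build_incidence,
    distance_cost,
    landmark_block,
    landmark_weights,
    register,
    solve_step,
    stiffness_block,
)


class TestAssembleD:
    def test_single_point_row(self):
        D = assemble_D(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(D.toarray(), [[1, 2, 3, 1]])

    def test_two_points_block_diagonal(self):
        D = assemble_D(np.array([[1.0, 2, 3], [4.0, 5, 6]])).toarray()
        assert D.shape == (2, 8)
        np.testing.assert_array_equal(D[0, 4:], np.zeros(4))
        np.testing.assert_array_equal(D[1, :4], np.zeros(4))
        np.testing.assert_array_equal(D[1, 4:], [4, 5, 6, 1])

    def test_identity_stack_recovers_points(self, grid_cloud):
        D = assemble_D(grid_cloud.points)
        got = D @ TransformStack.identity(grid_cloud.n).stacked
        np.testing.assert_allclose(got, grid_cloud.points)

    def test_landmark_rows_select_vertices(self, grid_cloud):
        DL = assemble_DL(grid_cloud.points, [2, 5])
        got = DL @ TransformStack.identity(grid_cloud.n).stacked
        np.testing.assert_allclose(got, grid_cloud.points[[2, 5]])


class TestDistanceCost:
    def test_perfect_fit_is_zero(self, grid_cloud):
        D = assemble_D(grid_cloud.points)
        X = TransformStack.identity(grid_cloud.n)
        assert distance_cost(D, X, grid_cloud.points, np.ones(grid_cloud.n)) == 0.0

    def test_unit_residual_and_quadratic_weight(self):
        D = assemble_D(np.array([[0.0, 0, 0]]))
        X = TransformStack.identity(1)
        U = np.array([[1.0, 0, 0]])  # 1 mm off
        assert distance_cost(D, X, U, np.ones(1)) == pytest.approx(1.0)
        assert distance_cost(D, X, U, np.array([2.0])) == pytest.approx(4.0)


class TestIncidence:
    def test_single_arc_sign_convention(self):
        from anricp import GridTopology

        M = build_incidence(GridTopology(edges=np.array([[0, 1]])), 2)
        np.testing.assert_array_equal(M.toarray(), [[-1.0, 1.0]])

    def test_row_sums_zero_on_grids(self):
        for rows, cols, conn in [(2, 2, 4), (5, 4, 8), (25, 25, 4)]:
            topo = build_grid_topology(rows, cols, conn)
            M = build_incidence(topo, rows * cols)
            np.testing.assert_array_equal(np.asarray(M.sum(axis=1)).ravel(), 0.0)

    def test_25x25_dimensions_and_nnz(self):
        topo = build_grid_topology(25, 25, 4)
        M = build_incidence(topo, 625)
        assert M.shape == (1200, 625)
        assert M.nnz == 2400

    def test_out_of_range_rejected(self, grid_topology):
        from anricp import InvalidInputError

        with pytest.raises(InvalidInputError):
            build_incidence(grid_topology, 3)


class TestStiffnessBlock:
    def test_equal_transforms_give_zero_rows(self):
        M = sparse.csr_matrix(np.array([[-1.0, 1.0]]))
        X = TransformStack.translation(2, (5.0, -2.0, 1.0)).stacked
        out = stiffness_block(M, np.eye(4), 1.0) @ X
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_translation_difference_hand_expanded_kron(self):
        # two blocks differing by a translation δ in x: the 4E×4N product has
        # a single nonzero entry δ, so the squared norm is δ²
        delta = 3.5
        M = sparse.csr_matrix(np.array([[-1.0, 1.0]]))
        X1 = TransformStack.identity(1).blocks[0]
        X2 = X1.copy()
        X2[3, 0] += delta
        X = np.vstack([X1, X2])
        out = stiffness_block(M, np.eye(4), 1.0) @ X
        assert np.sum(out**2) == pytest.approx(delta**2)

    def test_alpha_scales_linearly(self, grid_topology, grid_cloud):
        M = build_incidence(grid_topology, grid_cloud.n)
        S1 = stiffness_block(M, np.eye(4), 1.0)
        S2 = stiffness_block(M, np.eye(4), 2.0)
        np.testing.assert_allclose(S2.toarray(), 2.0 * S1.toarray())


class TestLandmarkBlock:
    def test_coincident_landmarks_zero_residual(self, grid_cloud):
        DL = assemble_DL(grid_cloud.points, [1, 3])
        UL = grid_cloud.points[[1, 3]]
        rows, rhs = landmark_block(DL, UL, 1.0)
        res = rows @ TransformStack.identity(grid_cloud.n).stacked - rhs
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_beta_zero_contributes_nothing(self, grid_cloud):
        DL = assemble_DL(grid_cloud.points, [1])
        rows, rhs = landmark_block(DL, grid_cloud.points[[1]], 0.0)
        assert rows is None and rhs is None

    def test_single_landmark_2mm_cost(self):
        pts = np.array([[0.0, 0.0, 0.0]])
        DL = assemble_DL(pts, [0])
        UL = np.array([[2.0, 0.0, 0.0]])
        rows, rhs = landmark_block(DL, UL, 1.0)
        res = rows @ TransformStack.identity(1).stacked - rhs
        assert np.sum(res**2) == pytest.approx(4.0)


class TestAssembleSystem:
    def test_variant_a_row_bookkeeping_without_landmarks(self, grid_cloud, grid_topology):
        n = grid_cloud.n
        M = build_incidence(grid_topology, n)
        D = assemble_D(grid_cloud.points)
        A, B = assemble_system(
            "isotropic", 10.0, M, np.eye(4), D, grid_cloud.points, np.ones(n)
        )
        assert A.shape == (4 * grid_topology.n_edges + n, 4 * n)
        assert B.shape[0] == A.shape[0]

    def test_stiffness_rhs_rows_are_zero(self, grid_cloud, grid_topology):
        n = grid_cloud.n
        M = build_incidence(grid_topology, n)
        D = assemble_D(grid_cloud.points)
        _, B = assemble_system(
            "anisotropic", 5.0, M, np.eye(4), D, grid_cloud.points, np.ones(n)
        )
        np.testing.assert_array_equal(B[: 4 * grid_topology.n_edges], 0.0)

    def test_variant_c_pins_weighted_landmark_rows(self, grid_cloud, grid_topology):
        n = grid_cloud.n
        M = build_incidence(grid_topology, n)
        D = assemble_D(grid_cloud.points)
        w = landmark_weights(n, [4])
        U = grid_cloud.points + 1.0  # pretend matched targets
        U[4] = [7.0, 8.0, 9.0]  # pinned target landmark coordinates
        DL = assemble_DL(grid_cloud.points, [4])
        A, B = assemble_system(
            "anisotropic_landmark", 5.0, M, np.eye(4), D, U, w, DL, U[[4]]
        )
        row = 4 * grid_topology.n_edges + 4
        np.testing.assert_allclose(B[row], 4.0 * np.array([7.0, 8.0, 9.0]))
        assert w[4] == 4.0 and w[0] == 0.25

    def test_variant_c_without_landmarks_is_config_error(self, grid_cloud, grid_topology):
        n = grid_cloud.n
        M = build_incidence(grid_topology, n)
        D = assemble_D(grid_cloud.points)
        with pytest.raises(ConfigError):
            assemble_system(
                "anisotropic_landmark", 5.0, M, np.eye(4), D, grid_cloud.points, np.ones(n)
            )

    def test_variant_a_beta0_equals_variant_c_uniform_bit_for_bit(self, grid_cloud, grid_topology):
        n = grid_cloud.n
        M = build_incidence(grid_topology, n)
        D = assemble_D(grid_cloud.points)
        U = grid_cloud.points + 2.0
        DL = assemble_DL(grid_cloud.points, [1])
        A1, B1 = assemble_system("isotropic", 3.0, M, np.eye(4), D, U, np.ones(n), DL, U[[1]], beta=0.0)
        A2, B2 = assemble_system("anisotropic_landmark", 3.0, M, np.eye(4), D, U, np.ones(n), DL, U[[1]])
        assert (A1 != A2).nnz == 0
        np.testing.assert_array_equal(B1, B2)


class TestSolveStep:
    def test_identity_system(self):
        A = sparse.identity(8, format="csr")
        B = np.arange(24, dtype=float).reshape(8, 3)
        X = solve_step(A, B)
        np.testing.assert_allclose(X.stacked, B, atol=1e-12)

    def test_matches_dense_pseudoinverse_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(2, 11)
            rows = 4 * n + rng.integers(1, 10)
            A = sparse.csr_matrix(rng.normal(size=(rows, 4 * n)))
            B = rng.normal(size=(rows, 3))
            X = solve_step(A, B).stacked
            oracle = np.linalg.pinv(A.toarray()) @ B
            np.testing.assert_allclose(X, oracle, atol=1e-6 * max(1.0, np.abs(oracle).max()))

    def test_recovers_known_solution_of_consistent_system(self, rng):
        n = 6
        A = sparse.csr_matrix(rng.normal(size=(5 * n, 4 * n)))
        X0 = rng.normal(size=(4 * n, 3))
        X = solve_step(A, A @ X0).stacked
        np.testing.assert_allclose(X, X0, atol=1e-8)

    def test_global_minimum_under_random_perturbations(self, rng):
        for _ in range(20):
            n = rng.integers(2, 6)
            A = sparse.csr_matrix(rng.normal(size=(4 * n + 5, 4 * n)))
            B = rng.normal(size=(A.shape[0], 3))
            X = solve_step(A, B).stacked
            best = np.sum((A @ X - B) ** 2)
            for _ in range(5):
                Xp = X + rng.normal(scale=1e-3, size=X.shape)
                assert np.sum((A @ Xp - B) ** 2) >= best - 1e-12

    def test_rank_deficient_system_solved_with_ridge(self, rng, caplog):
        # duplicate columns make AᵀA exactly singular
        base = rng.normal(size=(12, 4))
        A = sparse.csr_matrix(np.hstack([base, base]))
        B = rng.normal(size=(12, 3))
        with caplog.at_level("WARNING", logger="anricp"):
            X = solve_step(A, B).stacked
        assert np.all(np.isfinite(X))
        # the fit still reaches the least-squares optimum
        oracle = np.linalg.pinv(A.toarray()) @ B
        np.testing.assert_allclose(A @ X, A.toarray() @ oracle, atol=1e-6)


class TestRegister:
    def test_fixed_point_identity(self, grid_cloud):
        cfg = RegistrationConfig(variant="isotropic", max_iterations=20)
        res = register(grid_cloud, grid_cloud.copy(), config=cfg)
        assert res.converged and res.iterations <= 2
        assert res.m1_mm < 1e-9
        assert res.m3_pct == 100.0
        dev = np.abs(res.transform.blocks - TransformStack.identity(grid_cloud.n).blocks)
        assert dev.max() < 1e-6

    def test_rigid_translation_recovery(self, small_spec):
        from anricp.synth import flat_mesh_pair

        src, tgt, _ = flat_mesh_pair(small_spec)
        cfg = RegistrationConfig(
            variant="isotropic", alpha_start=1e6, alpha_decay=1.0, max_iterations=30
        )
        res = register(src, tgt, config=cfg)
        disp = res.cloud.points - src.points
        np.testing.assert_allclose(disp, np.broadcast_to([0, 0, 100.0], disp.shape), atol=1e-3)

    def test_variant_c_requires_landmarks(self, grid_cloud):
        with pytest.raises(ConfigError):
            register(grid_cloud, grid_cloud, config=RegistrationConfig(variant="anisotropic_landmark"))

    def test_missing_topology_rejected(self):
        cloud = PointCloud(np.random.default_rng(0).normal(size=(10, 3)) + [0, 0, 1100])
        with pytest.raises(ConfigError):
            register(cloud, cloud)

    def test_trace_records_schedule_and_costs(self, grid_cloud):
        cfg = RegistrationConfig(
            variant="isotropic", alpha_start=8.0, alpha_period=2, max_iterations=5, tol=0.0
        )
        res = register(grid_cloud, grid_cloud.with_points(grid_cloud.points + [0, 0, 5.0]), config=cfg)
        assert [row["alpha"] for row in res.trace] == [8.0, 8.0, 4.0, 4.0, 2.0]
        assert all(row["total"] >= 0 for row in res.trace)
        assert all(row["e_d"] >= 0 and row["e_s"] >= 0 for row in res.trace)

    def test_stiffness_monotone_in_alpha_on_fixed_correspondences(self, grid_cloud, grid_topology):
        # one solve per alpha on a frozen target assignment: the mean per-arc
        # transform difference must not increase with stiffness
        rng = np.random.default_rng(7)
        n = grid_cloud.n
        M = build_incidence(grid_topology, n)
        U = grid_cloud.points + rng.normal(scale=5.0, size=(n, 3))
        D = assemble_D(grid_cloud.points)
        diffs = []
        for alpha in (1.0, 10.0, 100.0, 1000.0):
            A, B = assemble_system("isotropic", alpha, M, np.eye(4), D, U, np.ones(n))
            X = solve_step(A, B)
            arc = X.blocks[grid_topology.edges[:, 0]] - X.blocks[grid_topology.edges[:, 1]]
            diffs.append(np.linalg.norm(arc.reshape(len(arc), -1), axis=1).mean())
        assert all(a >= b - 1e-12 for a, b in zip(diffs, diffs[1:]))

    def test_registration_landmarks_pinned_in_variant_c(self, small_spec):
        from anricp.synth import step_pattern_pair

        src, tgt, _, lm = step_pattern_pair(small_spec.__class__(kind="step_pair", rows=8, cols=8, noise_enabled=False))
        cfg = RegistrationConfig(variant="anisotropic_landmark", max_iterations=10)
        res = register(src, tgt, landmarks=lm, config=cfg)
        reg_src, reg_tgt = lm.registration_pairs
        np.testing.assert_array_equal(res.correspondences.target_index[reg_src], reg_tgt)
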