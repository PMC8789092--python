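import numpy as np
import pytest
import scipy.linalg
import scipy.optimize
from scipy.stats import spearmanr

from helixcycle import (
    ExpressionMatrix,
    ModelConfig,
    Scale,
    compute_Q,
    compute_responsibilities,
    evaluate_objective,
    fit,
    fit_helix,
    initialize_state,
    simulate_cycle,
    update_basis,
    update_centroids,
    update_embedding,
)
from helixcycle.helix_core import (
    ConfigurationError,
    DegenerateInputError,
    HelixFit,
    QOperator,
    _helix_points,
)


def random_responsibilities(rng, n, k):
    r = rng.random((n, k)) + 1e-3
    return r / r.sum(axis=1, keepdims=True)


class TestResponsibilities:
    def test_single_cluster_gives_ones(self, rng):
        Z = rng.normal(size=(3, 7))
        R = compute_responsibilities(Z, Z.mean(axis=1, keepdims=True), 1.0)
        np.testing.assert_allclose(R, 1.0)

    def test_equidistant_centroids_split_evenly(self):
        Z = np.zeros((3, 1))
        Y = np.array([[1.0, -1.0], [0, 0], [0, 0]])
        R = compute_responsibilities(Z, Y, 1.0)
        np.testing.assert_allclose(R, [[0.5, 0.5]])

    def test_matches_scalar_hand_evaluation(self):
        # z=(1,0,0), y1=(1,0,0), y2=(-1,0,0), sigma=1:
        # r1 = exp(0)/(exp(0)+exp(-4)) = 1/(1+e^-4)
        Z = np.array([[1.0], [0.0], [0.0]])
        Y = np.array([[1.0, -1.0], [0, 0], [0, 0]])
        R = compute_responsibilities(Z, Y, 1.0)
        assert R[0, 0] == pytest.approx(1.0 / (1.0 + np.exp(-4.0)), abs=1e-12)

    def test_rows_sum_to_one_and_positive_at_tiny_sigma(self, rng):
        Z = rng.normal(scale=10.0, size=(3, 40))
        Y = rng.normal(scale=10.0, size=(3, 3))
        R = compute_responsibilities(Z, Y, 1e-3)
        assert np.isfinite(R).all()
        assert (R > 0).all() and (R <= 1).all()
        np.testing.assert_allclose(R.sum(axis=1), 1.0, atol=1e-12)


class TestCentroids:
    def test_one_hot_gives_cluster_means(self, rng):
        Z = rng.normal(size=(3, 6))
        R = np.zeros((6, 2))
        R[:3, 0] = 1.0
        R[3:, 1] = 1.0
        Y = update_centroids(Z, R)
        np.testing.assert_allclose(Y[:, 0], Z[:, :3].mean(axis=1))
        np.testing.assert_allclose(Y[:, 1], Z[:, 3:].mean(axis=1))

    def test_uniform_weights_give_global_mean(self, rng):
        Z = rng.normal(size=(3, 5))
        R = np.full((5, 3), 1.0 / 3)
        Y = update_centroids(Z, R)
        for k in range(3):
            np.testing.assert_allclose(Y[:, k], Z.mean(axis=1))

    def test_matches_elementwise_weighted_average(self, rng):
        Z = rng.normal(size=(3, 6))
        R = random_responsibilities(rng, 6, 2)
        Y = update_centroids(Z, R)
        for k in range(2):
            expected = sum(R[i, k] * Z[:, i] for i in range(6)) / R[:, k].sum()
            np.testing.assert_allclose(Y[:, k], expected, atol=1e-12)


class TestQOperator:
    def test_single_cluster_eigenstructure(self):
        # K=1: R=1s, Q^-1 = (1+lam+gam)I - (gam/N) J with eigenvalues
        # 1+lam (all-ones direction) and 1+lam+gam elsewhere
        n, lam, gam = 6, 2.0, 5.0
        R = np.ones((n, 1))
        Minv = compute_Q(R, lam, gam).dense()
        M = np.linalg.inv(Minv)
        eig = np.sort(np.linalg.eigvalsh(M))
        np.testing.assert_allclose(eig[0], 1 + lam, atol=1e-9)
        np.testing.assert_allclose(eig[1:], 1 + lam + gam, atol=1e-9)

    def test_gamma_zero_is_scaled_identity(self, rng):
        R = random_responsibilities(rng, 5, 2)
        Q = compute_Q(R, 3.0, 0.0)
        np.testing.assert_allclose(Q.dense(), np.eye(5) / 4.0, atol=1e-12)

    def test_action_matches_explicit_inverse(self, rng):
        R = random_responsibilities(rng, 8, 3)
        lam, gam = 2.0, 5.0
        nk = R.sum(axis=0)
        Minv_explicit = np.linalg.inv(
            (1 + lam + gam) * np.eye(8) - gam * (R / nk) @ R.T)
        Q = compute_Q(R, lam, gam)
        np.testing.assert_allclose(Q.dense(), Minv_explicit, atol=1e-10)
        np.testing.assert_allclose(
            Q.dense() @ ((1 + lam + gam) * np.eye(8) - gam * (R / nk) @ R.T),
            np.eye(8), atol=1e-10)

    def test_woodbury_route_agrees_with_dense(self, rng):
        R = random_responsibilities(rng, 60, 3)
        dense = QOperator(R, 50.0, 50.0, woodbury_threshold=1000)
        wood = QOperator(R, 50.0, 50.0, woodbury_threshold=10)
        assert wood.use_woodbury and not dense.use_woodbury
        B = rng.normal(size=(60, 4))
        np.testing.assert_allclose(wood.solve(B), dense.solve(B), atol=1e-8)

    def test_min_eigenvalue_bound_over_random_responsibilities(self, rng):
        # the matrix inverted is always PD with min eigenvalue >= 1+lam
        lam, gam = 50.0, 50.0
        for _ in range(100):
            n = int(rng.integers(4, 30))
            k = int(rng.integers(1, 5))
            R = random_responsibilities(rng, n, k)
            nk = R.sum(axis=0)
            M = (1 + lam + gam) * np.eye(n) - gam * (R / nk) @ R.T
            assert np.linalg.eigvalsh(M).min() >= 1 + lam - 1e-10


def eq7_objective(Z, X, W, C, R, lam, gam):
    """Working objective with Y eliminated (Y = ZR Gamma^-1)."""
    Y = Z @ R / R.sum(axis=0)
    d2 = ((Z.T[:, None, :] - Y.T[None, :, :]) ** 2).sum(axis=2)
    return (((X - W @ Z) ** 2).sum() + lam * ((Z - C) ** 2).sum()
            + gam * (R * d2).sum())


class TestEmbeddingUpdate:
    def test_small_weights_approach_pure_projection(self, rng):
        X = rng.normal(size=(6, 5))
        W = np.linalg.qr(rng.normal(size=(6, 3)))[0]
        C = rng.normal(size=(3, 5))
        R = random_responsibilities(rng, 5, 2)
        lam = gam = 1e-12
        Z = update_embedding(W, X, C, compute_Q(R, lam, gam), lam)
        np.testing.assert_allclose(Z, W.T @ X, atol=1e-9)

    def test_fixed_point_when_helix_equals_projection(self, rng):
        X = rng.normal(size=(6, 5))
        W = np.linalg.qr(rng.normal(size=(6, 3)))[0]
        C = W.T @ X
        R = random_responsibilities(rng, 5, 2)
        Z = update_embedding(W, X, C, compute_Q(R, 7.0, 0.0), 7.0)
        np.testing.assert_allclose(Z, W.T @ X, atol=1e-10)

    def test_is_the_exact_minimizer(self, rng):
        X = rng.normal(size=(6, 5))
        W = np.linalg.qr(rng.normal(size=(6, 3)))[0]
        C = rng.normal(size=(3, 5))
        R = random_responsibilities(rng, 5, 2)
        lam, gam = 3.0, 2.0
        Z = update_embedding(W, X, C, compute_Q(R, lam, gam), lam)
        base = eq7_objective(Z, X, W, C, R, lam, gam)
        for _ in range(200):
            pert = Z + rng.normal(scale=0.05, size=Z.shape)
            assert eq7_objective(pert, X, W, C, R, lam, gam) >= base - 1e-9
        res = scipy.optimize.minimize(
            lambda z: eq7_objective(z.reshape(3, 5), X, W, C, R, lam, gam),
            Z.ravel() + 0.1, method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
        assert base <= res.fun * (1 + 1e-6) + 1e-9
        np.testing.assert_allclose(res.x.reshape(3, 5), Z, atol=1e-4)


class TestBasisUpdate:
    def test_identity_procrustes(self):
        R = np.ones((4, 1))
        Q = compute_Q(R, 1.0, 0.0)
        # choose C, X so that A = C Q X^T = I/2: C = I3x4-ish
        C = np.eye(3, 4)
        X = np.eye(3, 4)
        W = update_basis(C, Q, X)
        np.testing.assert_allclose(W, np.eye(3), atol=1e-10)

    def test_attains_nuclear_norm(self, rng):
        C = rng.normal(size=(3, 10))
        X = rng.normal(size=(8, 10))
        R = random_responsibilities(rng, 10, 3)
        Q = compute_Q(R, 2.0, 3.0)
        W = update_basis(C, Q, X)
        A = Q.rmul(C) @ X.T
        np.testing.assert_allclose(W.T @ W, np.eye(3), atol=1e-10)
        nuc = scipy.linalg.svdvals(A).sum()
        assert np.trace(A @ W) == pytest.approx(nuc, rel=1e-8)

    def test_dominates_random_orthonormal_matrices(self, rng):
        A = rng.normal(size=(3, 10))
        U, _, Vt = scipy.linalg.svd(A, full_matrices=False)
        W = Vt.T @ U.T
        best = np.trace(A @ W)
        for _ in range(500):
            Wp = np.linalg.qr(rng.normal(size=(10, 3)))[0]
            assert np.trace(A @ Wp) <= best + 1e-9


class TestFitHelix:
    def test_exact_recovery_on_clean_points(self):
        theta = np.linspace(0.1, 6.0, 20)
        Z = _helix_points(1.0, 0.5, theta)
        h = fit_helix(Z)
        assert h.a == pytest.approx(1.0, abs=1e-6)
        assert h.v == pytest.approx(0.5, abs=1e-6)
        assert h.residual < 1e-10

    def test_broken_generator_leaves_residual(self):
        theta = np.linspace(0.1, 6.0, 20)
        Z = _helix_points(1.0, 0.5, theta)
        Z[0, 10:] += 2 * np.pi * 0.5   # full-turn shift on x only: not a helix
        h = fit_helix(Z)
        assert h.residual > 1e-3

    def test_zhat_matches_formula_exactly(self, rng):
        Z = rng.normal(size=(3, 30)) + np.array([[0.0], [0.0], [2.0]])
        h = fit_helix(Z)
        np.testing.assert_array_equal(h.Zhat, _helix_points(h.a, h.v, h.theta))
        assert h.a > 0 and h.v > 0

    def test_matches_nonlinear_least_squares_oracle(self, rng):
        true_theta = np.sort(rng.uniform(0, 4 * np.pi, 40))
        Z = _helix_points(2.0, 1.0, true_theta) + rng.normal(0, 0.05, (3, 40))
        h = fit_helix(Z)

        def resid(p):
            a, v = p[0], p[1]
            th = p[2:]
            return (Z - _helix_points(a, v, th)).ravel()

        sol = scipy.optimize.least_squares(
            resid, np.concatenate([[2.0, 1.0], true_theta]), method="lm")
        oracle = float((sol.fun ** 2).sum())
        assert h.residual <= oracle + 1e-4

    def test_warm_start_never_increases_residual(self, rng):
        Z = rng.normal(size=(3, 25))
        h1 = fit_helix(Z)
        h2 = fit_helix(Z, warm_start=h1)
        assert h2.residual <= h1.residual + 1e-12

    def test_too_few_cells_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_helix(np.zeros((3, 3)))


class TestObjective:
    def test_uniform_responsibilities_leave_only_entropy(self):
        # X = WZ, Z = Zhat, every cell at every centroid, uniform R:
        # only the entropy term survives: gam*sigma*N*K*(1/K)log(1/K) = -2 log 2
        from helixcycle.helix_core import ModelState

        cfg = ModelConfig(lam=1.0, gam=1.0, sigma=1.0, K=2)
        theta = np.array([1.0, 1.0])
        Zhat = _helix_points(1.0, 1.0, theta)
        helix = HelixFit(a=1.0, v=1.0, theta=theta, Zhat=Zhat, residual=0.0)
        Z = Zhat.copy()                       # two identical cells
        W = np.eye(4, 3)
        state = ModelState(config=cfg, X=W @ Z, gene_means=np.zeros(4), W=W,
                           Z=Z, helix=helix, R=np.full((2, 2), 0.5),
                           Y=Z.copy())
        assert evaluate_objective(state) == pytest.approx(-2 * np.log(2))

    def test_one_hot_responsibilities_zero_entropy(self, rng):
        from helixcycle.helix_core import ModelState
        cfg = ModelConfig(lam=2.0, gam=3.0, sigma=5.0, K=2)
        Z = rng.normal(size=(3, 4))
        helix = fit_helix(Z)
        W = np.linalg.qr(rng.normal(size=(6, 3)))[0]
        X = rng.normal(size=(6, 4))
        Y = rng.normal(size=(3, 2))
        R = np.zeros((4, 2))
        R[:2, 0] = 1.0
        R[2:, 1] = 1.0
        state = ModelState(config=cfg, X=X, gene_means=np.zeros(6), W=W, Z=Z,
                           helix=helix, R=R, Y=Y)
        d2 = ((Z.T[:, None, :] - Y.T[None, :, :]) ** 2).sum(axis=2)
        expected = (((X - W @ Z) ** 2).sum() + 2.0 * helix.residual
                    + 3.0 * (R * d2).sum())
        assert evaluate_objective(state) == pytest.approx(expected, rel=1e-12)

    def test_matches_term_by_term_loop(self, rng):
        from helixcycle.helix_core import ModelState
        cfg = ModelConfig(lam=1.5, gam=2.5, sigma=0.7, K=3)
        Z = rng.normal(size=(3, 6))
        helix = fit_helix(Z)
        W = np.linalg.qr(rng.normal(size=(8, 3)))[0]
        X = rng.normal(size=(8, 6))
        Y = rng.normal(size=(3, 3))
        R = random_responsibilities(rng, 6, 3)
        state = ModelState(config=cfg, X=X, gene_means=np.zeros(8), W=W, Z=Z,
                           helix=helix, R=R, Y=Y)
        total = 0.0
        for i in range(6):
            total += ((X[:, i] - W @ Z[:, i]) ** 2).sum()
            total += cfg.lam * ((Z[:, i] - helix.Zhat[:, i]) ** 2).sum()
            for k in range(3):
                total += cfg.gam * R[i, k] * ((Z[:, i] - Y[:, k]) ** 2).sum()
                total += cfg.gam * cfg.sigma * R[i, k] * np.log(R[i, k])
        assert evaluate_objective(state) == pytest.approx(total, rel=1e-10)


def _log2_matrix(values):
    return ExpressionMatrix(np.asarray(values, dtype=float), scale=Scale.log2)


class TestInitialization:
    def test_rank3_data_reconstructs_exactly(self, rng):
        D, N = 30, 25
        latent = rng.normal(size=(3, N))
        basis = rng.normal(size=(D, 3))
        X = basis @ latent + rng.normal(size=(D, 1))  # gene offsets
        state = initialize_state(_log2_matrix(X), ModelConfig(seed=1))
        err = ((state.X - state.W @ state.Z) ** 2).sum()
        assert err < 1e-16 * (X ** 2).sum()

    def test_deterministic_under_fixed_seed(self, rng):
        X = rng.normal(size=(20, 15)) ** 2
        a = initialize_state(_log2_matrix(X), ModelConfig(seed=7))
        b = initialize_state(_log2_matrix(X), ModelConfig(seed=7))
        np.testing.assert_array_equal(a.Z, b.Z)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.Y, b.Y)

    def test_basis_orthonormal(self, rng):
        X = rng.normal(size=(50, 40)) ** 2
        state = initialize_state(_log2_matrix(X), ModelConfig(seed=0))
        np.testing.assert_allclose(state.W.T @ state.W, np.eye(3), atol=1e-10)

    def test_too_few_cells_rejected(self, rng):
        X = rng.random((10, 2))
        with pytest.raises(ConfigurationError):
            initialize_state(_log2_matrix(X), ModelConfig(K=3))

    def test_constant_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            initialize_state(_log2_matrix(np.ones((10, 8))), ModelConfig())


class TestFit:
    def test_recovers_generating_angles_noiselessly(self):
        ds = simulate_cycle(n_genes=50, n_cells=120, noise_sd=0.0,
                            poisson=False, seed=3, within_phase_sd_frac=None)
        state = fit(ds.matrix, ModelConfig(seed=0))
        rho = spearmanr(state.helix.theta, ds.true_theta).statistic
        assert abs(rho) > 0.99

    def test_identical_runs_give_identical_traces(self):
        ds = simulate_cycle(n_genes=30, n_cells=40, seed=5)
        from helixcycle import filter_genes, normalize_log2
        m = normalize_log2(ds.matrix)
        cfg = ModelConfig(seed=2, max_iter=10)
        t1 = fit(m, cfg).objective_trace
        t2 = fit(m, cfg).objective_trace
        assert t1 == t2

    def test_objective_trace_non_increasing(self):
        from helixcycle import normalize_log2
        for seed in range(3):
            ds = simulate_cycle(n_genes=40, n_cells=50, noise_sd=0.3, seed=seed)
            state = fit(normalize_log2(ds.matrix), ModelConfig(seed=seed,
                                                               max_iter=30))
            tr = np.array(state.objective_trace)
            assert np.all(np.diff(tr) <= 1e-9 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_basis_stays_orthonormal(self):
        from helixcycle import normalize_log2
        ds = simulate_cycle(n_genes=40, n_cells=50, seed=1)
        state = fit(normalize_log2(ds.matrix), ModelConfig(max_iter=15))
        np.testing.assert_allclose(state.W.T @ state.W, np.eye(3), atol=1e-8)

    def test_scale_equivariance_without_clustering(self, rng):
        # at gam ~ 0 the objective at the optimum scales by c^2 when X -> cX
        X = np.abs(rng.normal(size=(25, 30))) + 0.5
        cfg = ModelConfig(lam=50.0, gam=1e-12, sigma=1e-6, max_iter=10, seed=0)
        s1 = fit(_log2_matrix(X), cfg)
        c = 3.0
        s2 = fit(_log2_matrix(c * X), cfg)
        assert s2.objective_trace[-1] == pytest.approx(
            c ** 2 * s1.objective_trace[-1], rel=1e-6)
        assert s2.helix.a == pytest.approx(c * s1.helix.a, rel=1e-4)
        assert s2.helix.v == pytest.approx(c * s1.helix.v, rel=1e-4)


class TestJointClosedForm:
    def test_one_pass_beats_random_perturbations(self, rng):
        # for fixed R and helix C, one pass of the closed-form updates
        # attains a lower full objective than random (W, Z) perturbations
        D, N, K, lam, gam, sigma = 7, 8, 2, 3.0, 2.0, 0.5
        X = rng.normal(size=(D, N))
        C = rng.normal(size=(3, N))
        R = random_responsibilities(rng, N, K)
        Q = compute_Q(R, lam, gam)
        W = update_basis(C, Q, X)
        Z = update_embedding(W, X, C, Q, lam)
        Y = update_centroids(Z, R)

        def full_obj(W_, Z_):
            Y_ = Z_ @ R / R.sum(axis=0)
            d2 = ((Z_.T[:, None, :] - Y_.T[None, :, :]) ** 2).sum(axis=2)
            return (((X - W_ @ Z_) ** 2).sum() + lam * ((Z_ - C) ** 2).sum()
                    + gam * (R * d2).sum())

        base = full_obj(W, Z)
        for _ in range(1000):
            Wp = np.linalg.qr(rng.normal(size=(D, 3)))[0]
            Zp = Z + rng.normal(scale=0.1, size=Z.shape)
            assert full_obj(Wp, Zp) >= base - 1e-9


class TestTuneParameters:
    def test_coordinate_search_returns_grid_values(self):
        from helixcycle import normalize_log2, tune_parameters

        ds = simulate_cycle(n_genes=30, n_cells=45, seed=8)
        m = normalize_log2(ds.matrix)
        cfg, scores = tune_parameters(
            m, ds.true_phase, lam_grid=(10.0, 50.0), gam_grid=(50.0,),
            sigma_grid=(0.001,), base=ModelConfig(max_iter=10, seed=0))
        assert cfg.lam in (10.0, 50.0)
        assert cfg.gam == 50.0 and cfg.sigma == 0.001
        assert all(0.0 <= a <= 1.0 for a in scores.values())
        # the returned config is the best probed one
        assert scores[(cfg.lam, cfg.gam, cfg.sigma)] == max(scores.values())
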