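"""Windowing, CP-constrained ALS and prediction scoring."""

import numpy as np
import pytest

import tvartlab as tl
from tvartlab.tvart import (
    TVARTConfig,
    TVARTFit,
    WindowedData,
    build_windows,
    export_temporal_modes,
    fit_tvart,
    full_rank,
    load_fit,
    predict_and_score,
    reconstruct_system_matrix,
    save_fit,
)


def _linear_series(A, b, x0, n, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.empty((n, len(x0)))
    x[0] = x0
    for t in range(1, n):
        x[t] = A @ x[t - 1] + b + noise * rng.normal(size=len(x0))
    return x


class TestBuildWindows:
    def test_window_count(self):
        states = np.zeros((61, 2))
        data = build_windows(states, 10, 1)
        assert data.T == 6 and data.M == 10

    def test_response_bounds(self):
        n, M, delay = 107, 10, 5
        states = np.arange(n, dtype=float)[:, None]
        data = build_windows(states, M, delay)
        last_pred = data.X[-1, 0, -1]
        last_resp = data.Y[-1, 0, -1]
        assert last_resp == last_pred + delay
        assert last_resp <= n - 1

    def test_predictors_partition_without_overlap(self):
        states = np.arange(85, dtype=float)[:, None]
        data = build_windows(states, 10, 3)
        preds = data.X[:, 0, :].ravel()
        assert len(preds) == data.T * 10
        assert len(np.unique(preds)) == len(preds)
        assert np.array_equal(preds, np.arange(data.T * 10, dtype=float))

    def test_augmentation_row(self):
        data = build_windows(np.zeros((30, 2)), 10, 1)
        assert np.all(data.X[:, -1, :] == 1.0)

    def test_insufficient_samples(self):
        with pytest.raises(ValueError, match="samples"):
            build_windows(np.zeros((10, 2)), 10, 1)


class TestFitTVART:
    def test_exact_recovery_of_rank1_affine_system(self):
        # noiseless data from x(t+1) = A x(t) + b with rank-1 [A|b].
        # A single autonomous run collapses onto the range of A and leaves
        # the factors unidentifiable, so the oracle pools windows from
        # several transients with distinct starting points.
        A = np.outer([1.0, 0.5], [0.76, 0.38])
        b = np.array([0.1, 0.05])
        rng = np.random.default_rng(7)
        Xs, Ys = [], []
        for _ in range(10):
            x = _linear_series(A, b, rng.uniform(-1, 1, 2), 41)
            d = build_windows(x, 40, 1)
            Xs.append(d.X)
            Ys.append(d.Y)
        data = WindowedData(np.concatenate(Xs), np.concatenate(Ys), 1)
        cfg = TVARTConfig(window_M=40, rank_R=1, delay_steps=1, eta=1e3, beta=0.0, seed=0)
        fit = fit_tvart(data, cfg)
        for k in range(data.T):
            Ab = reconstruct_system_matrix(fit, k)
            assert np.max(np.abs(Ab[:, :2] - A)) < 1e-3
            assert np.max(np.abs(Ab[:, 2] - b)) < 1e-3
        assert fit.r2 > 0.999

    @pytest.mark.parametrize("regularization", ["spline", "total_variation"])
    def test_cost_trace_non_increasing(self, regularization, rng):
        for trial in range(5):
            x = rng.normal(size=(240, 3)).cumsum(axis=0) * 0.05
            data = build_windows(x, 20, 2)
            cfg = TVARTConfig(window_M=20, rank_R=2, delay_steps=2, eta=0.7,
                              beta=0.4, regularization=regularization,
                              max_iter=25, seed=trial)
            fit = fit_tvart(data, cfg)
            ct = np.asarray(fit.cost_trace)
            assert np.all(np.diff(ct) <= 1e-9 * np.maximum(np.abs(ct[:-1]), 1.0))

    def test_switching_system_recovered_by_clustering(self):
        # alternate between two stable linear systems every 5 windows
        rng = np.random.default_rng(0)
        A1 = np.array([[0.9, 0.05], [0.0, 0.8]])
        A2 = np.array([[0.5, -0.2], [0.1, 0.3]])
        b1, b2 = np.array([0.1, 0.0]), np.array([-0.1, 0.2])
        M, n_windows = 30, 20
        x = np.zeros((M * n_windows + 1, 2))
        x[0] = [0.3, 0.3]
        for t in range(M * n_windows):
            k = (t // M // 5) % 2
            A, b = (A1, b1) if k == 0 else (A2, b2)
            x[t + 1] = A @ x[t] + b + 0.01 * rng.normal(size=2)
        data = build_windows(x, M, 1)
        fit = fit_tvart(data, TVARTConfig(window_M=M, rank_R=2, delay_steps=1,
                                          eta=10.0, beta=0.01, seed=1))
        truth = (np.arange(data.T) // 5) % 2
        ca = tl.cluster_temporal_modes_gmm(fit.U3, 2, seed=0)
        res = tl.match_clusters_to_attractors(ca.labels, truth)
        assert res["accuracy"] == 100.0

    def test_matches_ols_for_single_full_rank_window(self, rng):
        # R=N+1, T=1, beta=0, eta large reduces to ordinary affine LS
        x = rng.normal(size=(61, 2))
        data = build_windows(x, 60, 1)
        assert data.T == 1
        fit = fit_tvart(data, TVARTConfig(window_M=60, rank_R=full_rank(2),
                                          delay_steps=1, eta=1e8, beta=0.0,
                                          max_iter=300, rel_tol=1e-14, seed=0))
        Ab = reconstruct_system_matrix(fit, 0)
        Xa = data.X[0].T  # (M, 3) with ones column
        ols, *_ = np.linalg.lstsq(Xa, data.Y[0].T, rcond=None)
        assert np.max(np.abs(Ab - ols.T)) < 1e-6

    def test_seed_determinism(self, rng):
        x = rng.normal(size=(150, 2)).cumsum(axis=0) * 0.1
        data = build_windows(x, 15, 1)
        cfg = TVARTConfig(window_M=15, rank_R=2, delay_steps=1, seed=42, max_iter=10)
        f1, f2 = fit_tvart(data, cfg), fit_tvart(data, cfg)
        assert np.array_equal(f1.U3, f2.U3)

    def test_population_permutation_invariance(self):
        # the regularized cost is exactly equivariant under jointly
        # permuting populations in the data and the factor rows
        rng = np.random.default_rng(3)
        x = rng.normal(size=(200, 3)).cumsum(axis=0) * 0.05
        perm = np.array([2, 0, 1])
        cfg = TVARTConfig(window_M=20, rank_R=2, delay_steps=1, seed=0, max_iter=10)
        from tvartlab.tvart import _cost

        def stats(data):
            Gx = np.einsum("tim,tjm->tij", data.X, data.X)
            YXT = np.einsum("tim,tjm->tij", data.Y, data.X)
            yy = np.einsum("tim,tim->t", data.Y, data.Y)
            return Gx, YXT, yy

        fit = fit_tvart(build_windows(x, 20, 1), cfg)
        c1 = _cost(*stats(build_windows(x, 20, 1)), fit.U1, fit.U2, fit.U3, cfg)
        U2p = np.vstack([fit.U2[:3][perm], fit.U2[3:]])
        c2 = _cost(*stats(build_windows(x[:, perm], 20, 1)),
                   fit.U1[perm], U2p, fit.U3, cfg)
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_long_delay_shrinks_system_matrices(self, two_attractor_traj):
        # on stationary multistable data, growing the horizon drives A_k
        # toward 0 (predictions tend to window-wise constants)
        norms = {}
        for delay in (1, 150):
            data = build_windows(two_attractor_traj, 100, delay)
            fit = fit_tvart(data, TVARTConfig(window_M=100, rank_R=3,
                                              delay_steps=delay, seed=0, max_iter=30))
            sn = [np.linalg.norm(reconstruct_system_matrix(fit, k)[:, :2], 2)
                  for k in range(0, data.T, 25)]
            norms[delay] = np.mean(sn)
        assert norms[150] < 0.5 * norms[1]

    def test_rank_bound_enforced(self):
        data = build_windows(np.zeros((50, 2)), 10, 1)
        with pytest.raises(ValueError, match="rank"):
            fit_tvart(data, TVARTConfig(window_M=10, rank_R=4, delay_steps=1))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"window_M": 1},
            {"rank_R": 0},
            {"delay_steps": 0},
            {"eta": 0.0},
            {"beta": -0.1},
            {"regularization": "lasso"},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            TVARTConfig(**kwargs)


class TestReconstruction:
    def test_identity_factors_give_diagonal(self):
        U1 = np.eye(2)
        U2 = np.vstack([np.eye(2), np.zeros((1, 2))])
        U3 = np.array([[3.0, -1.0]])
        fit = TVARTFit(U1, U2, U3, TVARTConfig(rank_R=2))
        Ab = reconstruct_system_matrix(fit, 0)
        assert np.allclose(Ab[:, :2], np.diag([3.0, -1.0]))
        assert np.allclose(Ab[:, 2], 0.0)

    def test_matches_brute_force_triple_product(self, rng):
        N, R, T = 3, 2, 4
        U1, U2, U3 = rng.normal(size=(N, R)), rng.normal(size=(N + 1, R)), rng.normal(size=(T, R))
        fit = TVARTFit(U1, U2, U3, TVARTConfig(rank_R=R))
        for k in range(T):
            ref = U1 @ np.diag(U3[k]) @ U2.T
            assert np.allclose(reconstruct_system_matrix(fit, k), ref)

    def test_cp_scale_invariance(self, rng):
        N, R, T = 2, 2, 3
        U1, U2, U3 = rng.normal(size=(N, R)), rng.normal(size=(N + 1, R)), rng.normal(size=(T, R))
        fit = TVARTFit(U1, U2, U3, TVARTConfig(rank_R=R))
        c = 3.7
        scaled = TVARTFit(U1 * [1 / c, 1], U2, U3 * [c, 1], TVARTConfig(rank_R=R))
        for k in range(T):
            assert np.allclose(
                reconstruct_system_matrix(fit, k), reconstruct_system_matrix(scaled, k)
            )

    def test_out_of_range_window(self):
        fit = TVARTFit(np.eye(2), np.eye(3, 2), np.ones((2, 2)), TVARTConfig(rank_R=2))
        with pytest.raises(IndexError):
            reconstruct_system_matrix(fit, 2)


class TestScoring:
    def _fit_for(self, Y_values, P_values):
        # 1-D toy: build a WindowedData + fit whose predictions are forced
        Y = np.asarray(Y_values, float).reshape(1, 1, -1)
        M = Y.shape[2]
        X = np.zeros((1, 2, M))
        X[0, 1] = 1.0  # only the offset row is active
        U1 = np.array([[1.0]])
        U2 = np.array([[0.0], [1.0]])
        fit = TVARTFit(U1, U2, np.array([[1.0]]), TVARTConfig(rank_R=1))
        return fit, WindowedData(X, Y, 1)

    def test_perfect_prediction(self):
        x = _linear_series(np.array([[0.5]]), np.array([0.2]), np.array([1.0]), 50)
        data = build_windows(x, 10, 1)
        fit = fit_tvart(data, TVARTConfig(window_M=10, rank_R=1, delay_steps=1,
                                          eta=1e6, beta=0.0, seed=0))
        s = predict_and_score(fit, data)
        assert s["mse"] < 1e-10
        assert s["r2"] == pytest.approx(1.0, abs=1e-8)

    def test_predicting_global_mean_gives_zero_r2(self):
        Y = np.array([1.0, 2.0, 3.0])
        fit, data = self._fit_for(Y, None)
        fit.U3[0, 0] = Y.mean()  # constant prediction = global mean
        s = predict_and_score(fit, data)
        assert s["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_mse(self):
        # responses {1,2,3}, predictions {1,2,5} -> mse = 4/3
        fit, data = self._fit_for([1.0, 2.0, 3.0], None)
        data.X[0, 0] = [0.0, 1.0, 4.0]
        fit.U1[0, 0] = 1.0
        fit.U2[:, 0] = [1.0, 1.0]  # prediction = x + 1 -> {1, 2, 5} for x {0,0,4}
        fit.U3[0, 0] = 1.0
        s = predict_and_score(fit, data)
        assert s["mse"] == pytest.approx(4.0 / 3.0)


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        x = rng.normal(size=(120, 2)).cumsum(axis=0) * 0.1
        data = build_windows(x, 20, 1)
        fit = fit_tvart(data, TVARTConfig(window_M=20, rank_R=2, delay_steps=1,
                                          seed=0, max_iter=5))
        save_fit(tmp_path / "fit", fit)
        back = load_fit(tmp_path / "fit")
        assert np.array_equal(back.U1, fit.U1)
        assert np.array_equal(back.U2, fit.U2)
        assert np.array_equal(back.U3, fit.U3)
        assert back.config == fit.config
        export_temporal_modes(tmp_path / "u3.csv", fit)
        u3 = np.loadtxt(tmp_path / "u3.csv", delimiter=",", skiprows=1)
        assert np.allclose(u3, fit.U3)
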