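import numpy as np
import pandas as pd
import pytest

from guidenet import (
    IntensityMatrix,
    MarkerMap,
    NcrPenalty,
    OmicsMatrix,
    build_laplacian,
    grouping_check,
    ncr_cv,
    ncr_solve,
    network_penalty,
    qtl_regions,
)
from guidenet.simulate import SimulationConfig, simulate_dataset
from conftest import random_network
from _oracles import solve_ncr_qp


def two_node_net(w=1.0):
    return IntensityMatrix(
        pd.DataFrame([[0.0, w], [w, 0.0]], index=["a", "b"], columns=["a", "b"])
    )


class TestLaplacian:
    def test_two_connected_nodes(self):
        lap = build_laplacian(two_node_net())
        assert np.allclose(lap.to_numpy(), [[1, -1], [-1, 1]])
        beta = np.array([2.0, -1.0])
        assert beta @ lap.to_numpy() @ beta == pytest.approx((2.0 - (-1.0)) ** 2)

    def test_isolated_node_row_is_zero(self):
        w = pd.DataFrame(
            [[0, 1, 0], [1, 0, 0], [0, 0, 0]], index=list("abc"), columns=list("abc"), dtype=float
        )
        lap = build_laplacian(IntensityMatrix(w))
        arr = lap.to_numpy()
        assert np.all(arr[2] == 0) and np.all(arr[:, 2] == 0)
        beta = np.array([1.0, 1.0, 99.0])
        assert beta @ arr @ beta == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_quadratic_form_equals_edge_sum(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, k=5, density=0.6)
        lap = build_laplacian(net)
        beta = rng.normal(size=5)
        quad = beta @ lap.to_numpy() @ beta
        assert abs(quad - network_penalty(beta, net)) < 1e-12

    def test_psd_and_sqrt(self, rng):
        net = random_network(rng, k=8, density=0.5)
        lap = build_laplacian(net)
        eig = np.linalg.eigvalsh(lap.to_numpy())
        assert eig.min() > -1e-10
        root = lap.sqrt_matrix()
        assert np.abs(root @ root - lap.to_numpy()).max() < 1e-8

    def test_penalty_zero_when_beta_proportional_to_sqrt_strength(self, rng):
        net = random_network(rng, k=6, density=0.7)
        s = net.weights.sum(axis=1).to_numpy()
        beta = 3.14 * np.sqrt(s)
        assert network_penalty(beta, net) == pytest.approx(0.0, abs=1e-12)


class TestNcrSolve:
    def test_unpenalized_equals_ols(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        beta = ncr_solve(X, y, None, NcrPenalty(0.0, 0.0))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(beta - ols).max() < 1e-10

    def test_pure_smoothness_matches_closed_form(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        net = random_network(rng, k=5, density=0.8)
        lap = build_laplacian(net)
        lam2 = 2.5
        beta = ncr_solve(X, y, lap, NcrPenalty(0.0, lam2))
        closed = np.linalg.solve(X.T @ X + lam2 * lap.to_numpy(), X.T @ y)
        assert np.abs(beta - closed).max() < 1e-8

    def test_orthonormal_design_soft_thresholding(self, rng):
        q, n = 6, 40
        M = rng.normal(size=(n, q))
        Q, _ = np.linalg.qr(M)
        X = Q[:, :q]  # X'X = I
        y = rng.normal(size=n)
        lam1 = 0.8
        beta = ncr_solve(X, y, None, NcrPenalty(lam1, 0.0))
        b = X.T @ y
        expected = np.sign(b) * np.maximum(np.abs(b) - lam1 / 2, 0.0)
        assert np.abs(beta - expected).max() < 1e-8

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_qp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 8))
        y = rng.normal(size=10)
        net = random_network(rng, k=8, density=0.5)
        lap = build_laplacian(net)
        for lam1 in [0.2, 1.0, 4.0]:
            for lam2 in [0.0, 0.7, 3.0]:
                ours = ncr_solve(X, y, lap, NcrPenalty(lam1, lam2))
                oracle = solve_ncr_qp(X, y, lap.to_numpy(), lam1, lam2)
                assert np.abs(ours - oracle).max() < 1e-5

    def test_sparsity_monotone_in_l1(self, rng):
        X = rng.normal(size=(40, 10))
        y = X[:, 0] * 2 + X[:, 3] - X[:, 7] + rng.normal(size=40) * 0.5
        nnz = []
        for lam1 in np.geomspace(50, 0.01, 12):
            beta = ncr_solve(X, y, None, NcrPenalty(lam1, 0.0))
            nnz.append(int((beta != 0).sum()))
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))

    def test_dimension_mismatch_error(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        lap = build_laplacian(random_network(rng, k=6))
        with pytest.raises(ValueError, match="nodes"):
            ncr_solve(X, y, lap, NcrPenalty(0.1, 0.5))


class TestGrouping:
    def test_duplicated_predictors_converge_with_large_l2(self, rng):
        x = rng.normal(size=40)
        X = np.column_stack([x, x + rng.normal(size=40) * 0.01])
        y = x * 2 + rng.normal(size=40) * 0.1
        net = two_node_net(1.0)
        lap = build_laplacian(net)
        gaps = []
        for lam2 in [0.0, 1.0, 100.0, 10000.0]:
            beta = ncr_solve(X, y, lap, NcrPenalty(0.05, lam2))
            report = grouping_check(beta, net)
            gaps.append(report.attrs["weighted_mean_gap"])
        assert gaps[-1] < 1e-3
        assert gaps[-1] <= gaps[0]

    def test_empty_network_empty_report(self, rng):
        net = IntensityMatrix.empty(["a", "b"])
        report = grouping_check(np.array([1.0, -2.0]), net)
        assert len(report) == 0
        assert report.attrs["weighted_mean_gap"] == 0.0

    def test_smoothing_never_increases_weighted_gap(self, rng):
        net = random_network(rng, k=6, density=0.6)
        lap = build_laplacian(net)
        X = rng.normal(size=(50, 6))
        y = rng.normal(size=50)
        b0 = ncr_solve(X, y, lap, NcrPenalty(0.1, 0.0))
        b1 = ncr_solve(X, y, lap, NcrPenalty(0.1, 50.0))
        g0 = grouping_check(b0, net).attrs["weighted_mean_gap"]
        g1 = grouping_check(b1, net).attrs["weighted_mean_gap"]
        assert g1 <= g0 + 1e-12


class TestNcrCv:
    def test_noiseless_recovery(self, rng):
        n, q, p = 50, 8, 3
        X = OmicsMatrix(pd.DataFrame(rng.normal(size=(n, q))))
        beta = np.zeros((q, p))
        beta[0, 0] = beta[1, 1] = beta[2, 2] = 2.0
        Y = OmicsMatrix(pd.DataFrame(X.to_numpy() @ beta, columns=list("abc")))
        fit = ncr_cv(
            X, Y, None,
            lambda1_grid=np.array([1e-4, 1e-3]),
            lambda2_grid=np.array([0.0]),
            folds=4, seed=0,
        )
        assert np.abs(fit.fitted.to_numpy() - Y.to_numpy()).max() < 1e-2
        best = fit.cv_table.groupby("response")["cv_mse"].min()
        assert best.max() < 1e-4

    def test_single_point_grid_equals_direct_solve(self, rng):
        n, q = 30, 5
        Xarr = rng.normal(size=(n, q))
        X = OmicsMatrix(pd.DataFrame(Xarr))
        y = Xarr[:, 0] + rng.normal(size=n) * 0.3
        Y = OmicsMatrix(pd.DataFrame({"y": y}))
        net = random_network(rng, k=q)
        lap = build_laplacian(net)
        fit = ncr_cv(
            X, Y, lap,
            lambda1_grid=np.array([0.5]),
            lambda2_grid=np.array([1.0]),
            folds=3, seed=1, standardize=False,
        )
        direct = ncr_solve(Xarr, y - y.mean(), lap, NcrPenalty(0.5, 1.0))
        assert np.abs(fit.coefficients["y"].to_numpy() - direct).max() < 1e-10

    def test_grouped_signal_prefers_network_penalty(self):
        """With block-correlated active predictors, CV should pick lambda2 > 0
        most of the time and never predict worse than the plain LASSO."""
        wins, mse_pairs = 0, []
        reps = 7
        for seed in range(reps):
            cfg = SimulationConfig(
                n_samples=90, n_guiding=30, guiding_kind="ggm-expression",
                n_target=1, n_blocks=1, block_size=5, effect_size=0.8,
                noise_sd=1.0, group_shift_sd=0.0, seed=seed,
            )
            X, Y, truth = simulate_dataset(cfg)
            w = np.abs(truth.true_guiding_precision.to_numpy())
            np.fill_diagonal(w, 0.0)
            net = IntensityMatrix(
                pd.DataFrame(w, index=X.feature_ids, columns=X.feature_ids)
            )
            lap = build_laplacian(net)
            # train/test split
            tr = list(range(60))
            te = list(range(60, 90))
            Xtr = OmicsMatrix(X.values.iloc[tr])
            Ytr = OmicsMatrix(Y.values.iloc[tr])
            fit = ncr_cv(Xtr, Ytr, lap, folds=5, seed=seed)
            lasso_fit = ncr_cv(
                Xtr, Ytr, lap, lambda2_grid=np.array([0.0]), folds=5, seed=seed
            )
            pen = fit.penalties[fit.response_ids[0]]
            if pen.lambda2 > 0:
                wins += 1
            Xte = X.values.iloc[te].to_numpy()
            yte = Y.values.iloc[te].to_numpy().ravel()
            for f, tag in ((fit, "ncr"), (lasso_fit, "lasso")):
                pred = Xte @ f.coefficients.to_numpy().ravel() + f.intercepts.iloc[0]
                mse_pairs.append((tag, seed, float(np.mean((yte - pred) ** 2))))
        assert wins > reps / 2
        ncr_mse = np.mean([m for t, _, m in mse_pairs if t == "ncr"])
        lasso_mse = np.mean([m for t, _, m in mse_pairs if t == "lasso"])
        assert ncr_mse <= lasso_mse * 1.05

    def test_fewer_samples_than_folds_error(self, rng):
        X = OmicsMatrix(pd.DataFrame(rng.normal(size=(3, 2))))
        Y = OmicsMatrix(pd.DataFrame(rng.normal(size=(3, 1))))
        with pytest.raises(ValueError, match="folds"):
            ncr_cv(X, Y, None, folds=5)


class TestQtlRegions:
    def _fit_with_coefs(self, coefs: pd.DataFrame):
        from guidenet.ncr import NcrFit

        n = 4
        fitted = pd.DataFrame(np.zeros((n, coefs.shape[1])), columns=coefs.columns)
        return NcrFit(
            coefficients=coefs,
            intercepts=pd.Series(0.0, index=coefs.columns),
            penalties={},
            fitted=fitted,
        )

    def test_all_zero_column_gives_empty_list(self):
        mmap = MarkerMap(
            pd.DataFrame({"marker": ["m1", "m2"], "chromosome": [1, 1], "position": [0.0, 10.0]})
        )
        coefs = pd.DataFrame({"t1": [0.0, 0.0]}, index=["m1", "m2"])
        out = qtl_regions(self._fit_with_coefs(coefs), mmap)
        assert len(out["t1"]) == 0

    def test_unmapped_feature_error(self):
        mmap = MarkerMap(
            pd.DataFrame({"marker": ["m1"], "chromosome": [1], "position": [0.0]})
        )
        coefs = pd.DataFrame({"t1": [1.0, 2.0]}, index=["m1", "mX"])
        with pytest.raises(ValueError, match="mX"):
            qtl_regions(self._fit_with_coefs(coefs), mmap)

    def test_planted_qtl_detected_near_causal_marker(self):
        cfg = SimulationConfig(
            n_samples=120, n_guiding=40, n_chromosomes=2, n_target=2,
            n_blocks=2, block_size=3, effect_size=2.0, noise_sd=0.3,
            group_shift_sd=0.0, seed=7,
        )
        X, Y, truth = simulate_dataset(cfg)
        from guidenet import linear_map_network

        net = linear_map_network(truth.marker_map)
        net = IntensityMatrix(net.weights.loc[X.feature_ids, X.feature_ids])
        lap = build_laplacian(net)
        fit = ncr_cv(X, Y, lap, folds=4, seed=1)
        regions = qtl_regions(fit, truth.marker_map)
        order = {m: i for i, m in enumerate(truth.marker_map.marker_ids)}
        for resp in fit.response_ids:
            causal = set(truth.true_coefficients.index[truth.true_coefficients[resp] != 0])
            found = set(regions[resp]["marker"])
            # at least one causal marker or an immediate map neighbour is flagged
            neighbours = set()
            for m in found:
                i = order[m]
                neighbours.update(
                    truth.marker_map.marker_ids[max(0, i - 1) : i + 2]
                )
            assert causal & (found | neighbours)

    def test_shared_causal_marker_reported_for_both_responses(self):
        cfg = SimulationConfig(
            n_samples=100, n_guiding=30, n_chromosomes=1, n_target=2,
            n_blocks=1, block_size=4, effect_size=2.0, noise_sd=0.3,
            group_shift_sd=0.0, seed=11,
        )
        X, Y, truth = simulate_dataset(cfg)
        fit = ncr_cv(X, Y, None, folds=4, seed=2)
        regions = qtl_regions(fit, truth.marker_map)
        sets = [set(r["marker"]) for r in regions.values()]
        assert sets[0] & sets[1]
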