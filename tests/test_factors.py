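"""Horn retention, ML factor analysis recovery, Harman scoring identities,
viscosity regression bookkeeping, transfer, and the random-predictor null."""

import warnings

import numpy as np
import pandas as pd
import pytest

from viscperc.factors import (bootstrap_random_predictor_baseline,
                              build_viscosity_model, factor_scores,
                              fit_factor_model, fit_viscosity_regression,
                              horn_parallel_analysis, predict_transfer,
                              procrustes_align, tucker_congruence)
from viscperc.synth import (default_loadings, generate_feature_ratings,
                            generate_viscosity_ratings, make_ground_truth,
                            make_set1_design, make_set2_design)


def block_loadings(primary=0.8, cross=0.0):
    lam = np.zeros((20, 4))
    for j in range(4):
        lam[5 * j:5 * j + 5, j] = primary
        if cross:
            lam[5 * j:5 * j + 5, (j + 1) % 4] = cross
    return lam


def four_factor_data(seed, n=192, noise_sd=0.3, primary=0.8):
    rng = np.random.default_rng(seed)
    lam = block_loadings(primary)
    F = rng.standard_normal((n, 4))
    return F @ lam.T + noise_sd * rng.standard_normal((n, 20)), lam, F


class TestHorn:
    def test_pure_noise_retains_zero(self):
        hits = 0
        for seed in range(25):
            X = np.random.default_rng(10_000 + seed).standard_normal((200, 20))
            hits += horn_parallel_analysis(X, n_random=60, seed=seed) == 0
        assert hits >= 23  # >= 90% of seeds

    def test_four_factor_structure_retained(self):
        hits = 0
        for seed in range(25):
            X, _, _ = four_factor_data(seed)
            hits += horn_parallel_analysis(X, n_random=60, seed=seed) == 4
        assert hits >= 24  # >= 95% of seeds

    def test_rank_one_structure_retains_one(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.standard_normal(200), np.ones(20)) * 0.8 \
            + 0.3 * rng.standard_normal((200, 20))
        assert horn_parallel_analysis(X, seed=0) == 1

    def test_invariant_to_permutation_and_rescaling(self):
        X, _, _ = four_factor_data(42)
        k0 = horn_parallel_analysis(X, seed=1)
        rng = np.random.default_rng(1)
        perm = rng.permutation(20)
        scaled = X[:, perm] * rng.uniform(0.5, 5.0, size=20) + rng.uniform(-2, 2, 20)
        assert horn_parallel_analysis(scaled, seed=1) == k0

    def test_constant_column_rejected(self):
        X = np.random.default_rng(0).standard_normal((50, 5))
        X[:, 2] = 1.0
        with pytest.raises(ValueError):
            horn_parallel_analysis(X)


class TestFactorModel:
    def test_noiseless_reconstruction(self):
        X, _, _ = four_factor_data(0, noise_sd=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # expected Heywood
            m = fit_factor_model(X, 4)
        R = np.corrcoef(X, rowvar=False)
        assert np.abs(m.implied_correlation() - R).max() < 1e-3

    def test_heywood_warning_emitted(self):
        X, _, _ = four_factor_data(0, noise_sd=0.0)
        with pytest.warns(RuntimeWarning, match="Heywood"):
            fit_factor_model(X, 4)

    def test_loading_recovery_congruence(self):
        congs = []
        for seed in range(10):
            X, lam, _ = four_factor_data(seed, noise_sd=0.1)
            m = fit_factor_model(X, 4)
            congs.append(tucker_congruence(lam, procrustes_align(lam, m.loadings)))
        assert min(congs) >= 0.95

    def test_rotated_truth_gives_same_fit_quality(self):
        # ML fit is invariant to orthogonal rotation of the generating loadings
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        lam = block_loadings(0.8)
        F = rng.standard_normal((300, 4))
        E = 0.2 * rng.standard_normal((300, 20))
        X1 = F @ lam.T + E
        X2 = F @ (lam @ Q).T @ np.eye(20) + E  # same column space
        m1 = fit_factor_model(X1, 4)
        m2 = fit_factor_model(pd.DataFrame(X2), 4)
        r1 = np.abs(m1.implied_correlation() - np.corrcoef(X1, rowvar=False)).max()
        r2 = np.abs(m2.implied_correlation() - np.corrcoef(X2, rowvar=False)).max()
        assert r1 == pytest.approx(r2, abs=2e-3)

    def test_majority_positive_sign_convention(self):
        X, _, _ = four_factor_data(3, noise_sd=0.2)
        m = fit_factor_model(X, 4)
        for j in range(4):
            col = m.loadings[:, j]
            assert (col > 0).sum() >= (col < 0).sum()

    def test_too_many_factors_rejected(self):
        X, _, _ = four_factor_data(0)
        with pytest.raises(ValueError):
            fit_factor_model(X, 20)


class TestFactorScores:
    def test_score_weights_left_inverse_identity(self):
        X, lam, F = four_factor_data(1, noise_sd=0.2)
        m = fit_factor_model(X, 4)
        W = m.score_weights
        np.testing.assert_allclose(m.loadings.T @ W, np.eye(4), atol=1e-8)

    def test_exact_factor_data_recovers_scores(self):
        # data standardized by the model, generated exactly as Z = F . L^T
        rng = np.random.default_rng(2)
        lam = default_loadings()
        F = rng.standard_normal((100, 4))
        Z = F @ lam.T
        from viscperc.factors import FactorModel
        m = FactorModel(lam, np.full(20, 0.5), [f"f{i}" for i in range(20)],
                        list("abcd"), train_mean=np.zeros(20), train_sd=np.ones(20))
        scores = m.standardize(pd.DataFrame(Z, columns=m.feature_names)) @ m.score_weights
        np.testing.assert_allclose(scores, F, atol=1e-8)

    def test_training_scores_centered(self):
        X, _, _ = four_factor_data(4, noise_sd=0.2)
        m = fit_factor_model(X, 4)
        s = factor_scores(m, pd.DataFrame(X, columns=m.feature_names))
        assert np.abs(s.mean(axis=0)).max() < 1e-8

    def test_feature_mismatch_reported(self):
        X, _, _ = four_factor_data(5)
        m = fit_factor_model(X, 4)
        bad = pd.DataFrame(X[:, :19], columns=m.feature_names[:19])
        with pytest.raises(ValueError, match="missing"):
            factor_scores(m, bad)


class TestViscosityRegression:
    def test_degrees_of_freedom_192_rows(self):
        X, _, F = four_factor_data(6, noise_sd=0.1)
        y = 0.5 + F @ [0.1, 0.05, -0.05, 0.02]
        _, rep = fit_viscosity_regression(pd.DataFrame(F), y)
        assert (rep.df1, rep.df2, rep.n) == (4, 187, 192)

    def test_noiseless_linear_r2_one(self):
        rng = np.random.default_rng(7)
        F = rng.standard_normal((50, 4))
        y = 1.0 + F @ [0.2, -0.1, 0.3, 0.05]
        _, rep = fit_viscosity_regression(pd.DataFrame(F), y)
        assert rep.r2 == pytest.approx(1.0)

    def test_coefficient_recovery_within_two_se(self):
        rng = np.random.default_rng(8)
        beta = np.array([0.4, 0.12, -0.08, 0.05, 0.1])
        within = 0
        for _ in range(100):
            F = rng.standard_normal((192, 4))
            y = beta[0] + F @ beta[1:] + 0.05 * rng.standard_normal(192)
            params, rep = fit_viscosity_regression(pd.DataFrame(F), y)
            se = 0.05 / np.sqrt(192)  # conservative se scale for unit-variance F
            within += np.all(np.abs(params[1:] - beta[1:]) < 2.5 * se * np.sqrt(1.1))
        assert within >= 90


class TestTransfer:
    def _fitted(self, seed=0):
        d1 = make_set1_design()
        t1 = make_ground_truth(d1, seed=seed, noise_sd=0.05)
        feats = generate_feature_ratings(t1, d1, 1, seed)
        visc = generate_viscosity_ratings(t1, d1, 4, seed)
        m = fit_factor_model(feats, 4)
        s = factor_scores(m, feats)
        vm, rep = build_viscosity_model(m, s, visc)
        return vm, rep, feats, visc

    def test_transfer_to_training_set_is_idempotent(self):
        vm, rep, feats, visc = self._fitted()
        pred, _ = predict_transfer(vm, feats, visc, standardize_with="self")
        train_pred = vm.predict_from_scores(
            factor_scores(vm.factor_model, feats).to_numpy())
        np.testing.assert_allclose(pred, train_pred, atol=1e-10)

    def test_transfer_df_56_rows(self):
        vm, _, _, _ = self._fitted()
        d2 = make_set2_design()
        t2 = make_ground_truth(d2, seed=77, noise_sd=0.05)
        feats2 = generate_feature_ratings(t2, d2, 2, 77)
        visc2 = generate_viscosity_ratings(t2, d2, 4, 77)
        _, rep = predict_transfer(vm, feats2, visc2)
        assert (rep.df1, rep.df2, rep.n) == (1, 54, 56)

    def test_shared_generative_model_transfers_well(self):
        r2 = []
        for seed in range(3):
            vm, _, _, _ = self._fitted(seed)
            d2 = make_set2_design()
            t2 = make_ground_truth(d2, seed=seed + 500, noise_sd=0.05)
            feats2 = generate_feature_ratings(t2, d2, 2, seed + 1)
            visc2 = generate_viscosity_ratings(t2, d2, 4, seed + 1)
            _, rep = predict_transfer(vm, feats2, visc2)
            r2.append(rep.r2)
        assert min(r2) >= 0.85


class TestRandomPredictorBaseline:
    def test_saturation_at_n_minus_one(self):
        rng = np.random.default_rng(9)
        y = rng.uniform(size=30)
        out = bootstrap_random_predictor_baseline(y, n_predictors=29, n_boot=100,
                                                  seed=0)
        assert out["mean"] == pytest.approx(1.0, abs=1e-8)

    def test_single_predictor_expected_r2(self):
        rng = np.random.default_rng(10)
        y = rng.uniform(size=192)
        out = bootstrap_random_predictor_baseline(y, n_predictors=1, n_boot=800,
                                                  seed=1)
        assert out["mean"] == pytest.approx(1 / 191, rel=0.25)

    def test_mean_r2_monotone_in_predictor_count(self):
        rng = np.random.default_rng(11)
        y = rng.uniform(size=60)
        means = [bootstrap_random_predictor_baseline(y, k, n_boot=150, seed=2)["mean"]
                 for k in (1, 10, 25, 45)]
        assert all(np.diff(means) > 0)

    def test_full_chain_recovery(self):
        """Simulate -> rate -> Horn(=4) -> fit -> regress -> transfer."""
        d1, d2 = make_set1_design(), make_set2_design()
        t1 = make_ground_truth(d1, seed=3, noise_sd=0.05)
        t2 = make_ground_truth(d2, seed=1503, noise_sd=0.05)
        feats1 = generate_feature_ratings(t1, d1, 1, 3)
        visc1 = generate_viscosity_ratings(t1, d1, 4, 3)
        assert horn_parallel_analysis(feats1, seed=3) == 4
        m = fit_factor_model(feats1, 4)
        s = factor_scores(m, feats1)
        vm, rep = build_viscosity_model(m, s, visc1)
        assert rep.r2 > 0.9 and (rep.df1, rep.df2) == (4, 187)
        feats2 = generate_feature_ratings(t2, d2, 2, 4)
        visc2 = generate_viscosity_ratings(t2, d2, 4, 4)
        _, trep = predict_transfer(vm, feats2, visc2)
        assert trep.r2 >= 0.85 and (trep.df1, trep.df2) == (1, 54)
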