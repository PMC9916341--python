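"""Receptor-model source apportionment: uncertainties, weighted NMF, APCS-MLR."""

import numpy as np
import pytest

from aquarisk.sources import (
    UncertaintyError,
    UncertaintyModel,
    apcs_mlr,
    build_uncertainty,
    factor_contributions,
    fit_pmf,
    match_factors,
    q_value,
    signal_to_noise,
    varimax,
)


class TestUncertainty:
    def test_below_detection_limit(self):
        U = build_uncertainty(np.array([[0.05]]), ["Cr"])
        assert U[0, 0] == pytest.approx(5.0 / 6.0 * 0.1, abs=1e-5)

    def test_above_detection_limit(self):
        U = build_uncertainty(np.array([[2.0]]), ["Cr"])
        assert U[0, 0] == pytest.approx(np.sqrt(0.01 + (0.035 * 2.0) ** 2), abs=1e-5)

    def test_zero_mdl_limit(self):
        U = build_uncertainty(np.array([[1.0]]), ["v"], UncertaintyModel(mdl={"v": 0.0}))
        assert U[0, 0] == pytest.approx(0.035)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            build_uncertainty(np.array([[-1.0]]), ["Cr"])

    def test_bad_error_fraction(self):
        with pytest.raises(ValueError):
            UncertaintyModel(error_fraction=1.5)


class TestSignalToNoise:
    def test_all_below_uncertainty(self):
        X = np.full((4, 2), 0.5)
        U = np.ones((4, 2))
        assert (signal_to_noise(X, U) == 0).all()

    def test_twice_uncertainty(self):
        X = np.full((4, 2), 2.0)
        U = np.ones((4, 2))
        np.testing.assert_allclose(signal_to_noise(X, U), 1.0)

    def test_matches_bruteforce_loop(self, rng):
        X = rng.uniform(0, 3, (20, 5))
        U = rng.uniform(0.5, 1.5, (20, 5))
        expected = np.array(
            [
                np.mean(
                    [
                        (X[i, j] - U[i, j]) / U[i, j] if X[i, j] > U[i, j] else 0.0
                        for i in range(20)
                    ]
                )
                for j in range(5)
            ]
        )
        np.testing.assert_allclose(signal_to_noise(X, U), expected)

    def test_zero_uncertainty_rejected(self):
        with pytest.raises(UncertaintyError):
            signal_to_noise(np.ones((2, 2)), np.zeros((2, 2)))


class TestPmf:
    def test_exact_factorization_reaches_zero_q(self, rng):
        G = rng.uniform(0.5, 2.0, (30, 3))
        F = rng.uniform(0.1, 3.0, (3, 8))
        X = G @ F
        U = np.full_like(X, 0.1)
        model = fit_pmf(X, U, p=3, n_starts=5, seed=0)
        assert model.q_true <= 1e-6 * X.size

    def test_q_identity_when_residuals_equal_uncertainty(self, rng):
        # forcing e_ij = u_ij makes every scaled residual 1, so Q = n*m
        G = rng.uniform(0.5, 2.0, (10, 2))
        F = rng.uniform(0.1, 3.0, (2, 6))
        recon = G @ F
        U = np.full_like(recon, 0.05)
        X = recon + U
        assert q_value(X, U, G, F) == pytest.approx(X.size)

    def test_objective_monotone_nonincreasing(self, mixture3):
        X, U, _, _ = mixture3
        model = fit_pmf(X, U, p=3, n_starts=3, seed=4)
        diffs = np.diff(model.q_history)
        assert (diffs <= 1e-8 * np.abs(model.q_history[:-1]) + 1e-9).all()

    def test_seeded_reproducibility(self, mixture3):
        X, U, _, _ = mixture3
        a = fit_pmf(X, U, p=3, n_starts=3, seed=7)
        b = fit_pmf(X, U, p=3, n_starts=3, seed=7)
        np.testing.assert_array_equal(a.G, b.G)
        np.testing.assert_array_equal(a.F, b.F)

    def test_profile_recovery_on_generator_truth(self, mixture3):
        X, U, _, F_true = mixture3
        model = fit_pmf(X, U, p=3, n_starts=20, seed=3)
        _, sims = match_factors(model.F, F_true)
        assert sims.min() >= 0.95

    def test_bad_shapes_and_p(self):
        X = np.ones((4, 3))
        with pytest.raises(ValueError):
            fit_pmf(X, np.ones((4, 2)), p=2)
        with pytest.raises(ValueError):
            fit_pmf(X, np.ones((4, 3)), p=3)


class TestContributions:
    def test_single_factor_is_everything(self, rng):
        G = rng.uniform(0.5, 2.0, (10, 1))
        F = rng.uniform(0.5, 2.0, (1, 4))
        model = fit_pmf(G @ F, np.full((10, 4), 0.1), p=1, n_starts=2, seed=0)
        np.testing.assert_allclose(factor_contributions(model), 100.0)

    def test_columns_sum_to_100(self, mixture3):
        X, U, _, _ = mixture3
        model = fit_pmf(X, U, p=3, n_starts=5, seed=1)
        np.testing.assert_allclose(factor_contributions(model).sum(axis=0), 100.0)

    def test_known_mixing_recovered_within_10_points(self, mixture3):
        X, U, G_true, F_true = mixture3
        model = fit_pmf(X, U, p=3, n_starts=20, seed=3)
        perm, _ = match_factors(model.F, F_true)
        est = factor_contributions(model)[perm, :]
        mass_true = G_true.sum(axis=0)[:, None] * F_true
        truth = mass_true / mass_true.sum(axis=0)[None, :] * 100.0
        assert np.abs(est - truth).max() <= 10.0


class TestApcsMlr:
    @staticmethod
    def _two_source(rng, split=0.7, n=200, m=8):
        F = np.zeros((2, m))
        F[0, : m // 2] = rng.uniform(2, 5, m // 2)
        F[1, m // 2 :] = rng.uniform(2, 5, m - m // 2)
        G = rng.lognormal(0.5, 0.5, size=(n, 2))
        shares = np.array(
            [(G[:, [k]] * F[k]).sum() for k in range(2)], dtype=float
        )
        shares /= shares.sum()
        G[:, 0] *= split / shares[0]
        G[:, 1] *= (1 - split) / shares[1]
        return G @ F + rng.normal(0, 0.05, size=(n, m)), G, F

    def test_single_source_is_100pct(self, rng):
        F = rng.uniform(1, 4, (1, 6))
        G = rng.lognormal(0, 0.5, (100, 1))
        X = G @ F + rng.normal(0, 0.02, (100, 6))
        res = apcs_mlr(X, n_factors=1)
        assert res.contributions_pct[0] == pytest.approx(100.0, abs=2.0)

    def test_70_30_split_within_10_points(self, rng):
        X, _, _ = self._two_source(rng)
        res = apcs_mlr(X, n_factors=2)
        got = np.sort(res.contributions_pct)[::-1]
        assert abs(got[0] - 70.0) <= 10.0 and abs(got[1] - 30.0) <= 10.0

    def test_varimax_preserves_communalities(self, rng):
        A = rng.normal(size=(12, 4))
        V = varimax(A)
        np.testing.assert_allclose((A**2).sum(axis=1), (V**2).sum(axis=1), atol=1e-8)

    def test_constant_column_raises(self, rng):
        X = rng.uniform(0, 1, (20, 3))
        X[:, 1] = 2.0
        with pytest.raises(np.linalg.LinAlgError):
            apcs_mlr(X, n_factors=2)


class TestCrossValidation:
    def test_pmf_and_apcs_agree_on_dominant_source(self, mixture3):
        # the two routes must attribute each parameter to the same source
        X, U, G_true, F_true = mixture3
        model = fit_pmf(X, U, p=3, n_starts=20, seed=3)
        perm, _ = match_factors(model.F, F_true)
        pmf_dominant = np.argmax(factor_contributions(model)[perm, :], axis=0)
        apcs = apcs_mlr(X, n_factors=3)
        # match rotated loadings to true profiles by cosine as well
        perm_a, _ = match_factors(apcs.loadings.T, F_true)
        apcs_dominant = np.argmax(np.abs(apcs.loadings.T[perm_a, :]), axis=0)
        assert (pmf_dominant == apcs_dominant).mean() >= 0.8
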