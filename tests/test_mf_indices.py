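"""Index equations, discriminant fit, centroid distances, concordance."""

import numpy as np
import pytest

from mfindices import (
    DataError,
    EffectSummary,
    ProfileTable,
    SingularCorrelationError,
    axis_angle,
    classify_concordance,
    fit_mf_model,
    mahalanobis_centroid_distance,
    mfc_scores,
    mfd_scores,
    mfp_scores,
    mft_scores,
    score_profiles,
    summarize_indices,
)
from mfindices.mf_indices import _partial_corr_given_binary

from conftest import force_identity_correlation, make_profiles, pooled_variance


def _eff(d, R, n_male=100, n_female=100):
    d = np.asarray(d, dtype=float)
    return EffectSummary(
        d=d, d_norm=float(np.linalg.norm(d)), R=np.asarray(R, dtype=float),
        n_male=n_male, n_female=n_female,
    )


class TestDiscriminantFit:
    def test_identity_correlation_gives_a_equals_d(self, small_profiles):
        prof = force_identity_correlation(small_profiles)
        model = fit_mf_model(prof)
        np.testing.assert_allclose(model.a, model.eff.d, atol=1e-8)
        assert model.D_M == pytest.approx(model.eff.d_norm, abs=1e-8)

    def test_two_by_two_explicit_inverse(self, two_trait_profiles):
        # R = [[1,-.5],[-.5,1]], d = (.5,-.5) -> a = (1/3,-1/3), D_M = sqrt(1/3)
        eff = _eff([0.5, -0.5], [[1, -0.5], [-0.5, 1]])
        a = np.linalg.solve(eff.R, eff.d)
        np.testing.assert_allclose(a, [1 / 3, -1 / 3], atol=1e-12)
        D_M, _ = mahalanobis_centroid_distance(eff)
        assert D_M == pytest.approx(np.sqrt(1 / 3), abs=1e-12)

    def test_duplicate_trait_raises_singularity_error(self, small_profiles):
        values = np.column_stack(
            [small_profiles.values, small_profiles.values[:, 0]]
        )
        dup = ProfileTable(values=values, sex=small_profiles.sex)
        with pytest.raises(SingularCorrelationError, match="condition number"):
            fit_mf_model(dup)

    def test_residual_of_linear_solve(self, small_profiles):
        model = fit_mf_model(small_profiles)
        assert np.max(np.abs(model.eff.R @ model.a - model.eff.d)) < 1e-8

    def test_direction_agrees_with_sklearn_lda(self, small_profiles):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        from mfindices import standardize

        model = fit_mf_model(small_profiles)
        _, z = standardize(small_profiles)
        lda = sklearn.LinearDiscriminantAnalysis(
            solver="lsqr", priors=[0.5, 0.5]
        ).fit(z, small_profiles.sex)
        cos = model.a @ lda.coef_.ravel() / (
            np.linalg.norm(model.a) * np.linalg.norm(lda.coef_)
        )
        assert cos == pytest.approx(1.0, abs=1e-6)


class TestScoreEquations:
    def test_mfd_examples(self):
        eff = _eff([0.6, -0.8], np.eye(2))
        assert mfd_scores(np.zeros((1, 2)), eff)[0] == pytest.approx(0.0)
        np.testing.assert_allclose(
            mfd_scores(np.array([[1.0, -1.0]]), eff), [1.4], atol=1e-12
        )
        one = _eff([1.0], [[1.0]])
        assert mfd_scores(np.array([[0.5]]), one)[0] == pytest.approx(0.5)

    def test_mfd_zero_d_rejected(self):
        eff = _eff([0.0, 0.0], np.eye(2))
        with pytest.raises(DataError, match="dimorphism"):
            mfd_scores(np.zeros((1, 2)), eff)

    def test_mft_two_trait_oracle(self, two_trait_profiles):
        model = fit_mf_model(two_trait_profiles)
        model.eff.d = np.array([0.5, -0.5])
        model.eff.R = np.array([[1, -0.5], [-0.5, 1]])
        model.a = np.linalg.solve(model.eff.R, model.eff.d)
        model.D_M = float(np.sqrt(model.eff.d @ model.a))
        got = mft_scores(np.array([[1.0, -1.0]]), model)
        assert got[0] == pytest.approx((2 / 3) / np.sqrt(1 / 3), abs=1e-12)

    def test_mft_unit_pooled_variance_on_training_sample(self, small_profiles):
        model = fit_mf_model(small_profiles)
        scores = score_profiles(model, small_profiles)
        assert pooled_variance(scores.mft, small_profiles.sex) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_mfp_logistic_anchors(self, small_profiles):
        model = fit_mf_model(small_profiles)
        p = small_profiles.p
        assert mfp_scores(np.zeros((1, p)), model)[0] == pytest.approx(0.5)
        # z'a = 1 -> e/(1+e)
        z = model.a[None, :] / (model.a @ model.a)
        assert mfp_scores(z, model)[0] == pytest.approx(
            np.e / (1 + np.e), abs=1e-12
        )
        # extreme scores saturate inside (0, 1)
        huge = 1e6 * model.a[None, :]
        val = mfp_scores(huge, model)[0]
        assert 0.0 < val < 1.0

    def test_mfc_centroid_anchors(self, small_profiles):
        model = fit_mf_model(small_profiles)
        m, f = model.eff.centroids()
        assert mfc_scores(m[None, :], model)[0] == pytest.approx(1.0, abs=1e-10)
        assert mfc_scores(f[None, :], model)[0] == pytest.approx(-1.0, abs=1e-10)
        assert mfc_scores(np.zeros((1, model.p)), model)[0] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_boundary_point_scores_zero_on_all_indices(self, small_profiles):
        model = fit_mf_model(small_profiles)
        z0 = np.zeros((1, model.p))
        assert mfd_scores(z0, model.eff)[0] == pytest.approx(0.0, abs=1e-12)
        assert mft_scores(z0, model)[0] == pytest.approx(0.0, abs=1e-12)
        assert mfc_scores(z0, model)[0] == pytest.approx(0.0, abs=1e-12)
        assert mfp_scores(z0, model)[0] == pytest.approx(0.5, abs=1e-12)


class TestCentroidDistance:
    def test_bias_correction_plug_in_formula(self):
        # p = 5, n_M = n_F = 50, D_M = 1 -> D_Mu = sqrt(92/98 - 0.2)
        eff = _eff(
            np.sqrt(np.full(5, 1 / 5)), np.eye(5), n_male=50, n_female=50
        )
        D_M, D_Mu = mahalanobis_centroid_distance(eff)
        assert D_M == pytest.approx(1.0, abs=1e-12)
        assert D_Mu == pytest.approx(np.sqrt(92 / 98 - 0.2), abs=1e-12)

    def test_large_sample_correction_vanishes(self):
        eff = _eff([0.4, 0.6], np.eye(2), n_male=10**6, n_female=10**6)
        D_M, D_Mu = mahalanobis_centroid_distance(eff)
        assert abs(D_M - D_Mu) < 1e-3

    def test_negative_corrected_square_floors_at_zero(self):
        eff = _eff([0.01, 0.01], np.eye(2), n_male=5, n_female=5)
        _, D_Mu = mahalanobis_centroid_distance(eff)
        assert D_Mu == 0.0


class TestConcordance:
    def test_single_discordant_profile(self):
        flags, frac = classify_concordance(np.array([-0.2]), np.array([0.3]))
        assert flags.tolist() == [True] and frac == 1.0

    def test_identity_correlation_gives_no_discordance(self, small_profiles):
        prof = force_identity_correlation(small_profiles)
        model = fit_mf_model(prof)
        scores = score_profiles(model, prof)
        assert scores.discordant.sum() == 0

    def test_fraction_matches_elementwise_sign_oracle(self):
        rng = np.random.default_rng(2)
        mfd = rng.normal(size=500)
        mft = 0.6 * mfd + 0.8 * rng.normal(size=500)
        flags, frac = classify_concordance(mfd, mft)
        oracle = np.array([(x < 0 < y) or (y < 0 < x) for x, y in zip(mfd, mft)])
        np.testing.assert_array_equal(flags, oracle)
        assert frac == pytest.approx(oracle.mean())

    def test_exact_zero_is_concordant(self):
        flags, _ = classify_concordance(np.array([0.0]), np.array([-1.0]))
        assert not flags[0]


class TestAxisAngle:
    def test_identity_correlation_angle_zero(self, small_profiles):
        prof = force_identity_correlation(small_profiles)
        model = fit_mf_model(prof)
        assert axis_angle(model.eff, model) == pytest.approx(0.0, abs=1e-4)

    def test_two_trait_arccos_oracle(self):
        eff = _eff([0.5, -0.5], [[1, -0.5], [-0.5, 1]])
        a = np.linalg.solve(eff.R, eff.d)
        model = fit_mf_model(make_profiles(p=2, n=100, seed=3))
        model.eff, model.a = eff, a
        expect = np.degrees(
            np.arccos(eff.d @ a / (np.linalg.norm(eff.d) * np.linalg.norm(a)))
        )
        assert axis_angle(eff, model) == pytest.approx(expect, abs=1e-12)

    def test_angle_grows_with_offdiagonal_correlation(self):
        # d must not be an eigenvector of R, else a stays parallel to d
        d = np.array([0.8, 0.2])
        angles = []
        for r in (0.0, 0.2, 0.4, 0.6, 0.8):
            R = np.array([[1, r], [r, 1]])
            eff = _eff(d, R)
            model = fit_mf_model(make_profiles(p=2, n=100, seed=3))
            model.eff, model.a = eff, np.linalg.solve(R, d)
            angles.append(axis_angle(eff, model))
        assert all(a < b for a, b in zip(angles, angles[1:]))


class TestLogisticMethod:
    def test_tracks_lda_closely_on_normal_data(self, small_profiles):
        lda = fit_mf_model(small_profiles, method="lda")
        logit = fit_mf_model(small_profiles, method="logistic")
        s_lda = score_profiles(lda, small_profiles)
        s_log = score_profiles(logit, small_profiles)
        assert np.corrcoef(s_lda.mft, s_log.mft)[0, 1] > 0.99
        assert np.corrcoef(s_lda.mfp, s_log.mfp)[0, 1] > 0.99

    def test_logistic_mft_has_unit_pooled_variance(self, small_profiles):
        model = fit_mf_model(small_profiles, method="logistic")
        scores = score_profiles(model, small_profiles)
        assert pooled_variance(scores.mft, small_profiles.sex) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_mfp_is_inverse_logit_of_linear_predictor(self, small_profiles):
        from mfindices import standardize
        from scipy.special import expit

        model = fit_mf_model(small_profiles, method="logistic")
        _, z = standardize(small_profiles)
        beta = model.logistic_coefficients
        eta = beta[0] + z @ beta[1:]
        scores = score_profiles(model, small_profiles)
        np.testing.assert_allclose(scores.mfp, expit(eta), atol=1e-12)


class TestSummaries:
    def test_identical_scores_correlate_perfectly(self, small_profiles):
        prof = force_identity_correlation(small_profiles)
        model = fit_mf_model(prof)
        scores = score_profiles(model, prof)
        summary = summarize_indices(scores, model)
        assert summary["r"].loc["mfd", "mft"] == pytest.approx(1.0, abs=1e-8)
        assert summary["r_p"].loc["mfd", "mft"] == pytest.approx(1.0, abs=1e-6)
        assert summary["percent_discordant"] == 0.0
        assert summary["D_M"] == model.D_M

    def test_partial_correlation_matches_residual_oracle(self):
        rng = np.random.default_rng(8)
        s = np.array([1.0, 0.0] * 100)
        x = 0.8 * s + rng.normal(size=200)
        y = -0.5 * s + 0.4 * x + rng.normal(size=200)
        got = _partial_corr_given_binary(x, y, s)
        # two-stage regression oracle: correlate the residuals on s
        rx = x - np.polyval(np.polyfit(s, x, 1), s)
        ry = y - np.polyval(np.polyfit(s, y, 1), s)
        assert got == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)

    def test_partialling_a_null_covariate_is_a_no_op(self):
        rng = np.random.default_rng(4)
        s = np.array([1.0, 0.0] * 200)
        x, y0 = rng.normal(size=400), rng.normal(size=400)
        y = 0.5 * x + y0
        r = np.corrcoef(x, y)[0, 1]
        r_p = _partial_corr_given_binary(x, y, s)
        assert r_p == pytest.approx(r, abs=0.02)

    def test_zero_variance_scores_rejected(self, small_profiles):
        model = fit_mf_model(small_profiles)
        scores = score_profiles(model, small_profiles)
        scores.mfc = np.zeros_like(scores.mfc)
        with pytest.raises(DataError, match="zero variance"):
            summarize_indices(scores)


class TestScoringNewData:
    def test_frozen_standardization_scores_held_out_profiles(self):
        train = make_profiles(p=4, n=500, seed=21)
        test = make_profiles(p=4, n=200, seed=22)
        model = fit_mf_model(train)
        scores = score_profiles(model, test)
        z = model.std.transform(test.values)
        np.testing.assert_allclose(scores.mfd, mfd_scores(z, model.eff))
        np.testing.assert_allclose(scores.mft, mft_scores(z, model))
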