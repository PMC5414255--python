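"""PCA, shape-ANOVA, MANOVA, CVA, cross-validated classification."""

import numpy as np
import pandas as pd
import pytest

from enamelgmm.stats import (
    crossvalidated_classification,
    cva,
    factorial_shape_anova,
    manova_pillai,
    pca,
    predict_unknown,
    shape_along_axis,
    shape_along_scores,
)


class TestPca:
    def test_reconstruction_completeness(self, rng):
        X = rng.normal(size=(12, 8))
        model = pca(X)
        recon = model.mean + model.scores @ model.vectors.T
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_planar_data_has_rank_two(self, rng):
        basis = rng.normal(size=(2, 10))
        X = rng.normal(size=(15, 2)) @ basis + rng.normal(size=10)
        model = pca(X)
        assert len(model.eigenvalues) == 2

    def test_eigenvalues_match_covariance_eigh_oracle(self, rng):
        X = rng.normal(size=(20, 6))
        model = pca(X)
        oracle = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(model.eigenvalues, oracle[: len(model.eigenvalues)],
                                   rtol=1e-8)

    def test_retention_threshold_rule(self, rng):
        X = rng.normal(size=(30, 10)) * np.array([10, 5, 2] + [0.1] * 7)
        model = pca(X, threshold=0.99)
        frac = np.cumsum(model.eigenvalues) / model.eigenvalues.sum()
        assert frac[model.retained_m - 1] >= 0.99
        assert model.retained_m == 1 or frac[model.retained_m - 2] < 0.99

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero total variance"):
            pca(np.ones((5, 3)))


class TestFactorialAnova:
    def test_identical_shapes_have_zero_ss(self):
        X = np.tile([1.0, 2.0, 3.0], (12, 1))
        fa = np.repeat(["a", "b"], 6)
        fb = np.tile(["u", "v"], 6)
        t = factorial_shape_anova(X, fa, fb, n_perm=99).table
        assert t.loc[["A", "B", "A:B"], "SS"].max() < 1e-12

    def test_sequential_ss_decomposition_any_order(self, rng):
        X = rng.normal(size=(24, 5))
        fa = np.repeat(["a", "b", "c"], 8)
        fb = np.tile(np.repeat(["u", "v"], 4), 3)
        for first, second in [(fa, fb), (fb, fa)]:
            t = factorial_shape_anova(X, first, second, n_perm=99).table
            terms = t.loc[["A", "B", "A:B", "Residuals"], "SS"].sum()
            assert terms == pytest.approx(t.loc["Total", "SS"], rel=1e-8)

    def test_two_level_factor_equals_goodall_f(self, rng):
        g = np.repeat(["u", "v"], 9)
        Y = rng.normal(size=(18, 6))
        Y[g == "v"] += 0.4
        grand = Y.mean(axis=0)
        ssb = sum(
            (g == l).sum() * np.sum((Y[g == l].mean(axis=0) - grand) ** 2)
            for l in ("u", "v")
        )
        ssw = sum(np.sum((Y[g == l] - Y[g == l].mean(axis=0)) ** 2) for l in ("u", "v"))
        goodall = (ssb / 1) / (ssw / 16)
        t = factorial_shape_anova(Y, g, None, n_perm=99).table
        assert t.loc["A", "F"] == pytest.approx(goodall, rel=1e-10)

    def test_detects_strong_effect(self, rng):
        fa = np.repeat(["a", "b"], 10)
        fb = np.tile(["u", "v"], 10)
        X = rng.normal(size=(20, 4))
        X[fa == "b"] += 3.0
        t = factorial_shape_anova(X, fa, fb, n_perm=199, seed=5).table
        assert t.loc["A", "p"] <= 0.01
        assert t.loc["A", "Z"] > 2

    def test_single_level_factor_raises(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="two levels"):
            factorial_shape_anova(X, ["a"] * 10, ["u", "v"] * 5, n_perm=99)


class TestManova:
    def test_null_case(self, rng):
        X = rng.normal(size=(40, 3))
        g = np.repeat(["a", "b"], 20)
        res = manova_pillai(X, g)
        assert res.pillai < 0.3
        assert res.p > 0.01

    def test_two_group_hotelling_relation(self, rng):
        m = 4
        X = rng.normal(size=(30, m))
        g = np.repeat(["a", "b"], 15)
        X[g == "b"] += 0.8
        n1 = n2 = 15
        d = X[g == "a"].mean(axis=0) - X[g == "b"].mean(axis=0)
        S = (
            (X[g == "a"] - X[g == "a"].mean(axis=0)).T @ (X[g == "a"] - X[g == "a"].mean(axis=0))
            + (X[g == "b"] - X[g == "b"].mean(axis=0)).T @ (X[g == "b"] - X[g == "b"].mean(axis=0))
        ) / (n1 + n2 - 2)
        t2 = (n1 * n2) / (n1 + n2) * d @ np.linalg.inv(S) @ d
        res = manova_pillai(X, g)
        assert res.pillai == pytest.approx(t2 / (t2 + n1 + n2 - 2), rel=1e-8)

    def test_matches_statsmodels_pillai(self, rng):
        sm = pytest.importorskip("statsmodels.multivariate.manova")
        X = rng.normal(size=(45, 4))
        g = np.repeat(["a", "b", "c"], 15)
        X[g == "b"] += 0.5
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(4)])
        df["g"] = g
        stat = (
            sm.MANOVA.from_formula("v0+v1+v2+v3 ~ g", data=df)
            .mv_test().results["g"]["stat"]
        )
        res = manova_pillai(X, g)
        assert res.pillai == pytest.approx(stat.loc["Pillai's trace", "Value"], rel=1e-6)
        assert res.approx_f == pytest.approx(stat.loc["Pillai's trace", "F Value"], rel=1e-6)

    @pytest.mark.parametrize("effect", [0.0, 2.0], ids=["null", "strong"])
    def test_agrees_with_permutation_anova(self, effect):
        # Pillai MANOVA and the permutation shape-ANOVA should reach the
        # same qualitative verdict on clear null / strong-effect data
        for rep in range(10):
            rng = np.random.default_rng(500 + rep)
            X = rng.normal(size=(36, 4))
            g = np.repeat(["a", "b", "c"], 12)
            X[g == "b"] += effect
            man = manova_pillai(X, g)
            t = factorial_shape_anova(X, g, None, n_perm=199, seed=rep).table
            if effect > 0:
                assert man.p <= 0.05 and t.loc["A", "p"] <= 0.05
            else:
                # under the null both should usually retain; require joint
                # agreement rather than per-test calibration here
                assert (man.p <= 0.05) == (t.loc["A", "p"] <= 0.05) or (
                    man.p > 0.01 and t.loc["A", "p"] > 0.01
                )

    def test_singular_covariance_instructs_lower_retention(self, rng):
        X = rng.normal(size=(10, 9))
        g = np.repeat(["a", "b"], 5)
        with pytest.raises(ValueError, match="fewer PCs"):
            manova_pillai(X, g)


class TestCva:
    def test_two_groups_give_one_axis(self, rng):
        X = rng.normal(size=(20, 5))
        g = np.repeat(["a", "b"], 10)
        X[g == "b"] += 2
        model = cva(X, g)
        assert model.axes.shape[1] == 1

    def test_unit_pooled_within_variance(self, rng):
        X = rng.normal(size=(45, 6))
        g = np.repeat(["a", "b", "c"], 15)
        X[g == "b"] += 1.5
        model = cva(X, g)
        Z = model.transform(X)
        wss = np.zeros(Z.shape[1])
        for l in np.unique(g):
            sub = Z[g == l] - Z[g == l].mean(axis=0)
            wss += (sub**2).sum(axis=0)
        np.testing.assert_allclose(wss / (45 - 3), 1.0, atol=1e-8)

    def test_leading_axis_matches_angle_scan_oracle(self, rng):
        # 2-group 2-variable toy: brute-force scan over axis angle for the
        # direction maximizing between/within variance ratio
        X = rng.normal(size=(40, 2)) @ np.array([[1.0, 0.4], [0.0, 0.6]])
        g = np.repeat(["a", "b"], 20)
        X[g == "b"] += [1.5, -0.8]

        def ratio(theta):
            w = np.array([np.cos(theta), np.sin(theta)])
            z = X @ w
            grand = z.mean()
            b = sum((z[g == l].mean() - grand) ** 2 * (g == l).sum() for l in "ab")
            wss = sum(((z[g == l] - z[g == l].mean()) ** 2).sum() for l in "ab")
            return b / wss

        angles = np.arange(0, np.pi, 1e-3)
        best = angles[int(np.argmax([ratio(t) for t in angles]))]
        model = cva(X, g)
        axis = model.axes[:, 0] / np.linalg.norm(model.axes[:, 0])
        ang = np.arctan2(axis[1], axis[0]) % np.pi
        assert min(abs(ang - best), np.pi - abs(ang - best)) < 2e-3

    def test_singleton_group_raises_by_default(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="'b'"):
            cva(X, ["a", "a", "a", "a", "b"])


class TestClassification:
    def test_separated_clusters_classify_perfectly(self, rng):
        means = rng.normal(scale=20, size=(3, 4))
        X = np.vstack([m + rng.normal(size=(8, 4)) for m in means])
        g = np.repeat(["a", "b", "c"], 8)
        rep = crossvalidated_classification(X, g, rounds=200, seed=0)
        assert rep.ccv == 100.0
        assert rep.ccv_modal == 100.0

    def test_assignment_rates_sum_to_one(self, rng):
        X = rng.normal(size=(24, 3))
        g = np.tile(["a", "b", "c"], 8)
        rep = crossvalidated_classification(X, g, rounds=51, seed=1)
        np.testing.assert_allclose(rep.assignment_rates.sum(axis=1), 1.0, atol=1e-9)

    def test_mahalanobis_affine_invariance(self, rng):
        X = rng.normal(size=(30, 4))
        g = np.repeat(["a", "b", "c"], 10)
        X[g == "b"] += 0.7
        T = rng.normal(size=(4, 4)) + 2 * np.eye(4)
        r1 = crossvalidated_classification(X, g, rounds=60, seed=3)
        r2 = crossvalidated_classification(X @ T + 5.0, g, rounds=60, seed=3)
        np.testing.assert_allclose(
            r1.assignment_rates, r2.assignment_rates, atol=1e-6
        )
        assert r1.ccv == pytest.approx(r2.ccv, abs=1e-6)

    def test_two_member_group_split_one_and_one(self, rng):
        # smallest feasible twofold split: 1 training, 1 testing
        X = np.vstack([rng.normal(size=(10, 2)), rng.normal(size=(2, 2)) + 10])
        g = np.array(["big"] * 10 + ["tiny"] * 2)
        rep = crossvalidated_classification(X, g, rounds=40, seed=2)
        assert rep.ccv_per_group["tiny"] == 100.0


class TestPredictUnknown:
    def _fit(self, rng):
        means = rng.normal(scale=10, size=(3, 4))
        X = np.vstack([m + rng.normal(size=(10, 4)) for m in means])
        g = np.repeat(["a", "b", "c"], 10)
        model_pca = pca(X, threshold=0.999)
        scores = model_pca.retained_scores
        return cva(scores, g), model_pca, scores, g

    def test_group_centroid_maps_to_its_group(self, rng):
        model, pca_model, scores, g = self._fit(rng)
        centroid = scores[g == "b"].mean(axis=0)
        (pred,) = predict_unknown(model, pca_model, centroid)
        assert pred.group == "b"
        assert pred.posteriors["b"] == max(pred.posteriors.values())

    def test_equidistant_point_has_uniform_posterior(self, rng):
        model, pca_model, scores, g = self._fit(rng)
        # solve for a point equidistant from all canonical centroids
        gm = model.group_means
        # point in canonical space: circumcenter of the 3 centroids
        A = 2 * (gm[1:] - gm[0])
        b = (gm[1:] ** 2).sum(axis=1) - (gm[0] ** 2).sum()
        z, *_ = np.linalg.lstsq(A, b, rcond=None)
        x = z @ np.linalg.pinv(model.axes) + model.grand_mean
        (pred,) = predict_unknown(model, pca_model, x)
        for v in pred.posteriors.values():
            assert v == pytest.approx(1 / 3, abs=1e-6)

    def test_posteriors_match_softmax_oracle(self, rng):
        model, pca_model, scores, g = self._fit(rng)
        x = scores[0] + 0.5
        (pred,) = predict_unknown(model, pca_model, x)
        d2 = np.array([pred.mahalanobis_sq[l] for l in model.groups])
        oracle = np.exp(-d2 / 2) / np.exp(-d2 / 2).sum()
        np.testing.assert_allclose(
            [pred.posteriors[l] for l in model.groups], oracle, atol=1e-12
        )


class TestShapeAlongAxis:
    def test_score_zero_returns_consensus(self, rng):
        X = rng.normal(size=(15, 8))
        model = pca(X)
        np.testing.assert_allclose(
            shape_along_axis(model, 0, 0.0).ravel(), model.mean, atol=1e-12
        )

    def test_linearity(self, rng):
        X = rng.normal(size=(15, 8))
        model = pca(X)
        s1 = shape_along_axis(model, 1, 0.3).ravel() - model.mean
        s2 = shape_along_axis(model, 1, 0.6).ravel() - model.mean
        np.testing.assert_allclose(s2, 2 * s1, atol=1e-12)

    def test_regression_matches_least_squares_oracle(self, rng):
        X = rng.normal(size=(20, 6))
        model = pca(X)
        s = model.scores[:, 0]
        # direct least-squares of each coordinate on the axis score
        design = np.column_stack([np.ones(20), s])
        beta, *_ = np.linalg.lstsq(design, X, rcond=None)
        predicted = beta[0] + 1.7 * beta[1]
        np.testing.assert_allclose(
            shape_along_scores(X, s, 1.7).ravel(), predicted, atol=1e-8
        )
        # for PCA the regression vector equals the eigenvector
        np.testing.assert_allclose(beta[1], model.vectors[:, 0], atol=1e-8)
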