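"""PCA, confidence-ellipse outliers, PLS-DA, VIP and cross-validation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from csfnmr.errors import (
    DegenerateScoresError,
    InvalidParameterError,
    StratificationError,
    ValidationError,
)
from csfnmr.multivariate import (
    confusion_summary,
    cross_validate,
    ellipse_outliers,
    pca,
    pca_outlier_pass,
    plsda_fit,
    vip,
)


class TestPCA:
    def test_rank_one_data_single_component(self):
        t = np.linspace(0, 1, 10)
        X = np.outer(t, [1.0, -2.0, 0.5])
        model = pca(X, 2)
        frac = model.explained_variance_fraction
        assert frac[0] == pytest.approx(1.0, abs=1e-12)
        assert frac[1:] == pytest.approx(np.zeros(frac.size - 1), abs=1e-12)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((15, 6))
        model = pca(X, 6)
        recon = model.scores @ model.loadings.T + model.mean
        assert recon == pytest.approx(X, abs=1e-9)

    def test_fractions_match_covariance_eigenvalues(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 10)) @ np.diag(np.arange(1, 11))
        model = pca(X, 5)
        cov = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert model.explained_variance_fraction == pytest.approx(
            eig / eig.sum(), abs=1e-9)
        assert (np.diff(model.explained_variance_fraction) <= 1e-12).all()
        assert model.explained_variance_fraction.sum() == pytest.approx(
            1.0, abs=1e-9)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(3)
        model = pca(rng.standard_normal((20, 7)), 5)
        gram = model.loadings.T @ model.loadings
        assert gram == pytest.approx(np.eye(5), abs=1e-10)

    def test_ncomp_guard(self):
        with pytest.raises(ValidationError):
            pca(np.random.default_rng(0).standard_normal((5, 3)), 5)


class TestEllipseOutliers:
    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0, 0.01, size=(20, 2))
        scores[7] = [50.0, -40.0]
        flags = ellipse_outliers(scores, alpha=0.05)
        assert flags[7] and flags.sum() == 1

    def test_alpha_domain_guard(self):
        z = np.random.default_rng(0).standard_normal((10, 2))
        for alpha in (0.0, 0.7, 1.0, -0.1):
            with pytest.raises(InvalidParameterError):
                ellipse_outliers(z, alpha=alpha)

    def test_singular_scores_rejected(self):
        line = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(DegenerateScoresError):
            ellipse_outliers(line)

    def test_calibration_on_bivariate_normal(self):
        fracs = []
        for seed in range(5):
            z = np.random.default_rng(seed).standard_normal((1000, 2))
            fracs.append(ellipse_outliers(z, alpha=0.05).mean())
        assert 0.035 <= np.mean(fracs) <= 0.065

    def test_outlier_pass_refits_once(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((30, 5)),
                         index=[f"s{i}" for i in range(30)])
        X.iloc[3] += 40.0
        model, outliers = pca_outlier_pass(X, ncomp=2, alpha=0.05)
        assert "s3" in outliers
        assert model.scores.shape[0] == 30 - len(outliers)


def _separable(n=20, p=5, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = ["pos"] * (n // 2) + ["neg"] * (n - n // 2)
    X[: n // 2, 0] += gap
    return X, y


class TestPLSDA:
    def test_perfect_single_predictor(self):
        y = ["a"] * 5 + ["b"] * 5
        X = np.array([1.0] * 5 + [-1.0] * 5)[:, None]
        model = plsda_fit(X, y, 1)
        assert model.classify(X) == y
        assert model.r2 == pytest.approx(1.0, abs=1e-12)

    def test_score_orthogonality_and_unit_weights(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((18, 7))
        y = ["a"] * 9 + ["b"] * 9
        model = plsda_fit(X, y, 4)
        T = model.x_scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        assert np.linalg.norm(model.weights, axis=0) == pytest.approx(
            np.ones(4), abs=1e-12)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((12, 5))
        y = ["a"] * 6 + ["b"] * 6
        model = plsda_fit(X, y, 5)
        y_num = model.y_numeric
        Xc = np.column_stack([np.ones(12), X])
        beta, *_ = np.linalg.lstsq(Xc, y_num, rcond=None)
        assert model.predict(X) == pytest.approx(Xc @ beta, abs=1e-6)

    def test_matches_sklearn_pls1_predictions(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((20, 8))
        y = ["a"] * 10 + ["b"] * 10
        model = plsda_fit(X, y, 3)
        sk = PLSRegression(n_components=3, scale=False).fit(
            X, model.y_numeric)
        assert model.predict(X) == pytest.approx(
            sk.predict(X).ravel(), abs=1e-8)

    def test_rank_exhaustion_raises(self):
        X = np.zeros((6, 3))
        X[:, 0] = [1, 1, 1, -1, -1, -1]
        y = ["a"] * 3 + ["b"] * 3
        from csfnmr.errors import RankExhaustedError
        with pytest.raises(RankExhaustedError):
            plsda_fit(X, y, 3)


class TestVIP:
    def test_uniform_weights_give_unit_vip(self):
        y = ["a"] * 4 + ["b"] * 4
        base = np.array([1.0] * 4 + [-1.0] * 4)
        X = np.outer(base, np.ones(5))
        model = plsda_fit(X, y, 1)
        v = vip(model)
        assert v.scores.to_numpy() == pytest.approx(np.ones(5), abs=1e-10)

    def test_sum_of_squares_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n, p = int(rng.integers(8, 20)), int(rng.integers(3, 12))
            X = rng.standard_normal((n, p))
            y = ["a"] * (n // 2) + ["b"] * (n - n // 2)
            model = plsda_fit(X, y, min(3, p), strict=False)
            v = vip(model)
            assert float((v.scores**2).sum()) == pytest.approx(p, abs=1e-8)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((4, 3))
        y = ["a", "a", "b", "b"]
        model = plsda_fit(X, y, 2)
        W, q, T = model.weights, model.y_loadings, model.x_scores
        p = 3
        ss = np.array([q[a]**2 * T[:, a] @ T[:, a] for a in range(2)])
        expect = np.sqrt(p * np.array([
            sum(ss[a] * (W[j, a] / np.linalg.norm(W[:, a]))**2
                for a in range(2)) for j in range(p)]) / ss.sum())
        assert vip(model).scores.to_numpy() == pytest.approx(expect, abs=1e-10)


class TestCrossValidate:
    def test_confusion_arithmetic(self):
        sens, spec, ba = confusion_summary(8, 3, 7, 2)
        assert (sens, spec, ba) == (0.8, 0.7, 0.75)

    def test_separable_data(self):
        X, y = _separable(n=30, gap=6.0)
        cv = cross_validate(X, y, max_ncomp=3, k=5, repeats=3, seed=0)
        assert cv.q2[cv.chosen_ncomp - 1] > 0.9
        assert cv.balanced_accuracy == 1.0
        assert cv.balanced_accuracy == pytest.approx(
            (cv.sensitivity + cv.specificity) / 2, abs=1e-12)

    def test_r2_monotone_and_dominates_q2(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((24, 10))
        X[:12, :3] += 1.0
        y = ["a"] * 12 + ["b"] * 12
        cv = cross_validate(X, y, max_ncomp=5, k=4, repeats=2, seed=1)
        assert (np.diff(cv.r2) >= -1e-10).all()
        assert (cv.r2 >= cv.q2 - 1e-10).all()

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((34, 20))
        labels = np.array(["a"] * 20 + ["b"] * 14)
        bas = []
        for rep in range(10):
            y = rng.permutation(labels)
            cv = cross_validate(X, list(y), max_ncomp=3, k=5, repeats=1,
                                seed=rep)
            bas.append(cv.balanced_accuracy)
        assert 0.4 <= np.mean(bas) <= 0.6

    def test_rare_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        y = ["a"] * 7 + ["b"] * 3
        with pytest.raises(StratificationError):
            cross_validate(X, y, max_ncomp=2, k=5)

    def test_positive_class_selection(self):
        X, y = _separable(n=20)
        cv = cross_validate(X, y, max_ncomp=2, k=5, repeats=1, seed=0,
                            positive_class="pos")
        assert cv.positive_class == "pos"
        default = cross_validate(X, y, max_ncomp=2, k=5, repeats=1, seed=0)
        assert default.positive_class == "neg"   # first alphabetically
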