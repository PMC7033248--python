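"""Discriminant training/prediction and mouse-level PCA quality control."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import adenoquant as aq


def _gaussian_data(rng, n, p, delta, cls=("Ad", "nAd")):
    """Two spherical Gaussian classes with mean gap ``delta`` along x1."""
    half = n // 2
    X = rng.standard_normal((n, p))
    X[:half, 0] += delta
    y = np.array([cls[0]] * half + [cls[1]] * (n - half))
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(p)]), pd.Series(y)


def _concentric_data(rng, n, r_outer=4.0):
    """Class Ad at radius ~N(0,1), class nAd at radius ~N(r_outer,1)."""
    half = n // 2
    radius = np.concatenate([rng.normal(0, 1, half), rng.normal(r_outer, 1, n - half)])
    theta = rng.uniform(0, 2 * np.pi, n)
    X = pd.DataFrame({"x0": radius * np.cos(theta), "x1": radius * np.sin(theta)})
    y = pd.Series(["Ad"] * half + ["nAd"] * (n - half))
    return X, y


class TestTrainPredict:
    def test_no_signal_near_chance(self):
        rng = np.random.default_rng(0)
        Xtr, ytr = _gaussian_data(rng, 2000, 4, 0.0)
        Xte, yte = _gaussian_data(rng, 2000, 4, 0.0)
        model = aq.train_lda(Xtr, ytr)
        calls, _ = aq.predict(model, Xte)
        acc = (calls.to_numpy() == yte.to_numpy()).mean()
        assert abs(acc - 0.5) < 0.05

    def test_well_separated_matches_bayes_rule(self):
        rng = np.random.default_rng(1)
        Xtr, ytr = _gaussian_data(rng, 2000, 4, 5.0)
        Xte, yte = _gaussian_data(rng, 2000, 4, 5.0)
        model = aq.train_lda(Xtr, ytr)
        calls, _ = aq.predict(model, Xte)
        assert (calls.to_numpy() == yte.to_numpy()).mean() >= 0.99
        # discriminant direction close to the analytic one (e1)
        w = np.linalg.solve(model.pooled_cov, model.means[0] - model.means[1])
        w /= np.linalg.norm(w)
        assert abs(w[0]) > 0.99

    def test_quadratic_augmentation_separates_concentric_classes(self):
        rng = np.random.default_rng(2)
        X, y = _concentric_data(rng, 2000)
        plain = aq.train_lda(X, y)
        calls_plain, _ = aq.predict(plain, X)
        acc_plain = (calls_plain.to_numpy() == y.to_numpy()).mean()
        assert acc_plain <= 0.60

        Xa = aq.augment_squares(X)
        aug = aq.train_lda(Xa, y)
        calls_aug, _ = aq.predict(aug, Xa)
        acc_aug = (calls_aug.to_numpy() == y.to_numpy()).mean()
        assert acc_aug >= 0.90

    def test_boundary_is_a_conic_with_squares(self):
        """In the 2-D toy space the augmented decision boundary is one quadratic form."""
        rng = np.random.default_rng(3)
        X, y = _concentric_data(rng, 1500)
        Xa = aq.augment_squares(X)
        model = aq.train_lda(Xa, y)
        # discriminant: g(z) = w.z + b in augmented coords z=(x0,x1,x0²,x1²)
        Sinv = np.linalg.inv(model.pooled_cov)
        w = Sinv @ (model.means[0] - model.means[1])
        b = (np.log(model.priors[0] / model.priors[1])
             - 0.5 * (model.means[0] @ Sinv @ model.means[0]
                      - model.means[1] @ Sinv @ model.means[1]))
        g1, g2 = np.meshgrid(np.linspace(-7, 7, 60), np.linspace(-7, 7, 60))
        grid = pd.DataFrame({"x0": g1.ravel(), "x1": g2.ravel()})
        grid_a = aq.augment_squares(grid)
        calls, _ = aq.predict(model, grid_a)
        g = grid_a.to_numpy() @ w + b
        assert ((g > 0) == (calls.to_numpy() == "Ad")).all()

    def test_posteriors_normalized_and_peak_at_class_mean(self):
        rng = np.random.default_rng(4)
        X, y = _gaussian_data(rng, 600, 3, 6.0)
        model = aq.train_lda(X, y)
        calls, post = aq.predict(model, X)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)
        at_mean = pd.DataFrame([model.means[0]], columns=model.columns)
        c, p = aq.predict(model, at_mean)
        assert c.iloc[0] == "Ad"
        assert p["Ad"].iloc[0] > 0.99

    def test_agrees_with_sklearn_reference(self):
        """Independent cross-check of the discriminant formula."""
        rng = np.random.default_rng(5)
        X, y = _gaussian_data(rng, 400, 6, 2.0)
        model = aq.train_lda(X, y)
        calls, post = aq.predict(model, X.iloc[:100])
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        sk_calls = sk.predict(X.iloc[:100])
        sk_post = sk.predict_proba(X.iloc[:100])[:, list(sk.classes_).index("Ad")]
        assert (calls.to_numpy() == sk_calls).all()
        # sklearn normalizes the pooled covariance by N rather than N-2,
        # so posteriors agree only approximately
        assert np.allclose(post["Ad"].to_numpy(), sk_post, atol=0.02)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        X, y = _gaussian_data(rng, 300, 4, 1.0)
        m1 = aq.train_lda(X, y)
        perm = rng.permutation(len(X))
        m2 = aq.train_lda(X.iloc[perm], y.iloc[perm])
        assert np.allclose(m1.means, m2.means, atol=1e-10)
        assert np.allclose(m1.pooled_cov, m2.pooled_cov, atol=1e-10)
        assert np.allclose(m1.priors, m2.priors, atol=1e-12)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            aq.train_lda(X, pd.Series(["Ad", "Ad", "Ad"]))

    def test_column_mismatch_names_columns(self):
        rng = np.random.default_rng(7)
        X, y = _gaussian_data(rng, 100, 3, 2.0)
        model = aq.train_lda(X, y)
        bad = X.rename(columns={"x2": "zz"})
        with pytest.raises(ValueError, match="x2"):
            aq.predict(model, bad)

    def test_priors_are_empirical(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((100, 2)), columns=["a", "b"])
        y = pd.Series(["Ad"] * 30 + ["nAd"] * 70)
        model = aq.train_lda(X, y)
        assert model.priors == pytest.approx([0.3, 0.7])


def _qc_table(seed, n_mice=50, bias_mice=(), mouse_effect=0.0):
    spec = aq.SynthTableSpec(
        seed=seed, n_mice=n_mice, mouse_effect_sd=mouse_effect,
        bias_mice=bias_mice, bias_sd=3.0, bias_n_measures=6,
    )
    table = aq.generate_table(spec)
    X, _, mice = aq.build_design_matrix(table, aq.default_spec(table))
    return X, mice


class TestPcaQc:
    def test_null_flag_rate(self):
        X, mice = _qc_table(seed=10, n_mice=100, mouse_effect=0.0)
        report = aq.pca_qc(X, mice)
        assert len(report.flagged) <= 2  # <= 2% of 100 mice

    def test_recovers_exactly_the_biased_mice(self):
        biased = ("m003", "m017", "m042")
        X, mice = _qc_table(seed=11, n_mice=50, bias_mice=biased)
        report = aq.pca_qc(X, mice)
        assert tuple(report.flagged) == biased

    def test_rerun_after_excluding_biased_mice_is_clean(self):
        """Once the batch-biased mice are excluded, no residual bias is flagged."""
        X, mice = _qc_table(seed=11, n_mice=50, bias_mice=("m003", "m017", "m042"))
        report = aq.pca_qc(X, mice)
        keep = ~mice.isin(report.flagged)
        report2 = aq.pca_qc(X[keep.to_numpy()], mice[keep.to_numpy()])
        assert report2.flagged == []

    def test_single_feature_mouse_barycentre(self):
        X, mice = _qc_table(seed=13, n_mice=10)
        mice = mice.copy()
        lone = "lone"
        mice.iloc[0] = lone
        report = aq.pca_qc(X, mice)
        # barycentre of a one-feature mouse is that feature's PC1-2 score:
        # recompute scores independently
        Xv = X.to_numpy(float)
        Xv = (Xv - Xv.mean(0))
        sd = Xv.std(0)
        sd[sd == 0] = 1
        Xv /= sd
        _, _, vt = np.linalg.svd(Xv, full_matrices=False)
        score = Xv[0] @ vt[:2].T
        got = report.barycentres.loc[lone, ["PC1", "PC2"]].to_numpy(float)
        assert np.allclose(np.abs(got), np.abs(score), atol=1e-8)

    def test_needs_three_mice(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 3)))
        with pytest.raises(ValueError):
            aq.pca_qc(X, pd.Series(["a"] * 5 + ["b"] * 5))
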