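"""Global stage: PCA reduction, grid-searched SVM, scan-level rule."""

import numpy as np
import pytest

from ctforensics.classifier import (GlobalModel, GlobalModelConfig, ScanRule,
                                    classify_scan, classify_slice, fit_global)
from ctforensics.heatmap import detect_slice
from ctforensics.imageio import NormalizedSlice
from ctforensics.windows import GridConfig


def separable_clusters(n=600, d=50, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = (np.arange(n) % 2).astype(int)
    X[y == 1] += 8.0
    return X, y


class TestFitGlobal:
    def test_separable_clusters_reach_perfect_cv(self):
        X, y = separable_clusters()
        model = fit_global(X, y, GlobalModelConfig(reduced_dim=10, seed=0))
        assert model.cv_score == 1.0
        preds = (model.score_features(X) > 0.5).astype(int)
        assert np.array_equal(preds, y)

    def test_reduction_dimension_is_256_when_supported(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(400, 1000))
        y = (X[:, 0] > 0).astype(int)
        model = fit_global(X, y, GlobalModelConfig(seed=0))
        assert model.pca.n_components_ == 256
        assert model.pca.transform(X[:3]).shape == (3, 256)

    def test_reduced_dim_lowered_when_samples_are_scarce(self):
        X, y = separable_clusters(n=40, d=100)
        model = fit_global(X, y, GlobalModelConfig(reduced_dim=256, seed=0))
        assert model.pca.n_components_ <= 40

    def test_single_class_rejected(self):
        X = np.zeros((10, 5))
        with pytest.raises(ValueError):
            fit_global(X, np.ones(10), GlobalModelConfig())

    def test_empty_grid_rejected(self):
        X, y = separable_clusters(n=40, d=10)
        with pytest.raises(ValueError):
            fit_global(X, y, GlobalModelConfig(param_grid=[]))

    def test_singleton_grid_equals_direct_fit(self):
        from sklearn.decomposition import PCA
        from sklearn.svm import SVC

        X, y = separable_clusters(n=80, d=20, seed=3)
        grid = [{"kernel": ["linear"], "C": [1.0]}]
        model = fit_global(X, y, GlobalModelConfig(reduced_dim=5, param_grid=grid, seed=0))
        pca = PCA(n_components=5, random_state=0).fit(X)
        direct = SVC(kernel="linear", C=1.0, probability=True, random_state=0)
        direct.fit(pca.transform(X), y)
        np.testing.assert_allclose(model.clf.decision_function(model.pca.transform(X)),
                                   direct.decision_function(pca.transform(X)), atol=1e-8)

    def test_reduction_is_variance_optimal(self):
        """Top-k components match the eigendecomposition of the covariance and
        beat random orthogonal projections."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 12)) @ rng.normal(size=(12, 12))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        k = 4
        model = fit_global(X, y, GlobalModelConfig(reduced_dim=k, seed=0))
        C = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1][:k]
        np.testing.assert_allclose(model.pca.explained_variance_, eig, rtol=1e-8)
        pca_var = model.pca.transform(X).var(axis=0, ddof=1).sum()
        for _ in range(20):
            Q, _ = np.linalg.qr(rng.normal(size=(X.shape[1], k)))
            rand_var = ((X - X.mean(0)) @ Q).var(axis=0, ddof=1).sum()
            assert pca_var >= rand_var - 1e-9


class MeanDetector:
    def predict(self, patches):
        return np.clip(np.asarray(patches).mean(axis=(1, 2)), 0, 1)


@pytest.fixture(scope="module")
def tiny_cascade():
    """A stub detector + global model fitted on detect_slice heatmaps."""
    from ctforensics.glcm import feature_table

    cfg = GridConfig(64, 32, 8)
    det = MeanDetector()
    rng = np.random.default_rng(0)
    hs, labels = [], []
    for i in range(30):
        hot = i % 2
        pixels = np.clip(rng.uniform(0, 0.2, size=(64, 64)) + 0.6 * hot, 0, 1)
        slc = NormalizedSlice(pixels=pixels, lo=0, hi=1)
        hs.append(detect_slice(det, slc, cfg))
        labels.append(hot)
    X, y = feature_table(hs, labels)
    gmodel = fit_global(X, y, GlobalModelConfig(reduced_dim=5, seed=0))
    return gmodel, det, cfg


class TestClassifySlice:
    def test_same_slice_classified_identically(self, tiny_cascade):
        gmodel, det, cfg = tiny_cascade
        rng = np.random.default_rng(1)
        slc = NormalizedSlice(pixels=rng.uniform(0, 1, size=(64, 64)), lo=0, hi=1)
        assert classify_slice(gmodel, det, slc, cfg) == classify_slice(gmodel, det, slc, cfg)

    def test_held_out_hot_and_cold_slices_separate(self, tiny_cascade):
        gmodel, det, cfg = tiny_cascade
        rng = np.random.default_rng(99)
        cold_px = np.clip(rng.uniform(0, 0.2, size=(64, 64)), 0, 1)
        hot_px = np.clip(rng.uniform(0, 0.2, size=(64, 64)) + 0.6, 0, 1)
        hot = NormalizedSlice(pixels=hot_px, lo=0, hi=1)
        cold = NormalizedSlice(pixels=cold_px, lo=0, hi=1)
        assert classify_slice(gmodel, det, hot, cfg)[0] == 1
        assert classify_slice(gmodel, det, cold, cfg)[0] == 0

    def test_unfitted_model_raises(self):
        from sklearn.decomposition import PCA
        from sklearn.svm import SVC

        broken = GlobalModel(pca=PCA(2), clf=SVC(probability=True),
                             cfg=GlobalModelConfig(), best_params={}, cv_score=0.0)
        slc = NormalizedSlice(pixels=np.zeros((64, 64)), lo=0, hi=1)
        with pytest.raises(Exception):
            classify_slice(broken, MeanDetector(), slc, GridConfig(64, 32, 8))

    def test_model_roundtrip(self, tiny_cascade, tmp_path):
        gmodel, _, _ = tiny_cascade
        gmodel.save(tmp_path / "g.joblib")
        loaded = GlobalModel.load(tmp_path / "g.joblib")
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 50, size=(3, 40000))
        np.testing.assert_allclose(loaded.score_features(X), gmodel.score_features(X))


class TestScanRule:
    def test_nine_of_ten_positive_is_tampered(self):
        labels = [1] * 9 + [0]
        verdict, runs = classify_scan(labels, ScanRule())
        assert verdict and runs == [0]

    def test_eight_of_ten_is_clean(self):
        assert not classify_scan([1] * 8 + [0, 0], ScanRule())[0]

    def test_all_negative_is_clean(self):
        assert not classify_scan([0] * 25, ScanRule())[0]

    def test_short_sequence_evaluated_whole(self):
        assert classify_scan([1] * 5, ScanRule(m=10, n=5))[0]
        assert not classify_scan([1] * 5, ScanRule(m=10, n=9))[0]

    def test_monotone_in_slice_positivity(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            labels = rng.integers(0, 2, 30)
            before = classify_scan(labels, ScanRule())[0]
            zeros = np.nonzero(labels == 0)[0]
            if len(zeros) == 0:
                continue
            flipped = labels.copy()
            flipped[rng.choice(zeros)] = 1
            after = classify_scan(flipped, ScanRule())[0]
            assert after >= before

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            ScanRule(m=5, n=6)
        with pytest.raises(ValueError):
            classify_scan([], ScanRule())
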