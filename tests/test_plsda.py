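import numpy as np
import pytest

from fluocube import (
    PreprocessSpec,
    SimConfig,
    fit_pls,
    flat_field,
    generate_scene,
    predict_map,
    select_components,
    split_calibration,
    top_wavelengths,
    train_pairwise,
)
from fluocube.calibration import SpectraMatrix, concat_spectra, extract_roi_spectra
from fluocube.errors import DegenerateResponseError, ModelCompatibilityError, RankError, SplitError


def labeled(X, labels):
    X = np.asarray(X, dtype=float)
    return SpectraMatrix(X, np.asarray(labels, dtype=object), np.arange(X.shape[1], dtype=float))


def two_group_spectra(cfg, seed, n=150):
    parts = []
    for i, g in enumerate(cfg.groups):
        sc = generate_scene(g, cfg, seed=seed * 10 + i)
        cal = flat_field(sc.raw, sc.white, sc.dark)
        parts.append(extract_roi_spectra(cal, sc.mask_truth, n, seed, g))
    return concat_spectra(parts)


class TestFitPLS:
    def test_single_latent_factor_recovered_exactly(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=8)
        t = rng.normal(size=40)
        X = np.outer(t, w)
        y = X @ w
        m = fit_pls(X, y, k=1)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_equals_ols(self, seed):
        rng = np.random.default_rng(seed)
        n, b = 40, 6
        X = rng.normal(size=(n, b))
        y = (rng.normal(size=n) > 0).astype(float)
        m = fit_pls(X, y, k=b)
        Xc = X - X.mean(axis=0)
        beta_ols, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        ols_pred = Xc @ beta_ols + y.mean()
        np.testing.assert_allclose(m.predict(X), ols_pred, atol=1e-8)

    def test_informative_column_has_max_beta(self):
        rng = np.random.default_rng(1)
        n, b, j = 400, 10, 3
        X = rng.normal(size=(n, b)) * 0.5
        y = (rng.random(n) > 0.5).astype(float)
        X[:, j] += 3.0 * y
        m = fit_pls(X, y, k=2)
        assert int(np.argmax(np.abs(m.beta))) == j

    def test_beta_path_equals_scores_path(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 12))
        y = (rng.random(30) > 0.5).astype(float)
        for k in (1, 3, 6):
            m = fit_pls(X, y, k)
            np.testing.assert_allclose(m.predict(X), m.predict_scores_path(X), atol=1e-10)

    def test_centering_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 8))
        y = (rng.random(25) > 0.5).astype(float)
        shift = rng.normal(size=8) * 10
        m0 = fit_pls(X, y, 3)
        m1 = fit_pls(X + shift, y, 3)
        np.testing.assert_allclose(m0.predict(X), m1.predict(X + shift), atol=1e-10)

    def test_label_flip_antisymmetry(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 8))
        y = (rng.random(25) > 0.5).astype(float)
        m0 = fit_pls(X, y, 3)
        m1 = fit_pls(X, 1.0 - y, 3)
        np.testing.assert_allclose(m0.predict(X), 1.0 - m1.predict(X), atol=1e-10)

    def test_matches_sklearn_nipals(self):
        """Independent cross-check against scikit-learn's PLS regression."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 10))
        y = (rng.random(50) > 0.5).astype(float)
        for k in (1, 2, 4):
            ours = fit_pls(X, y, k)
            ref = sklearn_pls.PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(ours.predict(X), ref.predict(X).ravel(), atol=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateResponseError):
            fit_pls(np.eye(4), np.ones(4), 1)

    def test_excessive_k_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 3))
        y = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
        with pytest.raises(RankError):
            fit_pls(X, y, k=5)


class TestSelectComponents:
    def test_perfectly_separable_one_factor_selects_one(self):
        rng = np.random.default_rng(7)
        w = rng.normal(size=6)
        y = np.repeat([0.0, 1.0], 30)
        X = np.outer(y * 2 - 1, w) + rng.normal(0, 0.01, size=(60, 6))
        assert select_components(X, y, k_max=5, seed=0) == 1

    def test_k_max_one_returns_one(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 5))
        y = (rng.random(20) > 0.5).astype(float)
        assert select_components(X, y, k_max=1, seed=0) == 1

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 8))
        y = (rng.random(40) > 0.5).astype(float)
        assert select_components(X, y, seed=3) == select_components(X, y, seed=3)


class TestTopWavelengths:
    def test_one_hot_beta(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 5))
        y = (rng.random(20) > 0.5).astype(float)
        m = fit_pls(X, y, 1)
        m.wavelengths = np.array([600.0, 610.0, 620.0, 630.0, 640.0])
        m.beta = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        assert top_wavelengths(m, 1) == [(620.0, 1.0)]

    def test_m_equals_b_returns_all_sorted(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 5))
        y = (rng.random(20) > 0.5).astype(float)
        m = fit_pls(X, y, 2)
        m.wavelengths = np.array([600.0, 610.0, 620.0, 630.0, 640.0])
        wls = [w for w, _ in top_wavelengths(m, 5)]
        assert wls == sorted(wls) and len(wls) == 5


class TestSplitCalibration:
    def test_canonical_75_25_split(self):
        rng = np.random.default_rng(12)
        X = labeled(rng.random((800, 4)), ["a"] * 400 + ["b"] * 400)
        cal, pred = split_calibration(X, fraction=0.75, seed=0)
        for g in ("a", "b"):
            assert int((cal.labels == g).sum()) == 300
            assert int((pred.labels == g).sum()) == 100

    def test_two_row_classes_split_one_one(self):
        X = labeled(np.arange(8.0).reshape(4, 2), ["a", "a", "b", "b"])
        cal, pred = split_calibration(X, fraction=0.5, seed=0)
        for g in ("a", "b"):
            assert int((cal.labels == g).sum()) == 1
            assert int((pred.labels == g).sum()) == 1

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(13)
        X = labeled(rng.random((40, 3)), ["a"] * 20 + ["b"] * 20)
        a1, p1 = split_calibration(X, seed=5)
        a2, p2 = split_calibration(X, seed=5)
        np.testing.assert_array_equal(a1.X, a2.X)
        np.testing.assert_array_equal(p1.X, p2.X)

    def test_singleton_class_rejected(self):
        X = labeled(np.ones((3, 2)), ["a", "a", "b"])
        with pytest.raises(SplitError):
            split_calibration(X)


class TestTrainPairwise:
    def test_five_groups_give_ten_pairs(self, small_cfg):
        parts = []
        for i, g in enumerate(small_cfg.groups):
            sc = generate_scene(g, small_cfg, seed=100 + i)
            cal = flat_field(sc.raw, sc.white, sc.dark)
            parts.append(extract_roi_spectra(cal, sc.mask_truth, 60, i, g))
        sm = concat_spectra(parts)
        res = train_pairwise(sm, PreprocessSpec(), k_max=3, seed=0)
        assert len(res.pairs) == 10
        tab = res.prediction_table
        assert np.isfinite(tab.to_numpy(dtype=float)[np.tril_indices(5, k=-1)]).all()
        assert np.isnan(tab.to_numpy(dtype=float)[np.triu_indices(5)]).all()

    def test_accuracies_are_percentages(self, small_cfg):
        cfg = SimConfig(groups={"a": 1.0, "b": 0.5}, image_height=48, image_width=48)
        sm = two_group_spectra(cfg, seed=2, n=80)
        res = train_pairwise(sm, PreprocessSpec(method="snv"), k_max=3, seed=1)
        pr = res.pairs[0]
        assert 0.0 <= pr.calibration_accuracy <= 100.0
        assert 0.0 <= pr.prediction_accuracy <= 100.0


class TestPredictMap:
    @pytest.fixture
    def fitted(self):
        cfg = SimConfig(groups={"MHL-2": (0.55, 0.45), "Cg": (1.0, 1.0)}, image_height=48, image_width=48)
        sm = two_group_spectra(cfg, seed=3, n=150)
        res = train_pairwise(sm, PreprocessSpec(method="snv"), k_max=3, seed=2)
        model = res.pairs[0].model  # pair (MHL-2, Cg): Cg coded 1
        assert model.class_pair == ("MHL-2", "Cg")
        return cfg, model

    def test_map_equals_batch_prediction(self, fitted):
        cfg, model = fitted
        sc = generate_scene("Cg", cfg, seed=77)
        cal = flat_field(sc.raw, sc.white, sc.dark)
        score = predict_map(model, cal, sc.mask_truth)
        rows, cols = np.nonzero(sc.mask_truth.values)
        X = SpectraMatrix(cal.data[rows, cols, :], np.full(len(rows), "?", dtype=object), cal.wavelengths)
        batch = model.predict(model.preprocessor.transform(X).X)
        np.testing.assert_allclose(score[rows, cols], batch, atol=1e-10)

    def test_control_scene_scores_above_half(self, fitted):
        cfg, model = fitted
        sc = generate_scene("Cg", cfg, seed=78)
        cal = flat_field(sc.raw, sc.white, sc.dark)
        score = predict_map(model, cal, sc.mask_truth)
        assert np.nanmean(score) > 0.5

    def test_off_mask_is_nan(self, fitted):
        cfg, model = fitted
        sc = generate_scene("Cg", cfg, seed=79)
        cal = flat_field(sc.raw, sc.white, sc.dark)
        score = predict_map(model, cal, sc.mask_truth)
        assert np.isnan(score[~sc.mask_truth.values]).all()

    def test_wavelength_mismatch_rejected(self, fitted):
        cfg, model = fitted
        other = SimConfig(n_bands=10, image_height=16, image_width=16, groups={"Cg": 1.0})
        sc = generate_scene("Cg", other, seed=1)
        cal = flat_field(sc.raw, sc.white, sc.dark)
        with pytest.raises(ModelCompatibilityError):
            predict_map(model, cal, sc.mask_truth)
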