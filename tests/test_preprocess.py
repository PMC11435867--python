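import itertools

import numpy as np
import pytest
from sklearn.decomposition import PCA as SkPCA

from cottonhsi import (
    HsiCube,
    LabelMap,
    PreprocessConfig,
    SpectralPCA,
    absorbance,
    band_discrimination,
    black_white_correct,
    crop,
    msc,
    pca_apply,
    pca_fit,
    preprocess_chain,
    standardize,
)
from conftest import rand_cube


def const_cube(value, shape=(3, 3, 4)):
    return HsiCube(np.full(shape, float(value)), np.linspace(400, 1000, shape[2]))


# ---------------------------------------------------------------- correction


class TestBlackWhiteCorrect:
    def test_raw_equals_dark_gives_zeros(self):
        out = black_white_correct(const_cube(50), const_cube(50), const_cube(250))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_raw_equals_white_gives_ones(self):
        out = black_white_correct(const_cube(250), const_cube(50), const_cube(250))
        np.testing.assert_array_equal(out.data, 1.0)

    def test_scalar_arithmetic(self):
        out = black_white_correct(const_cube(150), const_cube(50), const_cube(250))
        np.testing.assert_allclose(out.data, 0.5)

    def test_gain_invariance(self):
        """Scaling raw, dark and white by one positive gain leaves R unchanged."""
        rng = np.random.default_rng(0)
        raw, dark = rand_cube(rng, 4, 4, 5), rand_cube(rng, 4, 4, 5)
        white = HsiCube(dark.data + 1 + rng.random((4, 4, 5)), raw.wavelengths)
        r1 = black_white_correct(raw, dark, white)
        g = 3.7
        r2 = black_white_correct(
            raw.with_data(g * raw.data), dark.with_data(g * dark.data), white.with_data(g * white.data)
        )
        np.testing.assert_allclose(r1.data, r2.data, atol=1e-10)

    def test_degenerate_denominator_zeroed(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="cottonhsi.preprocess"):
            out = black_white_correct(const_cube(1), const_cube(0.5), const_cube(0.5))
        np.testing.assert_array_equal(out.data, 0.0)
        assert any("white - dark" in r.message for r in caplog.records)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            black_white_correct(const_cube(1), const_cube(0, shape=(2, 2, 4)), const_cube(1))


# ---------------------------------------------------------------- crop


class TestCrop:
    def test_full_range_identity(self, small_scene):
        raw, *_ , truth, spec = small_scene
        out, lab = crop(raw, truth, (0, raw.rows), (0, raw.cols))
        np.testing.assert_array_equal(out.data, raw.data)
        np.testing.assert_array_equal(lab.labels, truth.labels)

    def test_acquisition_scale_crop(self):
        """A full-frame acquisition cropped to the published region size."""
        cube = HsiCube(np.zeros((1800, 1538, 2), dtype=np.float32), np.array([400.0, 1000.0]))
        out, _ = crop(cube, None, (0, 971), (0, 841))
        assert out.data.shape == (971, 841, 2)  # all bands kept

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            crop(const_cube(1), None, (0, 5), (0, 3))

    def test_inverted_range(self):
        with pytest.raises(ValueError):
            crop(const_cube(1), None, (2, 1), (0, 3))


# ---------------------------------------------------------------- band discrimination


class TestBandDiscrimination:
    def test_two_constant_classes(self):
        data = np.zeros((2, 2, 3))
        data[0, :, :] = 0.2
        data[1, :, :] = 0.8
        cube = HsiCube(data, np.array([400.0, 500.0, 600.0]))
        labels = LabelMap(np.array([[1, 1], [2, 2]]))
        scores, best = band_discrimination(cube, labels)
        np.testing.assert_allclose(scores, 0.6)
        assert best == 0  # first maximal band

    def test_identical_band_scores_zero(self):
        data = np.zeros((2, 2, 2))
        data[..., 1] = [[0.1, 0.1], [0.9, 0.9]]  # band 0 identical across classes
        cube = HsiCube(data, np.array([400.0, 500.0]))
        scores, best = band_discrimination(cube, LabelMap(np.array([[1, 1], [2, 2]])))
        assert scores[0] == 0.0
        assert best == 1

    def test_matches_exhaustive_oracle(self, small_scene):
        raw, dark, white, truth, _ = small_scene
        cube = black_white_correct(raw, dark, white)
        scores, best = band_discrimination(cube, truth)
        X = cube.pixels()
        flat = truth.labels.ravel()
        classes = sorted(np.unique(flat))
        oracle = np.empty(cube.bands)
        for b in range(cube.bands):
            worst = np.inf
            for ci, cj in itertools.combinations(classes, 2):
                diff = abs(X[flat == ci, b].mean() - X[flat == cj, b].mean())
                worst = min(worst, diff)
            oracle[b] = worst
        np.testing.assert_allclose(scores, oracle, atol=1e-12)
        assert best == int(np.argmax(oracle))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            band_discrimination(const_cube(1), LabelMap(np.ones((3, 3), dtype=int)))


# ---------------------------------------------------------------- standardize


class TestStandardize:
    def test_three_values(self):
        cube = HsiCube(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1), np.array([500.0]))
        out, mu, sd = standardize(cube)
        np.testing.assert_allclose(out.data.ravel(), [-1.22474487, 0.0, 1.22474487])
        assert mu[0] == 2.0

    def test_post_moments_and_idempotence(self):
        rng = np.random.default_rng(1)
        cube = rand_cube(rng, 10, 10, 6)
        out, *_ = standardize(cube)
        X = out.pixels()
        assert np.abs(X.mean(axis=0)).max() < 1e-6
        assert np.abs(X.std(axis=0) - 1).max() < 1e-6
        again, *_ = standardize(out)
        np.testing.assert_allclose(again.data, out.data, atol=1e-9)

    def test_constant_band_zeroed(self, caplog):
        import logging

        data = np.random.default_rng(2).normal(size=(4, 4, 2))
        data[..., 1] = 7.0
        cube = HsiCube(data, np.array([400.0, 500.0]))
        with caplog.at_level(logging.WARNING, logger="cottonhsi.preprocess"):
            out, *_ = standardize(cube)
        np.testing.assert_array_equal(out.data[..., 1], 0.0)
        assert any("constant band" in r.message for r in caplog.records)

    def test_global_scope_scalar_moments(self):
        rng = np.random.default_rng(3)
        cube = rand_cube(rng, 8, 8, 5)
        out, mu, sd = standardize(cube, scope="global")
        assert np.ndim(mu) == 0 and np.ndim(sd) == 0
        assert abs(out.data.mean()) < 1e-9
        assert abs(out.data.std() - 1) < 1e-9
        # global scaling keeps the mean spectrum non-degenerate (unlike per-band)
        assert out.pixels().mean(axis=0).std() > 0


# ---------------------------------------------------------------- msc


class TestMsc:
    def test_reference_input_unchanged(self):
        ref = np.linspace(0.2, 0.8, 6)
        cube = HsiCube(np.tile(ref, (3, 3, 1)), np.linspace(400, 1000, 6))
        out, model = msc(cube)
        np.testing.assert_allclose(model.slopes, 1.0, atol=1e-12)
        np.testing.assert_allclose(model.intercepts, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data, cube.data, atol=1e-12)

    def test_affine_distortion_inverted_exactly(self):
        """Spectra a_i * ref + c_i are restored to ref to machine precision."""
        rng = np.random.default_rng(4)
        ref = np.linspace(0.1, 0.9, 8) + 0.05 * np.sin(np.arange(8))
        a = rng.uniform(0.5, 2.0, size=(5, 5))
        c = rng.normal(0, 0.3, size=(5, 5))
        data = a[..., None] * ref + c[..., None]
        cube = HsiCube(data, np.linspace(400, 1000, 8))
        out, model = msc(cube, reference=ref)
        np.testing.assert_allclose(model.slopes.reshape(5, 5), a, atol=1e-10)
        np.testing.assert_allclose(model.intercepts.reshape(5, 5), c, atol=1e-10)
        np.testing.assert_allclose(out.data, np.broadcast_to(ref, data.shape), atol=1e-10)

    def test_variance_shrinks_on_scattered_single_material(self):
        """Per-pixel affine scatter around one signature is (mostly) removed."""
        rng = np.random.default_rng(20)
        S = np.linspace(0.2, 0.8, 12) + 0.1 * np.sin(np.arange(12))
        a = 1.0 + 0.1 * rng.standard_normal((20, 20, 1))
        c = 0.05 * rng.standard_normal((20, 20, 1))
        noise = 0.005 * rng.standard_normal((20, 20, 12))
        cube = HsiCube(a * S + c + noise, np.linspace(400, 1000, 12))
        out, _ = msc(cube)
        before = cube.pixels().var(axis=0)
        after = out.pixels().var(axis=0)
        assert np.all(after < before)

    def test_reference_length_mismatch(self):
        with pytest.raises(ValueError, match="reference"):
            msc(const_cube(1.0), reference=np.ones(3))


# ---------------------------------------------------------------- pca


class TestPca:
    def test_rank_one_data(self):
        rng = np.random.default_rng(5)
        direction = rng.normal(size=6)
        t = rng.normal(size=50)
        cube = HsiCube((t[:, None] * direction).reshape(10, 5, 6), np.linspace(400, 1000, 6))
        model = pca_fit(cube, var_threshold=1.0)
        assert model.retained == 1
        assert np.all(model.eigenvalues[1:] < 1e-10)
        out = pca_apply(cube, model)
        recon = out.pixels() @ model.components.T + model.center
        np.testing.assert_allclose(recon, cube.pixels(), atol=1e-8)

    def test_threshold_two_band(self):
        """Variances 9 and 1 on orthogonal axes: b=0.9 retains one component."""
        rng = np.random.default_rng(6)
        n = 4000
        X = np.stack([3 * rng.standard_normal(n), rng.standard_normal(n)], axis=1)
        cube = HsiCube(X.reshape(80, 50, 2), np.array([400.0, 500.0]))
        model = pca_fit(cube, var_threshold=0.85)
        assert model.retained == 1

    def test_eigenvalues_match_independent_svd_route(self):
        """Population eigenvalues agree with sklearn's SVD-based PCA (rescaled)."""
        rng = np.random.default_rng(7)
        cube = rand_cube(rng, 50, 50, 20)
        model = pca_fit(cube, n_components=20)
        X = cube.pixels()
        sk = SkPCA(n_components=20).fit(X)
        m = X.shape[0]
        np.testing.assert_allclose(model.eigenvalues, sk.explained_variance_ * (m - 1) / m, rtol=1e-8)
        # loadings agree up to sign
        dots = np.abs(np.sum(model.components * sk.components_.T, axis=0))
        np.testing.assert_allclose(dots, 1.0, atol=1e-8)

    def test_orthonormal_loadings_and_descending_eigenvalues(self):
        rng = np.random.default_rng(8)
        model = pca_fit(rand_cube(rng, 30, 30, 12), n_components=5)
        np.testing.assert_allclose(model.components.T @ model.components, np.eye(5), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_threshold_rule_matches_exhaustive_scan(self):
        rng = np.random.default_rng(9)
        cube = rand_cube(rng, 40, 40, 10)
        for b in (0.5, 0.9, 0.97, 1.0):
            model = pca_fit(cube, var_threshold=b)
            ratio = np.cumsum(model.eigenvalues) / model.eigenvalues.sum()
            brute = next(p for p in range(1, 11) if ratio[p - 1] >= b - 1e-12)
            assert model.retained == brute

    def test_reconstruction_error_is_trailing_eigenvalue_sum(self):
        rng = np.random.default_rng(10)
        cube = rand_cube(rng, 20, 25, 8)
        model = pca_fit(cube, n_components=3)
        out = pca_apply(cube, model)
        recon = out.pixels() @ model.components.T + model.center
        err = ((cube.pixels() - recon) ** 2).sum()
        expected = model.eigenvalues[3:].sum() * cube.pixels().shape[0]
        np.testing.assert_allclose(err, expected, rtol=1e-8)

    def test_full_rank_lossless(self):
        rng = np.random.default_rng(11)
        cube = rand_cube(rng, 10, 10, 5)
        model = pca_fit(cube, n_components=5)
        out = pca_apply(cube, model)
        recon = out.pixels() @ model.components.T + model.center
        np.testing.assert_allclose(recon, cube.pixels(), atol=1e-9)

    def test_328_band_cube_to_16(self):
        rng = np.random.default_rng(12)
        cube = rand_cube(rng, 20, 20, 328)
        model = pca_fit(cube, n_components=16)
        out = pca_apply(cube, model)
        assert out.bands == 16

    def test_both_or_neither_selector_rejected(self):
        rng = np.random.default_rng(13)
        cube = rand_cube(rng, 5, 5, 3)
        with pytest.raises(ValueError):
            pca_fit(cube)
        with pytest.raises(ValueError):
            pca_fit(cube, var_threshold=0.9, n_components=2)
        with pytest.raises(ValueError):
            pca_fit(cube, n_components=4)

    def test_band_mismatch_on_apply(self):
        rng = np.random.default_rng(14)
        model = pca_fit(rand_cube(rng, 5, 5, 4), n_components=2)
        with pytest.raises(ValueError, match="bands"):
            pca_apply(rand_cube(rng, 5, 5, 6), model)

    def test_sklearn_pipeline_compatible(self):
        from sklearn.pipeline import make_pipeline

        from cottonhsi import BandStandardizer

        rng = np.random.default_rng(15)
        X = rng.normal(size=(100, 8))
        pipe = make_pipeline(BandStandardizer(), SpectralPCA(n_components=3))
        T = pipe.fit_transform(X)
        assert T.shape == (100, 3)


# ---------------------------------------------------------------- absorbance


@pytest.mark.parametrize("factor,expected", [(1.0, 0.0), (0.1, 1.0), (10.0, -1.0)])
def test_absorbance(factor, expected):
    I0 = np.linspace(0.5, 1.5, 4)
    cube = HsiCube(np.tile(I0 * factor, (2, 2, 1)), np.linspace(400, 1000, 4))
    out = absorbance(cube, I0)
    np.testing.assert_allclose(out.data, expected, atol=1e-12)


# ---------------------------------------------------------------- chain


class TestChain:
    def test_all_stages_disabled_identity(self, small_scene):
        raw, *_ = small_scene
        cfg = PreprocessConfig(bw_correct=False, standardize=False, msc=False, pca=False)
        res = preprocess_chain(raw, None, None, cfg)
        np.testing.assert_array_equal(res.cube.data, raw.data)

    def test_noise_free_chain_separates_classes(self, clean_scene):
        """Full chain with p=3 leaves class clusters well separated."""
        raw, dark, white, truth, _ = clean_scene
        res = preprocess_chain(raw, dark, white, PreprocessConfig(pca_components=3), labels=truth)
        assert res.cube.bands == 3
        X = res.cube.pixels()
        y = truth.labels.ravel()
        means = np.stack([X[y == c].mean(axis=0) for c in range(1, 10)])
        spreads = [X[y == c].std(axis=0).max() for c in range(1, 10)]
        for i in range(9):
            for j in range(i + 1, 9):
                assert np.linalg.norm(means[i] - means[j]) > max(spreads[i], spreads[j])

    def test_benchmark_configuration_band_count(self):
        rng = np.random.default_rng(16)
        cube = rand_cube(rng, 12, 12, 328)
        cfg = PreprocessConfig(bw_correct=False, pca_components=16)
        res = preprocess_chain(cube, None, None, cfg)
        assert res.cube.bands == 16
        assert res.pca_model.retained == 16
        assert res.msc_model is not None

    def test_labels_cropped_with_cube(self, small_scene):
        raw, dark, white, truth, _ = small_scene
        cfg = PreprocessConfig(crop_rows=(4, 40), crop_cols=(2, 30), pca_components=4)
        res = preprocess_chain(raw, dark, white, cfg, labels=truth)
        assert res.cube.data.shape[:2] == (36, 28)
        assert res.labels.labels.shape == (36, 28)
        np.testing.assert_array_equal(res.labels.labels, truth.labels[4:40, 2:30])
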