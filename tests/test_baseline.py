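"""Luminance, GLCM texture measures, feature vectors and the SVM baseline."""

import numpy as np
import pytest
from skimage.feature import graycomatrix

from chopmap.baseline import (
    GLCMConfig,
    TextureSVM,
    compute_glcm,
    extract_feature_vector,
    glcm_measures,
    quantize,
    to_luminance,
    train_svm_baseline,
)

WORKED_LEVELS = np.array([[0, 0, 1], [0, 0, 1], [0, 1, 1]])


def naive_glcm(q, levels, offsets, symmetric, normalize):
    """Independent oracle: explicit double loop over pixel pairs."""
    h, w = q.shape
    P = np.zeros((levels, levels))
    for dx, dy in offsets:
        for y in range(h):
            for x in range(w):
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < h and 0 <= x2 < w:
                    P[q[y, x], q[y2, x2]] += 1
    if symmetric:
        P = P + P.T
    if normalize and P.sum() > 0:
        P = P / P.sum()
    return P


class TestLuminance:
    def test_grey_pixel_invariant_under_weights(self):
        px = np.full((2, 2, 3), 100.0)
        np.testing.assert_allclose(to_luminance(px, (0.2, 0.5, 0.3)), 100.0)

    def test_pure_red_default_weights(self):
        px = np.zeros((1, 1, 3))
        px[0, 0, 0] = 255
        assert to_luminance(px)[0, 0] == pytest.approx(76.245)

    def test_black_is_zero(self):
        np.testing.assert_array_equal(to_luminance(np.zeros((3, 3, 3))), 0.0)

    def test_invalid_weights_raise(self):
        with pytest.raises(ValueError):
            to_luminance(np.zeros((2, 2, 3)), (0.5, 0.5, 0.5))


class TestQuantize:
    @pytest.mark.parametrize(
        "value,levels,expected", [(0, 32, 0), (255, 32, 31), (128, 2, 1), (127, 2, 0)]
    )
    def test_binning(self, value, levels, expected):
        assert quantize(np.array([[float(value)]]), levels)[0, 0] == expected

    def test_monotone(self):
        vals = np.linspace(0, 255, 100)[None, :]
        q = quantize(vals, 32)
        assert np.all(np.diff(q[0]) >= 0)

    def test_too_few_levels(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((2, 2)), 1)


class TestGLCM:
    def test_worked_example(self):
        P = compute_glcm(WORKED_LEVELS, 2, offsets=[(1, 0)], symmetric=True)
        np.testing.assert_allclose(
            P, [[4 / 12, 3 / 12], [3 / 12, 2 / 12]]
        )

    def test_constant_tile_single_entry(self):
        P = compute_glcm(np.full((4, 4), 3), 8, offsets=[(1, 0), (0, 1)])
        assert P[3, 3] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_normalized_sums_to_one(self, rng):
        q = rng.integers(0, 8, (10, 10))
        P = compute_glcm(q, 8)
        assert abs(P.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(P, P.T)

    def test_matches_naive_pair_counter(self, rng):
        offsets_pool = [(1, 0), (0, 1), (1, 1), (1, -1), (2, 0), (0, 2)]
        for _ in range(1000):
            q = rng.integers(0, 2, (4, 4))
            k = int(rng.integers(1, 4))
            offs = [offsets_pool[i] for i in rng.choice(len(offsets_pool), k, replace=False)]
            sym = bool(rng.integers(0, 2))
            mine = compute_glcm(q, 2, offsets=offs, symmetric=sym, normalize=True)
            ref = naive_glcm(q, 2, offs, sym, True)
            np.testing.assert_allclose(mine, ref)

    def test_matches_skimage_reference(self, rng):
        # skimage angle convention: 0 -> (dx=1,dy=0), pi/2 -> (dx=0,dy=1)
        q = rng.integers(0, 8, (12, 12)).astype(np.uint8)
        mine = compute_glcm(q, 8, offsets=[(1, 0)], symmetric=False, normalize=False)
        ref = graycomatrix(q, [1], [0], levels=8)[:, :, 0, 0]
        np.testing.assert_array_equal(mine, ref)
        mine_v = compute_glcm(q, 8, offsets=[(0, 1)], symmetric=False, normalize=False)
        ref_v = graycomatrix(q, [1], [np.pi / 2], levels=8)[:, :, 0, 0]
        np.testing.assert_array_equal(mine_v, ref_v)

    def test_offset_validation(self):
        with pytest.raises(ValueError):
            compute_glcm(np.zeros((3, 3), int), 2, offsets=[(0, 0)])
        with pytest.raises(ValueError):
            compute_glcm(np.zeros((2, 2), int), 2, offsets=[(3, 0)])


class TestMeasures:
    def test_worked_example_values(self):
        P = compute_glcm(WORKED_LEVELS, 2, offsets=[(1, 0)], symmetric=True)
        m = glcm_measures(P)
        assert m["contrast"] == pytest.approx(0.5)
        assert m["dissimilarity"] == pytest.approx(0.5)
        assert m["homogeneity"] == pytest.approx(0.75)
        assert m["mean"] == pytest.approx(5 / 12)
        assert m["variance"] == pytest.approx(35 / 144)

    def test_diagonal_mass(self):
        P = np.diag([0.25, 0.25, 0.5])
        m = glcm_measures(P)
        assert m["contrast"] == 0.0
        assert m["dissimilarity"] == 0.0
        assert m["homogeneity"] == pytest.approx(1.0)

    def test_point_mass(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        m = glcm_measures(P)
        assert m["mean"] == pytest.approx(2.0)
        assert m["variance"] == pytest.approx(0.0)

    def test_transpose_invariance_for_symmetric_matrices(self, rng):
        for _ in range(50):
            A = rng.uniform(0, 1, (6, 6))
            P = A + A.T
            P = P / P.sum()
            m1, m2 = glcm_measures(P), glcm_measures(P.T)
            for key in m1:
                assert m1[key] == pytest.approx(m2[key])

    def test_unnormalized_raises(self):
        with pytest.raises(ValueError):
            glcm_measures(np.ones((3, 3)))


class TestFeatureVector:
    def test_constant_tile(self):
        tile = np.full((8, 8, 3), 90, dtype=np.uint8)
        f = extract_feature_vector(tile)
        assert f.shape == (8,)
        np.testing.assert_allclose(f[:3], 90.0)
        assert f[4] == pytest.approx(0.0)  # variance
        assert f[5] == pytest.approx(0.0)  # contrast
        assert f[6] == pytest.approx(1.0)  # homogeneity
        assert f[7] == pytest.approx(0.0)  # dissimilarity

    def test_texture_distinguishes_equal_histograms(self):
        # checkerboard vs half-blocks: same pixel histogram, different GLCM
        cb = np.indices((8, 8)).sum(axis=0) % 2 * 255
        blocks = np.zeros((8, 8))
        blocks[:, 4:] = 255
        f_cb = extract_feature_vector(np.repeat(cb[:, :, None], 3, 2).astype(np.uint8))
        f_bl = extract_feature_vector(np.repeat(blocks[:, :, None], 3, 2).astype(np.uint8))
        np.testing.assert_allclose(f_cb[:3], f_bl[:3])  # equal RGB means
        assert f_cb[5] > f_bl[5]  # contrast differs


class TestSVMBaseline:
    def _blobs(self, rng, n=100):
        a = rng.normal(0, 1, (n // 2, 8))
        b = rng.normal(6, 1, (n // 2, 8))
        X = np.vstack([a, b])
        y = np.array(["bamboo"] * (n // 2) + ["other"] * (n // 2), dtype=object)
        return X, y

    def test_separable_blobs_high_cv_accuracy(self, rng):
        X, y = self._blobs(rng)
        pipe, best = train_svm_baseline(X, y, folds=5, seed=0)
        assert best["cv_accuracy"] >= 0.95
        assert np.mean(pipe.predict(X) == y) >= 0.95

    def test_selected_params_belong_to_grids(self, rng):
        X, y = self._blobs(rng)
        gammas, costs = [0.1, 1.0], [1.0, 10.0]
        _, best = train_svm_baseline(X, y, gamma_grid=gammas, cost_grid=costs, seed=0)
        assert best["gamma"] in gammas
        assert best["cost"] in costs

    def test_deterministic_selection(self, rng):
        X, y = self._blobs(rng)
        _, b1 = train_svm_baseline(X, y, seed=3)
        _, b2 = train_svm_baseline(X, y, seed=3)
        assert b1 == b2

    def test_single_class_raises(self, rng):
        X = rng.normal(0, 1, (20, 8))
        with pytest.raises(ValueError):
            train_svm_baseline(X, ["bamboo"] * 20)

    def test_empty_grid_raises(self, rng):
        X, y = self._blobs(rng)
        with pytest.raises(ValueError):
            train_svm_baseline(X, y, gamma_grid=[])

    def test_texture_svm_estimator_on_tiles(self, rng):
        smooth = np.full((20, 16, 16, 3), 120, dtype=np.uint8)
        noisy = rng.integers(0, 256, (20, 16, 16, 3), dtype=np.uint8)
        X = np.concatenate([smooth, noisy])
        y = np.array(["other"] * 20 + ["bamboo"] * 20, dtype=object)
        svm = TextureSVM(cv_folds=3, random_state=0).fit(X, y)
        assert svm.gamma_ in svm.gamma_grid
        assert svm.cost_ in svm.cost_grid
        assert np.mean(svm.predict(X) == y) == 1.0
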