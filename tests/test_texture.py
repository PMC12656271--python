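"""GLCM texture features: quantisation, matrices, metrics, windowed engine."""

import math

import numpy as np
import pytest

from maizelai import (
    BAND_NAMES, BandStack, compute_glcm, glcm_metrics, quantize_band,
    texture_features_for_sample,
)
from maizelai.texture import (
    TEXTURE_METRICS, TF_NAMES, _windowed_metric_maps, band_texture_metrics,
)

CHECKER = np.indices((4, 4)).sum(axis=0) % 2


def brute_force_window_metrics(level_window, offset):
    """Independent oracle: explicit pair enumeration + direct formulas."""
    dx, dy = offset
    h, w = level_window.shape
    counts = {}
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = int(level_window[r, c]), int(level_window[r2, c2])
                counts[(a, b)] = counts.get((a, b), 0) + 1
                counts[(b, a)] = counts.get((b, a), 0) + 1
    total = sum(counts.values())
    p = {k: v / total for k, v in counts.items()}
    mu_i = sum(i * v for (i, _), v in p.items())
    mu_j = sum(j * v for (_, j), v in p.items())
    var_i = sum((i - mu_i) ** 2 * v for (i, _), v in p.items())
    var_j = sum((j - mu_j) ** 2 * v for (_, j), v in p.items())
    cov = sum((i - mu_i) * (j - mu_j) * v for (i, j), v in p.items())
    sd = math.sqrt(var_i * var_j)
    return {
        "mean": mu_i,
        "var": var_i,
        "hom": sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items()),
        "con": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "dis": sum(abs(i - j) * v for (i, j), v in p.items()),
        "et": -sum(v * math.log(v) for v in p.values()),
        "sem": sum(v * v for v in p.values()),
        "cor": cov / sd if sd > 0 else 0.0,
    }


def brute_force_feature_means(level_array, window, offset):
    h, w = level_array.shape
    acc = {m: [] for m in TEXTURE_METRICS}
    for y in range(h - window + 1):
        for x in range(w - window + 1):
            vals = brute_force_window_metrics(level_array[y : y + window, x : x + window], offset)
            for m in TEXTURE_METRICS:
                acc[m].append(vals[m])
    return {m: float(np.mean(v)) for m, v in acc.items()}


class TestQuantize:
    def test_constant_band_maps_to_zero(self):
        assert np.all(quantize_band(np.full((4, 4), 0.7), 8) == 0)

    def test_three_values_two_levels(self):
        q = quantize_band(np.array([[0.0, 0.5, 1.0]]), 2)
        assert q.tolist() == [[0, 1, 1]]

    def test_full_resolution_identity_up_to_scale(self):
        arr = np.arange(256, dtype=float).reshape(16, 16) / 255.0
        q = quantize_band(arr, 256)
        assert np.array_equal(q, np.arange(256).reshape(16, 16))

    def test_levels_below_two_raise(self):
        with pytest.raises(ValueError):
            quantize_band(np.ones((2, 2)), 1)


class TestGLCM:
    def test_constant_window_single_entry(self):
        g = compute_glcm(np.zeros((4, 4), dtype=int), (1, 0), True, levels=3)
        assert g.p[0, 0] == 1.0 and g.p.sum() == 1.0

    def test_checkerboard_horizontal_offset(self):
        g = compute_glcm(CHECKER, (1, 0), True, levels=2)
        assert g.p[0, 1] == pytest.approx(0.5)
        assert g.p[1, 0] == pytest.approx(0.5)
        assert g.p[0, 0] == 0.0 and g.p[1, 1] == 0.0

    def test_checkerboard_diagonal_offset(self):
        # diagonal neighbours share colour; exact enumeration of the nine
        # (1, 1) pairs in a 4x4 checkerboard gives 5 dark and 4 light
        g = compute_glcm(CHECKER, (1, 1), True, levels=2)
        assert g.p[0, 0] == pytest.approx(5 / 9)
        assert g.p[1, 1] == pytest.approx(4 / 9)
        assert g.p[0, 1] == 0.0 and g.p[1, 0] == 0.0

    def test_offset_larger_than_window_raises(self):
        with pytest.raises(ValueError):
            compute_glcm(np.zeros((3, 3), dtype=int), (5, 0))

    def test_matches_skimage_whole_image_glcm(self):
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(3)
        img = rng.integers(0, 6, (16, 16))
        ours = compute_glcm(img, offset=(1, 0), symmetric=True, levels=6)
        ref = graycomatrix(
            img.astype(np.uint8), [1], [0], levels=6, symmetric=True, normed=True
        )[:, :, 0, 0]
        np.testing.assert_allclose(ours.p, ref, atol=1e-12)


class TestMetrics:
    def test_constant_window_closed_form(self):
        vals = glcm_metrics(compute_glcm(np.ones((4, 4), dtype=int), (1, 1), True, 2))
        assert vals["con"] == 0 and vals["dis"] == 0 and vals["et"] == 0
        assert vals["sem"] == 1 and vals["hom"] == 1 and vals["var"] == 0
        assert vals["cor"] == 0  # zero-variance convention

    def test_checkerboard_horizontal_closed_form(self):
        vals = glcm_metrics(compute_glcm(CHECKER, (1, 0), True, 2))
        assert vals["con"] == pytest.approx(1.0)
        assert vals["dis"] == pytest.approx(1.0)
        assert vals["hom"] == pytest.approx(0.5)
        assert vals["sem"] == pytest.approx(0.5)
        assert vals["et"] == pytest.approx(math.log(2))
        assert vals["cor"] == pytest.approx(-1.0)

    def test_checkerboard_diagonal_closed_form(self):
        vals = glcm_metrics(compute_glcm(CHECKER, (1, 1), True, 2))
        assert vals["con"] == pytest.approx(0.0)
        assert vals["cor"] == pytest.approx(1.0)


class TestWindowedEngine:
    @pytest.mark.parametrize("offset", [(1, 1), (1, 0), (0, 1), (2, 1), (-1, 1)])
    def test_engine_equals_per_window_glcm_loop(self, offset):
        rng = np.random.default_rng(11)
        arr = rng.integers(0, 5, (9, 10))
        maps = _windowed_metric_maps(arr, 4, offset, 5)
        for y in range(6):
            for x in range(7):
                ref = glcm_metrics(compute_glcm(arr[y : y + 4, x : x + 4], offset, True, 5))
                for m in TEXTURE_METRICS:
                    assert maps[m][y, x] == pytest.approx(ref[m], abs=1e-10)

    def test_engine_equals_independent_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            arr = rng.integers(0, 2, (8, 8))
            got = band_texture_metrics(arr.astype(float), window=4, offset=(1, 1), levels=2)
            want = brute_force_feature_means(quantize_band(arr.astype(float), 2), 4, (1, 1))
            for m in TEXTURE_METRICS:
                assert got[m] == pytest.approx(want[m], abs=1e-10)


class TestSampleFeatures:
    def _stack(self, fill=None, seed=0):
        rng = np.random.default_rng(seed)
        mk = (lambda: np.full((16, 16), fill)) if fill is not None else (lambda: rng.random((16, 16)))
        return BandStack({b: mk() for b in BAND_NAMES})

    def test_forty_named_features(self):
        feats = texture_features_for_sample(self._stack(), 0.0)
        assert tuple(feats) == TF_NAMES
        assert len(feats) == 40

    def test_constant_stack_degenerate_values(self):
        feats = texture_features_for_sample(self._stack(fill=0.3), 0.0)
        for b in BAND_NAMES:
            for m in ("con", "dis", "et", "var"):
                assert feats[f"{b}_{m}"] == 0.0
            for m in ("hom", "sem"):
                assert feats[f"{b}_{m}"] == 1.0

    def test_roi_smaller_than_window_raises(self):
        small = BandStack({b: np.ones((3, 3)) for b in BAND_NAMES})
        with pytest.raises(ValueError):
            texture_features_for_sample(small, 0.0, window=4)

    def test_block_mode_uses_disjoint_tiles(self):
        arr = np.random.default_rng(2).random((16, 16))
        sliding = band_texture_metrics(arr, window=4, mode="sliding")
        block = band_texture_metrics(arr, window=4, mode="block")
        assert sliding.keys() == block.keys()
        assert any(sliding[m] != block[m] for m in TEXTURE_METRICS)

    def test_affine_band_change_leaves_features_invariant(self):
        arr = np.random.default_rng(4).random((12, 12))
        a = band_texture_metrics(arr, window=4)
        b = band_texture_metrics(0.5 * arr + 0.2, window=4)
        for m in TEXTURE_METRICS:
            assert a[m] == pytest.approx(b[m], abs=1e-12)


def test_blue_variance_declines_with_lai(small_experiment, small_features):
    _, records, _ = small_experiment
    lai = np.array([r.lai_true for r in records])
    assert np.corrcoef(small_features["B_var"], lai)[0, 1] < 0
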