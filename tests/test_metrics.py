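"""Heterogeneity metrics: VIs, CV/CHA/SAM, GLCM textures, Rao's Q."""

import numpy as np
import pytest
from shapely.geometry import box

from canopydiv.metrics import (
    TextureConfig,
    VI_BANDS,
    cha_metric,
    cv_metric,
    glcm_texture,
    quantize_scene,
    raos_q,
    sam_metric,
    spectral_information_means,
    vegetation_index,
    _glcm_features_from_matrix,
)
from canopydiv.raster import PlotPixelSet
from conftest import make_raster

GF2 = ("B", "G", "R", "NIR")


def pixel_set(spectra, band_names=GF2, res=1.0):
    return PlotPixelSet(
        plot_id="P", spectra=np.asarray(spectra, dtype=float),
        band_names=tuple(band_names), resolution=res,
    )


class TestVegetationIndices:
    def test_ndvi_sr_hand_values(self):
        px = pixel_set([[0.05, 0.08, 0.1, 0.4]])
        assert vegetation_index(px, "NDVI", "GF2")[0] == pytest.approx(0.6)
        assert vegetation_index(px, "SR", "GF2")[0] == pytest.approx(4.0)

    def test_nir_equals_red(self):
        px = pixel_set([[0.05, 0.08, 0.2, 0.2]])
        assert vegetation_index(px, "NDVI", "GF2")[0] == pytest.approx(0.0)
        assert vegetation_index(px, "SR", "GF2")[0] == pytest.approx(1.0)

    def test_evi_all_zero_reflectance(self):
        # denominator = 0 + 0 - 0 + 1 = 1, numerator 0 → EVI = 0
        px = pixel_set([[0.0, 0.0, 0.0, 0.0]])
        assert vegetation_index(px, "EVI", "GF2")[0] == pytest.approx(0.0)

    def test_zero_denominator_gives_nan(self):
        px = pixel_set([[0.0, 0.0, 0.0, 0.0]])
        assert np.isnan(vegetation_index(px, "SR", "GF2")[0])

    def test_ccci_chain(self):
        s2 = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")
        spec = np.array([[0.04, 0.07, 0.05, 0.12, 0.25, 0.30, 0.45, 0.47, 0.20, 0.10]])
        px = pixel_set(spec, band_names=s2)
        ndvi = (0.45 - 0.05) / 0.50
        ndfr = (0.30 - 0.12) / 0.42
        lo = 0.281 * ndvi + 0.0225
        hi = 0.576 * ndvi - 0.0085
        expected = (ndfr - lo) / (hi - lo)
        assert vegetation_index(px, "CCCI", "S2")[0] == pytest.approx(expected, abs=1e-12)

    def test_unknown_vi_for_sensor(self):
        px = pixel_set([[0.1, 0.1, 0.1, 0.1]])
        with pytest.raises(ValueError, match="not defined"):
            vegetation_index(px, "NDWI", "GF2")

    def test_means_match_hand_arithmetic(self):
        spectra = np.array([[0.1, 0.2, 0.1, 0.4], [0.3, 0.2, 0.3, 0.6], [0.2, 0.2, 0.2, 0.5]])
        out = spectral_information_means(pixel_set(spectra), "GF2")
        assert out["mean_B"] == pytest.approx(0.2)
        assert out["mean_NIR"] == pytest.approx(0.5)
        ndvi = (spectra[:, 3] - spectra[:, 2]) / (spectra[:, 3] + spectra[:, 2])
        assert out["mean_NDVI"] == pytest.approx(ndvi.mean())
        # permutation invariance
        out2 = spectral_information_means(pixel_set(spectra[::-1]), "GF2")
        assert out == pytest.approx(out2)


class TestCv:
    def test_constant_series_zero(self):
        assert cv_metric([3.3, 3.3, 3.3]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_1_2_3(self):
        assert cv_metric([1.0, 2.0, 3.0]) == pytest.approx(0.5, abs=1e-12)

    def test_scale_invariance(self, rng):
        v = rng.uniform(0.5, 2.0, size=30)
        assert cv_metric(7.3 * v) == pytest.approx(cv_metric(v), rel=1e-12)

    def test_undefined_cases_warn(self):
        with pytest.warns(UserWarning, match="at least two"):
            assert np.isnan(cv_metric([1.0]))
        with pytest.warns(UserWarning, match="mean"):
            assert np.isnan(cv_metric([-1.0, 1.0]))


class TestCha:
    def test_identical_pixels_zero(self):
        assert cha_metric(np.tile([0.1, 0.2, 0.3, 0.4], (5, 1))) == 0.0

    def test_unit_square_area(self):
        # 4 spectra spanning a unit square in a 2-D subspace; the principal
        # axes are an orthonormal rotation, so the hull area is preserved
        base = np.array([0.3, 0.3, 0.3, 0.3])
        u = np.array([0.5, 0.5, 0.0, 0.0]) * np.sqrt(2)  # unit vectors
        v = np.array([0.0, 0.0, 0.5, -0.5]) * np.sqrt(2)
        corners = [base, base + u, base + v, base + u + v]
        assert cha_metric(np.array(corners)) == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_hull_oracle(self, rng):
        spectra = rng.uniform(size=(10, 4))
        area = cha_metric(spectra)
        # independent oracle: shoelace area of the brute-force hull of the
        # same 2-D projection
        X = spectra - spectra.mean(0)
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        pts = X @ vt[:2].T

        def brute_hull_area(points):
            # gift wrapping + shoelace, no scipy
            pts_l = sorted(map(tuple, points))
            def cross(o, a, b):
                return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])
            lower, upper = [], []
            for p in pts_l:
                while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
                    lower.pop()
                lower.append(p)
            for p in reversed(pts_l):
                while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
                    upper.pop()
                upper.append(p)
            hull = lower[:-1] + upper[:-1]
            area = 0.0
            for i in range(len(hull)):
                x0, y0 = hull[i]
                x1, y1 = hull[(i + 1) % len(hull)]
                area += x0 * y1 - x1 * y0
            return abs(area) / 2

        assert area == pytest.approx(brute_hull_area(pts), abs=1e-9)

    def test_collinear_cloud_zero(self):
        t = np.linspace(0, 1, 6)[:, None]
        spectra = t * np.array([0.1, 0.2, 0.3, 0.4])
        assert cha_metric(spectra) == 0.0

    def test_too_few_pixels(self):
        with pytest.raises(ValueError):
            cha_metric(np.ones((2, 4)))


class TestSam:
    def test_identical_pixels_zero(self):
        assert sam_metric(np.tile([0.2, 0.4], (4, 1))) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_pair_pi_over_4(self):
        # pixels (1,0) and (0,1): mean (0.5,0.5), each at 45 degrees
        assert sam_metric(np.array([[1.0, 0.0], [0.0, 1.0]])) == pytest.approx(np.pi / 4)

    def test_scale_invariance(self, rng):
        S = rng.uniform(0.1, 1.0, size=(6, 4))
        # scaling the whole cloud leaves every angle unchanged
        assert sam_metric(13.0 * S) == pytest.approx(sam_metric(S), abs=1e-12)
        # against a fixed reference, scaling one spectrum leaves its angle unchanged
        mean = S.mean(axis=0)

        def angle(s):
            return np.arccos(np.clip(s @ mean / (np.linalg.norm(s) * np.linalg.norm(mean)), -1, 1))

        assert angle(7.0 * S[2]) == pytest.approx(angle(S[2]), abs=1e-12)

    def test_zero_norm_excluded(self):
        with pytest.warns(UserWarning, match="zero-norm"):
            val = sam_metric(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
        assert val == pytest.approx(np.pi / 4)


class TestRaosQ:
    def test_constant_heights_zero(self):
        assert raos_q(np.full(10, 7.0)) == pytest.approx(0.0, abs=1e-12)

    def test_two_level_closed_form(self):
        # half at h, half at h + Δ: Q = Δ/2
        h = np.array([10.0] * 6 + [14.0] * 6)
        assert raos_q(h) == pytest.approx(2.0, abs=1e-12)

    def test_translation_invariance(self, rng):
        h = rng.uniform(5, 30, size=50)
        assert raos_q(h + 100.0) == pytest.approx(raos_q(h), abs=1e-9)

    def test_matches_double_sum_oracle(self, rng):
        h = rng.uniform(0, 25, size=40)
        brute = np.abs(h[:, None] - h[None, :]).sum() / (len(h) ** 2)
        assert raos_q(h) == pytest.approx(brute, abs=1e-12)

    def test_bounded_by_max_pairwise_difference(self, rng):
        h = rng.uniform(0, 30, size=25)
        assert 0.0 <= raos_q(h) <= np.ptp(h)


def brute_force_glcm_features(img, window, levels, distance=1,
                              offsets=((0, 1), (-1, 1), (-1, 0), (-1, -1))):
    """Independent oracle: pure-Python pair counting per window (both pair
    members inside the window and the image, both valid), then the textbook
    feature formulas on the direction-averaged symmetric matrix."""
    rows, cols = img.shape
    half = window // 2

    def in_win(r, c, i, j):
        return abs(i - r) <= half and abs(j - c) <= half and 0 <= i < rows and 0 <= j < cols

    feats_all = []
    for r in range(rows):
        for c in range(cols):
            if img[r, c] < 0:
                continue
            mats = []
            for dr, dc in offsets:
                M = np.zeros((levels, levels))
                for i in range(r - half, r + half + 1):
                    for j in range(c - half, c + half + 1):
                        i2, j2 = i + dr * distance, j + dc * distance
                        if not (in_win(r, c, i, j) and in_win(r, c, i2, j2)):
                            continue
                        a, b = img[i, j], img[i2, j2]
                        if a < 0 or b < 0:
                            continue
                        M[a, b] += 1
                        M[b, a] += 1
                if M.sum() > 0:
                    mats.append(M / M.sum())
            if not mats:
                continue
            feats_all.append(_glcm_features_from_matrix(np.mean(mats, axis=0)))
    return feats_all


class TestGlcm:
    def test_constant_image(self):
        img = make_raster(np.full((1, 9, 9), 3.3), res=1.0, band_names=("PC1",))
        cfg = TextureConfig(levels=8, window=3)
        out = glcm_texture(img, cfg, box(2, 2, 7, 7))
        assert out["Cont"] == pytest.approx(0.0)
        assert out["Dis"] == pytest.approx(0.0)
        assert out["Ent"] == pytest.approx(0.0)
        assert out["Asm"] == pytest.approx(1.0)
        assert np.isnan(out["Cor"])  # no variance → correlation undefined

    def test_checkerboard_horizontal_offset(self, monkeypatch):
        """4x4 two-level checkerboard with the horizontal offset only: every
        distance-1 pair differs by one level, so the GLCM carries all its
        mass off-diagonal and Cont = 1."""
        import canopydiv.metrics as m

        monkeypatch.setattr(m, "_DIRECTIONS", ((0, 1),))
        pattern = np.indices((4, 4)).sum(0) % 2
        quantized = pattern.astype(np.int64)
        mats = m._windowed_glcm(quantized, np.array([1]), np.array([1]), 3, 2, 1)
        P = mats[0]
        assert P.sum() == pytest.approx(1.0)
        assert P[0, 0] == 0.0 and P[1, 1] == 0.0  # off-diagonal mass 1
        feats = _glcm_features_from_matrix(P)
        assert feats["Cont"] == pytest.approx(1.0)
        # brute-force pair counting agrees
        brute = brute_force_glcm_features(quantized, 3, 2, offsets=((0, 1),))
        assert brute[5]["Cont"] == pytest.approx(1.0)

    def test_normalization_any_window(self, rng):
        img_vals = rng.integers(0, 6, size=(10, 10)).astype(float)
        img = make_raster(img_vals, res=1.0, band_names=("PC1",))
        quantized = quantize_scene(img, 6)
        from canopydiv.metrics import _windowed_glcm

        mats = _windowed_glcm(quantized, np.array([4, 5]), np.array([4, 7]), 5, 6, 1)
        for m in mats:
            assert m.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_pair_counting(self, rng):
        """All 8 features vs pure-Python pair counting on small images."""
        levels, window = 4, 3
        img_vals = rng.integers(0, levels, size=(7, 7))
        raster = make_raster(img_vals.astype(float), res=1.0, band_names=("PC1",))
        quantized = quantize_scene(raster, levels)
        cfg = TextureConfig(levels=levels, window=window)
        # plot covering the full raster
        out = glcm_texture(raster, cfg, box(0, 0, 7, 7))
        brute = brute_force_glcm_features(quantized, window, levels)
        for feat in ("Mean", "Hom", "Cont", "Dis", "Ent", "Asm", "Var", "Cor"):
            vals = np.array([f[feat] for f in brute])
            expected = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
            assert out[feat] == pytest.approx(expected, abs=1e-9), feat

    def test_window_map(self):
        cfg = TextureConfig()
        assert [cfg.window_for_resolution(r) for r in (0.8, 3, 4, 5, 10)] == [27, 7, 5, 3, 3]

    def test_window_larger_than_raster_errors(self, rng):
        img = make_raster(rng.uniform(size=(5, 5)), band_names=("PC1",))
        with pytest.raises(ValueError, match="window"):
            glcm_texture(img, TextureConfig(window=7), box(0, 0, 5, 5))
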