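"""MIA segmentation: equalization, window matrix, PCA, Canny, filters."""

import numpy as np
import pandas as pd
import pytest

import cryofront as cf
from cryofront.mia import (SEMImage, SegmentationMask, bharati_matrix,
                           combine_and_filter, edge_filter,
                           equalize_brightness, pca_score_image,
                           pore_percentiles, pore_properties, segment_by_score,
                           segment_pores)


def sem(arr, px=1.0):
    return SEMImage(intensity=np.asarray(arr, dtype=float), px_size_um=px)


class TestEqualizeBrightness:
    def test_constant_image_unchanged(self):
        img = sem(np.full((64, 64), 120.0))
        out = equalize_brightness(img, window=11)
        assert np.allclose(out.intensity, 120.0)

    def test_mean_preserved(self):
        rng = np.random.default_rng(1)
        img = sem(rng.uniform(0, 255, size=(128, 128)))
        out = equalize_brightness(img, window=31)
        assert abs(out.intensity.mean() - img.intensity.mean()) < 1e-6

    def test_row_ramp_removed(self):
        """Linear row-wise charging ramp flattened to < 2 % of its
        amplitude in the interior rows."""
        rng = np.random.default_rng(2)
        rows, cols = 200, 200
        amp = 60.0
        ramp = amp * (np.arange(rows)[:, None] - rows / 2) / rows
        img = sem(150.0 + ramp + np.zeros((rows, cols)))
        out = equalize_brightness(img, window=61)
        interior = out.intensity[40:-40]
        dev = np.abs(interior.mean(axis=1) - out.intensity.mean())
        assert dev.max() < 0.02 * amp

    def test_white_noise_variance_not_increased(self):
        rng = np.random.default_rng(3)
        img = sem(150.0 + rng.normal(0, 10, size=(128, 128)))
        out = equalize_brightness(img, window=21)
        assert out.intensity.var() <= img.intensity.var() + 1e-9

    def test_window_validation(self):
        img = sem(np.zeros((32, 32)))
        with pytest.raises(ValueError):
            equalize_brightness(img, window=10)
        with pytest.raises(ValueError, match="larger"):
            equalize_brightness(img, window=33)


class TestBharatiMatrix:
    def test_counting_oracle_5x5(self):
        X, shape = bharati_matrix(np.arange(25.0).reshape(5, 5), window=3)
        assert X.shape == (9, 9)
        assert shape == (3, 3)

    def test_constant_image_zero_variance(self):
        X, _ = bharati_matrix(np.full((6, 6), 7.0), window=3)
        assert np.all(X == 7.0)
        assert np.all(X.var(axis=0) == 0.0)

    def test_centre_column_is_interior_intensities(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(size=(10, 12))
        w = 5
        X, shape = bharati_matrix(img, window=w)
        centre = X[:, (w * w) // 2].reshape(shape)
        assert np.array_equal(centre, img[w // 2:-(w // 2), w // 2:-(w // 2)])

    def test_image_smaller_than_window(self):
        with pytest.raises(ValueError):
            bharati_matrix(np.zeros((3, 3)), window=5)


class TestPCAScoreImage:
    def test_orthonormal_loadings_and_ordered_variance(self):
        rng = np.random.default_rng(5)
        img = rng.normal(size=(40, 40))
        X, shape = bharati_matrix(img, window=3)
        _, loadings, evr = pca_score_image(X, shape, n_components=3)
        assert np.allclose(loadings @ loadings.T, np.eye(3), atol=1e-8)
        assert np.all(np.diff(evr) <= 1e-12)

    def test_two_texture_separation(self):
        """First-component scores separate dark/noisy pores from the smooth
        matrix with > 95 % agreement after an optimal threshold."""
        spec = cf.PoreSpec(n_pores=40, seed=7, porosity_target=0.2,
                           charging_gradient=0.0)
        image, _, labels = cf.generate_sem_image(
            spec, image_shape=(256, 256), return_mask=True)
        w = 5
        X, shape = bharati_matrix(image, window=w)
        scores, _, _ = pca_score_image(X, shape)
        truth = (labels > 0)[w // 2:-(w // 2), w // 2:-(w // 2)].ravel()
        s = scores[0].ravel()
        best = max(
            np.mean((s > np.quantile(s, q)) == truth)
            for q in np.linspace(0.5, 0.99, 50))
        assert best > 0.95

    def test_degenerate_input_rejected(self):
        X = np.full((50, 9), 3.0)
        with pytest.raises(ValueError, match="zero variance"):
            pca_score_image(X, (50, 1))


class TestSegmentByScore:
    def test_threshold_below_min_selects_all(self):
        score = np.arange(25.0).reshape(5, 5)
        m = segment_by_score(score, -1.0)
        assert m.binary.all()

    def test_threshold_above_max_selects_none(self):
        score = np.arange(25.0).reshape(5, 5)
        m = segment_by_score(score, 100.0)
        assert not m.binary.any()

    def test_quantile_mode_density(self):
        rng = np.random.default_rng(8)
        score = rng.normal(size=(200, 200))
        m = segment_by_score(score, 0.8, quantile_mode=True)
        assert m.binary.mean() == pytest.approx(0.2, abs=0.01)

    def test_nan_border_never_selected(self):
        score = np.full((5, 5), np.nan)
        score[2, 2] = 1.0
        m = segment_by_score(score, 0.0)
        assert m.binary.sum() == 1

    def test_labels_match_binary(self):
        score = np.zeros((6, 6))
        score[1:3, 1:3] = 5.0
        score[4:, 4:] = 5.0
        m = segment_by_score(score, 1.0)
        assert m.labels.max() == 2
        assert np.array_equal(m.labels > 0, m.binary)


class TestEdgeFilter:
    def test_constant_image_empty(self):
        assert not edge_filter(np.full((64, 64), 80.0)).any()

    def test_step_edge_within_one_pixel(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 100.0
        edges = edge_filter(img, canny_sigma=1.5)
        cols = np.nonzero(edges.any(axis=0))[0]
        assert cols.size > 0
        assert np.all(np.abs(cols - 31.5) <= 1.5)

    def test_disk_boundary_closes(self):
        from scipy import ndimage as ndi
        from skimage.draw import disk

        img = np.full((96, 96), 200.0)
        rr, cc = disk((48, 48), 15)
        img[rr, cc] = 60.0
        edges = edge_filter(img, canny_sigma=1.5)
        filled = ndi.binary_fill_holes(edges)
        assert filled.sum() > edges.sum() + 300  # interior captured

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            edge_filter(np.zeros((10, 10)), canny_lo=0.5, canny_hi=0.2)


def mask_of(binary):
    from skimage import measure

    binary = np.asarray(binary, dtype=bool)
    return SegmentationMask(binary=binary,
                            labels=measure.label(binary, connectivity=2))


class TestCombineAndFilter:
    def test_enumerated_areas(self):
        """Component areas {30, 50, 500, 1000, 1200} -> survivors
        {50, 500, 1000} (bounds inclusive)."""
        binary = np.zeros((200, 300), dtype=bool)
        specs = [(30, 0), (50, 40), (500, 80), (1000, 140), (1200, 220)]
        for area, col in specs:
            rows = area // 10
            binary[10:10 + rows, col:col + 10] = True
        out = combine_and_filter(mask_of(binary))
        areas = sorted(np.bincount(out.labels.ravel())[1:])
        assert areas == [50, 500, 1000]

    def test_empty_mask(self):
        out = combine_and_filter(mask_of(np.zeros((20, 20), dtype=bool)))
        assert not out.binary.any()

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        binary = rng.random((100, 100)) > 0.6
        once = combine_and_filter(mask_of(binary))
        twice = combine_and_filter(once)
        assert np.array_equal(once.binary, twice.binary)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            combine_and_filter(mask_of(np.zeros((10, 10), dtype=bool)),
                               edges=np.zeros((5, 5), dtype=bool))

    def test_total_area_non_increasing_without_edges(self):
        rng = np.random.default_rng(10)
        binary = rng.random((100, 100)) > 0.5
        out = combine_and_filter(mask_of(binary))
        assert out.binary.sum() <= binary.sum()

    def test_edge_interiors_fill_leaky_pores(self):
        """A pore missed by the score mask but ringed by closed edges is
        recovered through the edge filter."""
        from skimage.draw import circle_perimeter

        edges = np.zeros((64, 64), dtype=bool)
        rr, cc = circle_perimeter(32, 32, 8)
        edges[rr, cc] = True
        out = combine_and_filter(mask_of(np.zeros((64, 64), dtype=bool)),
                                 edges=edges)
        assert out.binary.sum() >= 150  # filled disk of radius ~8


class TestPoreProperties:
    def test_disk_properties(self):
        from skimage.draw import disk

        binary = np.zeros((64, 64), dtype=bool)
        rr, cc = disk((32, 32), 10)
        binary[rr, cc] = True
        table = pore_properties(mask_of(binary), px_size_um=1.0)
        assert len(table) == 1
        assert table["area_px"].iloc[0] == pytest.approx(np.pi * 100, rel=0.05)
        assert table["eq_diameter_um"].iloc[0] == pytest.approx(20.0, rel=0.05)

    def test_empty_mask_empty_table(self):
        table = pore_properties(mask_of(np.zeros((8, 8), dtype=bool)), 1.0)
        assert len(table) == 0

    def test_two_squares(self):
        binary = np.zeros((30, 30), dtype=bool)
        binary[2:10, 2:10] = True
        binary[15:23, 15:23] = True
        table = pore_properties(mask_of(binary), px_size_um=1.0)
        assert len(table) == 2
        assert np.allclose(table["area_px"], 64)
        assert np.allclose(table["eq_diameter_um"], np.sqrt(256 / np.pi),
                           rtol=1e-6)
        assert table["eq_diameter_um"].iloc[0] == pytest.approx(9.027, abs=0.01)


class TestPorePercentiles:
    def test_sort_based_oracle_1_to_100(self):
        table = pd.DataFrame({"eq_diameter_um": np.arange(1.0, 101.0)})
        q1, q3 = pore_percentiles(table)
        assert q1 == pytest.approx(25.75)
        assert q3 == pytest.approx(75.25)

    def test_all_equal(self):
        table = pd.DataFrame({"eq_diameter_um": [4.0] * 10})
        assert pore_percentiles(table) == (4.0, 4.0)

    def test_duplication_invariance(self):
        d = np.array([1.0, 3.0, 9.0, 12.0, 20.0])
        t1 = pd.DataFrame({"eq_diameter_um": d})
        t2 = pd.DataFrame({"eq_diameter_um": np.repeat(d, 2)})
        assert pore_percentiles(t1) == pore_percentiles(t2)

    def test_too_few_pores(self):
        with pytest.raises(ValueError):
            pore_percentiles(pd.DataFrame({"eq_diameter_um": [1.0, 2.0]}))


class TestEndToEnd:
    def test_recovered_areas_within_bounds(self, sem_suite):
        rec = sem_suite["recovered"]
        assert (rec["area_px"] >= 50).all()
        assert (rec["area_px"] <= 1000).all()

    def test_quartile_recovery(self, sem_suite):
        """Q1/Q3 of recovered equivalent diameters within 15 % of the
        ground truth restricted to the dimensional-filter range."""
        from cryofront.quantiles import quartiles

        truth = sem_suite["truth"]
        in_range = truth[(truth.area_px >= 50) & (truth.area_px <= 1000)]
        q1t, q3t = quartiles(in_range["eq_diameter_um"])
        q1r, q3r = quartiles(sem_suite["recovered"]["eq_diameter_um"])
        assert abs(q1r - q1t) / q1t < 0.15
        assert abs(q3r - q3t) / q3t < 0.15

    def test_pore_count_recovery(self, sem_suite):
        truth = sem_suite["truth"]
        n_in_range = ((truth.area_px >= 50) & (truth.area_px <= 1000)).sum()
        n_rec = len(sem_suite["recovered"])
        assert abs(n_rec - n_in_range) / n_in_range < 0.20

    def test_intensity_shift_invariance(self):
        spec = cf.PoreSpec(n_pores=60, seed=11, porosity_target=0.2,
                           diameter_scale_um=150.0)
        image, _ = cf.generate_sem_image(spec, image_shape=(256, 256))
        _, t1 = segment_pores(image, score_threshold=0.85)
        shifted = SEMImage(intensity=image.intensity + 17.0,
                           px_size_um=image.px_size_um,
                           cake_level=image.cake_level,
                           sample_id=image.sample_id)
        _, t2 = segment_pores(shifted, score_threshold=0.85)
        assert len(t1) > 5
        assert t1["area_px"].tolist() == t2["area_px"].tolist()
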