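"""The printed adhesion-counting operator chain and related measurements."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from phaseq import synthetic
from phaseq.adhesions import (
    adhesion_partition_coefficient,
    clahe,
    count_adhesions,
    count_particles,
    enhance_contrast,
    exp_transform,
    gate_cells_by_gfp,
    intermeans_threshold,
    log_filter,
    rolling_ball_background,
    threshold_default_dark,
    total_adhesion_area,
)
from phaseq.core_io import ImageStack
from phaseq.errors import ParameterError

from _oracles import brute_force_intermeans


class TestRollingBall:
    def test_constant_image_removed(self):
        out = rolling_ball_background(np.full((120, 120), 180.0))
        assert np.abs(out).max() < 1.0

    def test_puncta_on_ramp_preserved(self, rng):
        yy, xx = np.mgrid[0:160, 0:160]
        ramp = 40.0 + 60.0 * xx / 159.0
        img = ramp.copy()
        centres = [(40, 40), (80, 120), (120, 60)]
        for cy, cx in centres:
            blob = 100.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.0**2))
            img += blob
        out = rolling_ball_background(img, radius_px=50)
        assert out.min() >= 0.0
        for cy, cx in centres:
            assert out[cy, cx] == pytest.approx(100.0, rel=0.10)
        # ramp removed away from puncta
        assert out[10, 10] < 10.0 and out[150, 150] < 10.0

    def test_radius_exceeding_image_rejected(self):
        with pytest.raises(ParameterError):
            rolling_ball_background(np.zeros((30, 30)), radius_px=50)


class TestClahe:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 50.0)
        np.testing.assert_array_equal(clahe(img), img)

    def test_local_contrast_amplified_toward_equalization(self):
        # dim punctum in a dim region vs bright punctum in a bright region:
        # CLAHE amplifies the dim punctum's local contrast preferentially,
        # pushing the contrast ratio toward 1 (full equalization is capped
        # by the clipped-histogram excess redistribution at slope 6)
        yy, xx = np.mgrid[0:128, 0:128]
        img = np.where(xx < 64, 40.0, 160.0)
        img += np.where(
            (yy - 32) ** 2 + (xx - 32) ** 2 < 9, 20.0, 0.0
        )  # dim blob, dim side
        img += np.where(
            (yy - 96) ** 2 + (xx - 96) ** 2 < 9, 80.0, 0.0
        )  # bright blob, bright side
        out = clahe(img, blocksize=19)
        c_dim = out[32, 32] - np.median(out[20:44, 10:24])
        c_bright = out[96, 96] - np.median(out[84:108, 110:124])
        assert c_dim > 0 and c_bright > 0
        assert c_dim / 20.0 > 1.3  # dim contrast amplified
        assert (c_dim / c_bright) > 20.0 / 80.0  # ratio moved toward 1

    def test_output_within_working_range(self, rng):
        img = rng.uniform(0, 900, size=(64, 64))
        out = clahe(img)
        assert out.min() >= 0.0 and out.max() <= 900.0 + 1e-9

    def test_blocksize_validation(self):
        with pytest.raises(ParameterError):
            clahe(np.zeros((32, 32)), blocksize=2)


class TestExpTransform:
    def test_endpoints_preserved(self):
        img = np.array([[0.0, 255.0]])
        out = exp_transform(img, display_max=255.0)
        assert out[0, 0] == pytest.approx(0.0)
        assert out[0, 1] == pytest.approx(255.0)

    def test_strictly_increasing(self):
        v = np.linspace(0, 255, 100).reshape(1, -1)
        out = exp_transform(v, display_max=255.0)
        assert np.all(np.diff(out[0]) > 0)

    def test_midpoint_compressed_below_half(self):
        out = exp_transform(np.array([[127.5]]), display_max=255.0)
        assert out[0, 0] < 127.5 / 2  # curvature >= ln(2)*8 compresses >= 4x


class TestEnhanceContrast:
    def test_affine_on_ramp(self):
        ramp = np.linspace(10, 20, 10_000).reshape(100, 100)
        out = enhance_contrast(ramp, saturated_percent=0.35, out_max=255.0)
        inner = out[out > 0]
        diffs = np.diff(np.sort(inner.ravel()))
        assert np.allclose(diffs[diffs > 0], diffs[diffs > 0][0], rtol=1e-6)

    def test_saturated_fraction_matches_order_statistics(self, rng):
        img = rng.uniform(0, 1000, size=(200, 200))
        out = enhance_contrast(img, saturated_percent=0.35, out_max=255.0)
        n = img.size
        saturated = (out == 0).sum() + (out == 255.0).sum()
        assert saturated == pytest.approx(n * 0.0035, rel=0.15)

    def test_constant_image_logged_not_stretched(self):
        img = np.full((16, 16), 9.0)
        np.testing.assert_array_equal(enhance_contrast(img), img)


class TestLogFilter:
    def test_matched_blob_peaks_at_centre(self):
        yy, xx = np.mgrid[0:64, 0:64]
        blob = 100.0 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 2.0**2))
        out = log_filter(blob, sigma=2.0)
        assert np.unravel_index(np.argmax(out), out.shape) == (32, 32)

    def test_constant_image_zero_response(self):
        out = log_filter(np.full((32, 32), 80.0))
        assert np.all(out == 0.0)

    def test_scale_selectivity_sigma2_over_sigma8(self):
        yy, xx = np.mgrid[0:128, 0:128]
        small = 100.0 * np.exp(-((yy - 40) ** 2 + (xx - 40) ** 2) / (2 * 2.0**2))
        large = 100.0 * np.exp(-((yy - 90) ** 2 + (xx - 90) ** 2) / (2 * 8.0**2))
        resp = -ndimage.gaussian_laplace(small + large, sigma=2.0)
        assert resp[40, 40] > resp[90, 90]


class TestDefaultDarkThreshold:
    def test_bimodal_threshold_between_modes(self, rng):
        vals = np.concatenate(
            [rng.normal(50, 5, 5000), rng.normal(200, 5, 5000)]
        ).clip(0, 255).astype(np.uint8)
        img = vals.reshape(100, 100)
        mask = threshold_default_dark(img)
        assert mask.sum() == pytest.approx(5000, rel=0.02)
        assert img[mask].min() > 100

    def test_blank_image_empty_mask(self):
        assert not threshold_default_dark(np.full((16, 16), 3.0)).any()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_intermeans_scan(self, seed):
        rng = np.random.default_rng(seed)
        hist = rng.integers(0, 1000, size=256)
        hist[rng.integers(0, 256, size=50)] = 0
        if hist.sum() == 0:
            hist[128] = 1
        assert intermeans_threshold(hist) == brute_force_intermeans(hist)


class TestCountParticles:
    def test_empty_mask(self):
        count, table = count_particles(np.zeros((32, 32), bool))
        assert count == 0 and len(table) == 0

    def test_fifty_disjoint_objects(self):
        mask = np.zeros((200, 250), bool)
        for i in range(50):
            y, x = 10 + 20 * (i // 10), 10 + 24 * (i % 10)
            mask[y : y + 4, x : x + 5] = True  # area 20
        count, table = count_particles(mask)
        assert count == 50
        assert (table.area_px2 == 20).all()

    def test_area_filter_excludes_out_of_range(self):
        mask = np.zeros((100, 100), bool)
        mask[10:50, 10:40] = True  # 1200 px^2: above the cap
        mask[70:72, 70:72] = True  # 4 px^2: below the floor
        mask[80:85, 80:85] = True  # 25 px^2: kept
        count, table = count_particles(mask)
        assert count == 1
        assert table.area_px2.iloc[0] == 25

    def test_circularity_clipped_to_one(self):
        mask = np.zeros((20, 20), bool)
        mask[5:8, 5:8] = True
        _, table = count_particles(mask)
        assert 0 < table.circularity.iloc[0] <= 1.0

    def test_monotone_adding_punctum_never_decreases(self):
        mask = np.zeros((60, 60), bool)
        mask[10:14, 10:14] = True
        c1, _ = count_particles(mask)
        mask[40:44, 40:44] = True
        c2, _ = count_particles(mask)
        assert c2 >= c1


class TestFullChain:
    def test_eighty_puncta_counted_within_5pct(self):
        img, truth = synthetic.make_adhesion_image(
            80, cell_mask=synthetic.default_cell_mask((420, 420)),
            noise_sd=300.0, seed=11,
        )
        count, records = count_adhesions(img)
        assert count == pytest.approx(80, rel=0.05)
        assert records.area_px2.between(5, 1000).all()

    def test_count_invariant_under_2x_gain(self):
        img, _ = synthetic.make_adhesion_image(
            60, cell_mask=synthetic.default_cell_mask((420, 420)),
            noise_sd=300.0, seed=13,
        )
        c1, _ = count_adhesions(img)
        c2, _ = count_adhesions(ImageStack(img.pixels * 2.0))
        assert c1 == c2

    def test_blank_field_counts_zero(self):
        assert count_adhesions(np.zeros((128, 128)))[0] == 0
        assert count_adhesions(np.full((128, 128), 77.0))[0] == 0


class TestTotalAdhesionArea:
    def test_all_below_threshold_zero(self):
        assert total_adhesion_area(np.full((64, 64), 5000.0)) == 0.0

    def test_pixel_area_arithmetic(self):
        img = np.full((100, 100), 100.0)
        img.ravel()[:1000] = 6000.0
        # 1000 pixels at 0.1 um/px -> 10 um^2
        assert total_adhesion_area(img, pixel_size_um=0.1) == pytest.approx(10.0)

    def test_synthetic_adhesions_area_recovered(self):
        img, truth = synthetic.make_adhesion_image(
            30, adhesion_level=8000.0, cytoplasm_level=3000.0,
            noise_sd=100.0, seed=7,
        )
        area = total_adhesion_area(img.pixels, 5500.0, 65535.0)
        true_area = sum(r["area_px2_drawn"] for r in truth.parameters["adhesions"])
        assert area == pytest.approx(true_area, rel=0.25)  # rim tolerance

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ParameterError):
            total_adhesion_area(np.zeros((8, 8)), lower=100.0, upper=50.0)

    def test_monotone_in_suprathreshold_pixels(self):
        img = np.full((64, 64), 100.0)
        img[0, :10] = 6000.0
        a1 = total_adhesion_area(img)
        img[1, :10] = 6000.0
        assert total_adhesion_area(img) >= a1


class TestAdhesionPartition:
    def test_threefold_adhesions_recovered(self):
        img, truth = synthetic.make_adhesion_image(
            40, cell_mask=synthetic.default_cell_mask((420, 420)),
            area_range_px2=(100.0, 300.0), adhesion_level=9000.0,
            cytoplasm_level=3000.0, background_level=300.0,
            noise_sd=300.0, seed=5,
        )
        pc = adhesion_partition_coefficient(img, background=300.0)
        assert pc == pytest.approx(truth.parameters["true_ratio"], rel=0.10)

    def test_uniform_cell_pc_near_one(self, rng):
        img = np.clip(rng.normal(3000.0, 50.0, size=(128, 128)), 0, None)
        pc = adhesion_partition_coefficient(img, background=0.0)
        assert pc == pytest.approx(1.0, abs=0.1)

    def test_invariant_under_gain_and_matched_offset(self):
        img, _ = synthetic.make_adhesion_image(
            40, cell_mask=synthetic.default_cell_mask((420, 420)),
            area_range_px2=(100.0, 300.0), noise_sd=300.0, seed=5,
        )
        pc = adhesion_partition_coefficient(img, background=300.0)
        pc_gain = adhesion_partition_coefficient(img.pixels * 4.0, background=1200.0)
        pc_offset = adhesion_partition_coefficient(img.pixels + 700.0, background=1000.0)
        assert pc_gain == pytest.approx(pc, rel=0.01)
        assert pc_offset == pytest.approx(pc, rel=0.01)


class TestGfpGating:
    def _cells(self, means):
        return pd.DataFrame({"cell_id": range(len(means)), "gfp_mean": means})

    @pytest.mark.parametrize(
        "gfp,included",
        [(999.0, False), (1000.0, True), (5000.0, True), (5001.0, False)],
    )
    def test_inclusive_boundaries(self, gfp, included):
        gated, _ = gate_cells_by_gfp(self._cells([gfp]))
        assert (len(gated) == 1) is included

    def test_retention_fraction(self, rng):
        means = np.concatenate(
            [rng.uniform(1000, 5000, 60), rng.uniform(6000, 9000, 40)]
        )
        gated, retention = gate_cells_by_gfp(self._cells(means))
        assert len(gated) == 60
        assert retention == pytest.approx(0.6)
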