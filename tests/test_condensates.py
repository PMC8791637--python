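"""Droplet segmentation, partition coefficients, densities, enrichment."""

import numpy as np
import pandas as pd
import pytest

from phaseq import condensates, psf, synthetic
from phaseq.condensates import (
    bulk_mean,
    cluster_density,
    correct_illumination,
    droplet_regions,
    enrichment_in_clusters,
    flatfield_from_dye,
    partition_coefficients,
    segment_droplets,
    summarize_partition,
)
from phaseq.core_io import ImageStack
from phaseq.errors import (
    BulkRegionError,
    CalibrationError,
    ConfigurationError,
    DimensionError,
    ParameterError,
)
from phaseq.synthetic import DropletSpec


class TestFlatfield:
    def test_field_maximum_is_exactly_one(self):
        dye, dark, _ = synthetic.make_flatfield_pair("uniform", noise_sd=3.0, seed=1)
        field = flatfield_from_dye(dye, dark)
        assert field.max() == 1.0
        assert field.min() > 0

    def test_no_signal_is_calibration_error(self):
        with pytest.raises(CalibrationError):
            flatfield_from_dye(np.full((8, 8), 5.0), np.full((8, 8), 10.0))

    def test_shading_round_trip_flattens_image(self):
        yy, xx = np.mgrid[0:64, 0:64]
        ramp = 0.5 + 0.5 * xx / 63
        dye, dark, _ = synthetic.make_flatfield_pair(ramp, noise_sd=0.0)
        field = flatfield_from_dye(dye, dark)
        shaded = ImageStack(200.0 * ramp)
        flat = correct_illumination(shaded, field)
        assert flat.pixels.std() / flat.pixels.mean() < 1e-9

    def test_identity_field_leaves_image_unchanged(self):
        img = ImageStack(np.arange(64.0).reshape(8, 8))
        out = correct_illumination(img, np.ones((8, 8)))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_correction_is_not_idempotent(self):
        img = ImageStack(np.full((8, 8), 100.0))
        field = np.full((8, 8), 0.5)
        once = correct_illumination(img, field)
        twice = correct_illumination(once, field)
        assert np.all(twice.pixels == 4 * img.pixels)

    def test_zero_field_guarded(self):
        with pytest.raises(ParameterError):
            correct_illumination(ImageStack(np.ones((4, 4))), np.zeros((4, 4)))


class TestSegmentation:
    def test_blank_image_empty_mask(self):
        labels = segment_droplets(np.full((32, 32), 7.0))
        assert labels.max() == 0

    def test_ten_disjoint_discs_found_with_centroids(self):
        specs = [
            DropletSpec((40.0 + 80 * (i // 5), 40.0 + 85 * (i % 5)), 16.0, {"647": 300.0})
            for i in range(10)
        ]
        images, truth = synthetic.make_droplet_image(
            specs, {"647": 100.0}, psf_fwhm=2.0, seed=3, shape=(200, 440)
        )
        labels = segment_droplets(images["647"])
        regions = droplet_regions(labels)
        assert len(regions) == 10
        true_centres = np.array([s.center_yx for s in specs])
        got = regions[["centroid_y", "centroid_x"]].to_numpy()
        # labels are sorted by centroid (y, x), matching construction order
        np.testing.assert_allclose(got, true_centres, atol=1.0)

    def test_label_order_stable_by_centroid(self):
        img = np.zeros((40, 40))
        img[30:34, 2:6] = 10  # lower-left
        img[2:6, 30:34] = 10  # upper-right
        labels = segment_droplets(img)
        regions = droplet_regions(labels)
        assert regions.loc[0, "centroid_y"] < regions.loc[1, "centroid_y"]


class TestBulkMean:
    def test_no_droplets_gives_global_mean(self):
        img = np.arange(100.0).reshape(10, 10)
        assert bulk_mean(np.zeros((10, 10), int), img) == pytest.approx(img.mean())

    def test_recovers_generator_bulk_level(self, droplet_field):
        images, truth, _ = droplet_field
        labels = segment_droplets(images["647"])
        offset = truth.parameters["background_offset"]
        value = bulk_mean(labels, images["647"].pixels - offset, 5)
        assert value == pytest.approx(100.0, rel=0.02)

    def test_bulk_independent_of_interior_level(self):
        vals = []
        for level in (200.0, 400.0, 800.0):
            images, _ = synthetic.make_droplet_image(
                [DropletSpec((40.0, 40.0), 16.0, {"647": level})],
                {"647": 100.0},
                psf_fwhm=3.0,
                seed=2,
                shape=(96, 96),
            )
            labels = segment_droplets(images["647"])
            vals.append(bulk_mean(labels, images["647"], dilation_radius_px=8))
        assert max(vals) - min(vals) < 1.0

    def test_dilation_covering_field_raises(self):
        labels = np.ones((20, 20), int)
        with pytest.raises(BulkRegionError):
            bulk_mean(labels, np.ones((20, 20)), 5)


class TestPartitionCoefficients:
    def test_three_channel_recovery_within_10pct(self, droplet_field):
        images, truth, true_pc = droplet_field
        offset = truth.parameters["background_offset"]
        channels = {ch: img.pixels - offset for ch, img in images.items()}
        labels = segment_droplets(channels["647"])
        curve = psf.build_correction_curve(psf.gaussian_psf(4.0))
        bulk = {ch: bulk_mean(labels, channels[ch], 5) for ch in channels}
        records = partition_coefficients(
            labels, channels, bulk, curves={ch: curve for ch in channels}
        )
        summary = summarize_partition(records)
        for _, row in summary.iterrows():
            assert row["pc_mean"] == pytest.approx(true_pc[row["channel"]], rel=0.10)

    def test_sub12px_droplet_discarded_but_listed(self):
        specs = [
            DropletSpec((30.0, 30.0), 8.0, {"647": 300.0}),
            DropletSpec((30.0, 90.0), 20.0, {"647": 300.0}),
        ]
        images, _ = synthetic.make_droplet_image(
            specs, {"647": 100.0}, psf_fwhm=0.0, seed=1, shape=(120, 120)
        )
        labels = segment_droplets(images["647"])
        records = partition_coefficients(
            labels, {"647": images["647"]}, {"647": 100.0}, apply_correction=False
        )
        assert len(records) == 2
        small = records[records.diameter_px < 12]
        assert len(small) == 1 and bool(small.discarded.iloc[0])
        summary = summarize_partition(records)
        assert summary.loc[0, "n"] == 1

    def test_uniform_image_spurious_components_have_pc_one(self, rng):
        img = rng.normal(100.0, 1.0, size=(64, 64))
        labels = segment_droplets(img)
        if labels.max() == 0:
            pytest.skip("no spurious components segmented")
        records = partition_coefficients(
            labels,
            {"647": img},
            {"647": bulk_mean(labels, img, 0)},
            apply_correction=False,
            min_diameter_px=0.0,
        )
        assert records["pc_647"].mean() == pytest.approx(1.0, abs=0.05)

    def test_missing_curve_when_correction_fires_is_config_error(self):
        specs = [
            DropletSpec((30.0 + 60 * i, 30.0 + 60 * j), 13.0 + 3 * (2 * i + j), {"647": 300.0})
            for i in range(2)
            for j in range(2)
        ]
        images, _ = synthetic.make_droplet_image(
            specs, {"647": 100.0}, psf_fwhm=4.0, seed=5, shape=(160, 160)
        )
        labels = segment_droplets(images["647"])
        with pytest.raises(ConfigurationError):
            partition_coefficients(
                labels,
                {"647": images["647"]},
                {"647": 100.0},
                curves=None,
                trend_pretest=False,
            )

    def test_nonpositive_bulk_rejected(self):
        with pytest.raises(ParameterError):
            partition_coefficients(
                np.zeros((8, 8), int), {"647": np.ones((8, 8))}, {"647": 0.0}
            )

    def test_pc_invariant_under_global_gain(self, droplet_field):
        images, truth, _ = droplet_field
        offset = truth.parameters["background_offset"]
        channels = {"647": images["647"].pixels - offset}
        labels = segment_droplets(channels["647"])
        rec1 = partition_coefficients(
            labels, channels, {"647": bulk_mean(labels, channels["647"], 5)},
            apply_correction=False,
        )
        scaled = {"647": channels["647"] * 3.7}
        rec2 = partition_coefficients(
            labels, scaled, {"647": bulk_mean(labels, scaled["647"], 5)},
            apply_correction=False,
        )
        np.testing.assert_allclose(rec1["pc_647"], rec2["pc_647"], rtol=1e-9)


class TestClusterDensity:
    def test_density_arithmetic(self):
        # 25 clusters on a 0.05 mm x 0.05 mm field -> 10,000 per mm^2
        specs = [
            DropletSpec((50.0 + 90 * (i // 5), 50.0 + 90 * (i % 5)), 14.0, {"647": 300.0})
            for i in range(25)
        ]
        images, _ = synthetic.make_droplet_image(
            specs, {"647": 100.0}, psf_fwhm=2.0, seed=2, shape=(500, 500),
            pixel_size_um=0.1,
        )
        table = cluster_density([images["647"]], surface="lipids+integrin")
        assert table.loc[0, "field_area_mm2"] == pytest.approx(0.0025)
        assert table.loc[0, "cluster_count"] == 25
        assert table.loc[0, "density_per_mm2"] == pytest.approx(10_000.0)

    def test_empty_field_zero_density(self):
        img = ImageStack(np.full((100, 100), 50.0), pixel_size_um=0.1)
        table = cluster_density([img], surface="PEG")
        assert table.loc[0, "density_per_mm2"] == 0.0

    def test_half_fields_average_to_full_density(self):
        specs = [
            DropletSpec((50.0 + 90 * (i // 5), 50.0 + 90 * (i % 5)), 14.0, {"647": 300.0})
            for i in range(25)
        ]
        images, _ = synthetic.make_droplet_image(
            specs, {"647": 100.0}, psf_fwhm=2.0, seed=2, shape=(500, 500),
            pixel_size_um=0.1,
        )
        full = cluster_density([images["647"]], surface="x").loc[0]
        left = ImageStack(images["647"].pixels[:, :250], pixel_size_um=0.1)
        right = ImageStack(images["647"].pixels[:, 250:], pixel_size_um=0.1)
        halves = cluster_density([left, right], surface="x")
        avg = halves["density_per_mm2"].mean()
        assert avg == pytest.approx(full["density_per_mm2"], rel=0.01)


class TestEnrichment:
    def test_uniform_image_fold_one(self):
        img = np.full((64, 64), 50.0)
        mask = np.zeros((64, 64), int)
        mask[10:20, 10:20] = 1
        table = enrichment_in_clusters(img, mask, dilation_radius_px=3)
        assert table.loc[0, "fold_enrichment"] == pytest.approx(1.0)

    def test_twofold_clusters_recovered(self):
        # clusters at twice the membrane level: mean fold ~ 2
        specs = [
            DropletSpec((40.0 + 80 * (i // 3), 40.0 + 80 * (i % 3)), 16.0, {"488": 200.0})
            for i in range(9)
        ]
        images, _ = synthetic.make_droplet_image(
            specs, {"488": 100.0}, psf_fwhm=2.0, noise_sd=2.0, seed=7, shape=(260, 260)
        )
        labels = segment_droplets(images["488"])
        table = enrichment_in_clusters(images["488"], labels, dilation_radius_px=6)
        assert table["fold_enrichment"].mean() == pytest.approx(2.0, rel=0.10)

    def test_enrichment_invariant_under_gain(self):
        img = np.full((64, 64), 50.0)
        img[10:20, 10:20] = 150.0
        mask = np.zeros((64, 64), int)
        mask[10:20, 10:20] = 1
        t1 = enrichment_in_clusters(img, mask, 3)
        t2 = enrichment_in_clusters(img * 11.0, mask, 3)
        assert t1.loc[0, "fold_enrichment"] == pytest.approx(
            t2.loc[0, "fold_enrichment"], rel=1e-12
        )

    def test_empty_unclustered_region_raises(self):
        mask = np.ones((20, 20), int)
        with pytest.raises(BulkRegionError):
            enrichment_in_clusters(np.ones((20, 20)), mask, 2)
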