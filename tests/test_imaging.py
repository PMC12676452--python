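"""Tests for preprocessing, segmentation, morphometrics, and QC filtering."""

import numpy as np
import pytest
from skimage import draw as skdraw

import photoloc as pl
from photoloc.imaging import Roi, _polygon_moments


def regular_polygon(n, radius=10.0, center=(50.0, 50.0)):
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])


def roi_with_metrics(**fields):
    """QC-ready ROI with all metric fields set to passing defaults."""
    base = dict(circularity=0.9, aspect_ratio=1.2, solidity=0.95,
                area_px=300.0, median_interior=120.0, mean_interior=120.0,
                median_background=5.0, mean_background=5.0, channel="gfp")
    base.update(fields)
    roi = Roi(polygon=[(0, 0), (10, 0), (10, 10), (0, 10)],
              channel=base.pop("channel"))
    for k, v in base.items():
        setattr(roi, k, v)
    return roi


class TestCalibratePixelSize:
    def test_identity_when_already_calibrated(self):
        img = np.random.default_rng(0).integers(0, 255, (50, 50)).astype(np.uint8)
        out = pl.calibrate_pixel_size(img, 0.3785)
        np.testing.assert_array_equal(out, img)

    def test_upsampling_dimensions(self):
        img = np.zeros((100, 100))
        out = pl.calibrate_pixel_size(img, native_um_per_px=0.757)
        assert abs(out.shape[0] - 200) <= 1 and abs(out.shape[1] - 200) <= 1

    def test_total_intensity_preserved_under_area_weighting(self):
        yy, xx = np.mgrid[0:100, 0:100]
        img = 100 * np.exp(-((yy - 50) ** 2 + (xx - 50) ** 2) / 400.0)
        out = pl.calibrate_pixel_size(img, native_um_per_px=0.757)
        scale = (out.shape[0] * out.shape[1]) / (100 * 100)
        assert out.sum() == pytest.approx(img.sum() * scale, rel=0.01)

    def test_unknown_calibration_rejected(self):
        with pytest.raises(ValueError):
            pl.calibrate_pixel_size(np.zeros((10, 10)), 0.0)


class TestTophat:
    def test_constant_image_maps_to_zero(self):
        out = pl.tophat(np.full((40, 40), 77.0))
        np.testing.assert_allclose(out, 0.0)

    def test_small_disc_preserved_exactly(self):
        img = np.zeros((60, 60))
        rr, cc = skdraw.disk((30, 30), 5)
        img[rr, cc] = 200.0
        out = pl.tophat(img, disc_radius_px=10)
        # opening with a larger disc removes the object entirely
        np.testing.assert_allclose(out[rr, cc], 200.0)

    def test_broad_hill_suppressed(self):
        yy, xx = np.mgrid[0:200, 0:200]
        img = 100 * np.exp(-((yy - 100) ** 2 + (xx - 100) ** 2) / (2 * 100.0**2))
        out = pl.tophat(img, disc_radius_px=10)
        assert out.max() < 10.0

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            pl.tophat(np.zeros((5, 5)), disc_radius_px=0)


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((20, 20), 9.0)
        np.testing.assert_array_equal(pl.median_filter(img), img)

    def test_hot_pixel_removed(self):
        img = np.zeros((21, 21))
        img[10, 10] = 255.0
        np.testing.assert_array_equal(pl.median_filter(img), np.zeros((21, 21)))

    def test_step_edge_location_preserved(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 100.0
        out = pl.median_filter(img)
        np.testing.assert_array_equal(out, img)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            pl.median_filter(np.zeros((5, 5)), kernel_px=4)


class TestSegment:
    def test_well_separated_discs_all_found(self):
        img = np.full((300, 300), 5, dtype=np.uint8)
        rng = np.random.default_rng(1)
        centers = [(r, c) for r in range(30, 300, 60) for c in range(30, 300, 60)][:20]
        for r, c in centers:
            rr, cc = skdraw.disk((r, c), 8, shape=img.shape)
            img[rr, cc] = 200
        rois = pl.segment(img, pl.SegmenterSpec(threshold=50))
        assert len(rois) == 20

    def test_blank_image_gives_empty_list(self):
        assert pl.segment(np.zeros((50, 50), dtype=np.uint8)) == []

    def test_touching_discs_may_merge(self):
        img = np.zeros((60, 90), dtype=np.uint8)
        for c in (30, 46):  # overlapping discs
            rr, cc = skdraw.disk((30, c), 9, shape=img.shape)
            img[rr, cc] = 200
        rois = pl.segment(img, pl.SegmenterSpec(threshold=50))
        assert len(rois) in (1, 2)

    def test_external_backend_unavailable_points_to_builtin(self):
        with pytest.raises(RuntimeError, match="builtin"):
            pl.segment(np.zeros((10, 10)),
                       pl.SegmenterSpec(backend="external_adapter"))


class TestMorphometrics:
    def test_unit_square(self):
        roi = Roi(polygon=[(0, 0), (1, 0), (1, 1), (0, 1)], channel="gfp")
        pl.compute_morphometrics(roi)
        assert roi.area_px == pytest.approx(1.0)
        assert roi.circularity == pytest.approx(np.pi / 4, rel=1e-9)
        assert roi.solidity == pytest.approx(1.0, rel=1e-9)
        assert roi.aspect_ratio == pytest.approx(1.0, rel=1e-9)

    def test_regular_64gon_nearly_circular(self):
        roi = Roi(polygon=regular_polygon(64), channel="gfp")
        pl.compute_morphometrics(roi)
        assert roi.circularity > 0.99
        # closed-form check: circularity of a regular n-gon is (pi/n)/tan(pi/n)
        n = 64
        assert roi.circularity == pytest.approx((np.pi / n) / np.tan(np.pi / n),
                                                rel=1e-9)

    def test_elongated_rectangle(self):
        roi = Roi(polygon=[(0, 0), (10, 0), (10, 1), (0, 1)], channel="fos")
        pl.compute_morphometrics(roi)
        assert roi.circularity == pytest.approx(40 * np.pi / 484, rel=1e-9)
        assert roi.aspect_ratio == pytest.approx(10.0, rel=0.05)

    def test_degenerate_polygon_rejected(self):
        roi = Roi(polygon=[(0, 0), (1, 1), (2, 2)], channel="gfp")
        with pytest.raises(ValueError):
            pl.compute_morphometrics(roi)

    def test_regular_ngon_moment_oracle(self):
        # shoelace area matches the closed form n/2 r^2 sin(2pi/n)
        for n in (5, 8, 12, 33):
            verts = regular_polygon(n, radius=7.0)
            a, _, _ = _polygon_moments(verts)
            assert abs(a) == pytest.approx(
                n / 2 * 49.0 * np.sin(2 * np.pi / n), rel=1e-9)

    def test_raster_and_shoelace_area_agree(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            radius = rng.uniform(6, 15)
            verts = regular_polygon(32, radius=radius, center=(40, 40))
            roi = Roi(polygon=verts, channel="gfp")
            pl.compute_morphometrics(roi)
            if roi.area_px < 80:
                continue
            mask = pl.imaging.rasterize_polygon(verts, (80, 80))
            assert mask.sum() == pytest.approx(roi.area_px, rel=0.05)


class TestMeasureIntensity:
    def test_uniform_image(self):
        roi = Roi(polygon=regular_polygon(32, 8, (20, 20)), channel="gfp")
        pl.measure_intensity(roi, np.full((40, 40), 100.0))
        assert roi.mean_interior == 100.0 == roi.median_interior
        assert roi.mean_background == 100.0

    def test_disc_on_dark_background(self):
        # polygon traces the painted disc boundary, as a segmenter would
        img = np.full((60, 60), 10.0)
        rr, cc = skdraw.disk((30, 30), 10)
        img[rr, cc] = 200.0
        roi = Roi(polygon=regular_polygon(64, 10.0, (30, 30)), channel="fos")
        pl.measure_intensity(roi, img)
        assert roi.mean_interior == pytest.approx(200.0, abs=5.0)
        assert roi.mean_background == pytest.approx(10.0, abs=5.0)
        assert roi.signal_above_background == pytest.approx(190.0, abs=10.0)

    def test_neighbor_interiors_excluded_from_background(self):
        # neighbor disc intrudes into the 3-px contour band of the first
        img = np.full((60, 90), 10.0)
        for c in (30, 49):
            rr, cc = skdraw.disk((30, c), 9, shape=img.shape)
            img[rr, cc] = 200.0
        a = Roi(polygon=regular_polygon(64, 9.3, (30, 30)), channel="fos")
        b = Roi(polygon=regular_polygon(64, 9.3, (49, 30)), channel="fos")
        pl.measure_intensity(a, img, all_rois=[a, b])
        with_exclusion = a.mean_background
        pl.measure_intensity(a, img, exclude_other_interiors=False)
        without_exclusion = a.mean_background
        assert with_exclusion == pytest.approx(10.0, abs=5.0)
        assert without_exclusion > with_exclusion


class TestQcFilters:
    def test_engineered_single_rule_rejections(self):
        """Each ROI violates exactly one printed rule; keep/reject matches."""
        rois = [
            roi_with_metrics(),  # passes everything
            roi_with_metrics(circularity=0.35),
            roi_with_metrics(aspect_ratio=3.5),
            roi_with_metrics(solidity=0.5),
            roi_with_metrics(area_px=50.0),
            roi_with_metrics(area_px=1500.0),
            roi_with_metrics(median_interior=8.0, mean_interior=8.0),
            roi_with_metrics(channel="fos", mean_interior=15.0,
                             median_interior=15.0, mean_background=12.0,
                             median_background=12.0),  # SAB 3 < 7.65
        ]
        kept, rejected = pl.apply_qc_filters(rois)
        assert kept == [rois[0]]
        assert [r.qc_reason for r in rejected] == [
            "circularity", "aspect_ratio", "solidity", "area_below_min",
            "area_above_max", "median_intensity", "signal_above_background",
        ]

    def test_bright_circle_kept(self):
        roi = Roi(polygon=regular_polygon(64, 10, (30, 30)), channel="fos")
        pl.compute_morphometrics(roi)
        img = np.full((60, 60), 5.0)
        rr, cc = skdraw.disk((30, 30), 11)
        img[rr, cc] = 200.0
        pl.measure_intensity(roi, img)
        kept, _ = pl.apply_qc_filters([roi])
        assert kept == [roi]

    def test_gfp_has_no_signal_above_background_rule(self):
        roi = roi_with_metrics(channel="gfp", mean_interior=15.0,
                               median_interior=15.0, mean_background=12.0)
        kept, _ = pl.apply_qc_filters([roi])
        assert kept == [roi]

    def test_unpopulated_metrics_rejected(self):
        roi = Roi(polygon=[(0, 0), (5, 0), (5, 5), (0, 5)], channel="gfp")
        with pytest.raises(ValueError, match="unpopulated"):
            pl.apply_qc_filters([roi])

    def test_relaxing_thresholds_is_monotone(self):
        rng = np.random.default_rng(5)
        rois = [
            roi_with_metrics(
                circularity=rng.uniform(0.2, 1.0),
                aspect_ratio=rng.uniform(1.0, 5.0),
                solidity=rng.uniform(0.3, 1.0),
                area_px=rng.uniform(20, 1500),
                median_interior=rng.uniform(0, 50),
                mean_interior=rng.uniform(0, 50),
                mean_background=rng.uniform(0, 20),
                channel=rng.choice(["fos", "gfp"]),
            )
            for _ in range(100)
        ]
        baseline = len(pl.apply_qc_filters(rois, pl.QCThresholds())[0])
        relaxed = [
            pl.QCThresholds(circularity_min=0.2),
            pl.QCThresholds(aspect_ratio_max=5.0),
            pl.QCThresholds(solidity_min=0.4),
            pl.QCThresholds(area_min_px=10),
            pl.QCThresholds(area_max_px=2000),
            pl.QCThresholds(median_intensity_min=5),
            pl.QCThresholds(fos_signal_above_bg_min=1.0),
        ]
        for thr in relaxed:
            assert len(pl.apply_qc_filters(rois, thr)[0]) >= baseline
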