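import numpy as np
import pytest
from scipy import ndimage, stats

from palmpipe import punctaquant as pq, simkit
from palmpipe.punctaquant import CellGeometry, EventPair, SegmentationParams


class TestSubtractBackground:
    def test_constant_image_zeroed(self):
        img = np.full((32, 32), 7.0)
        out = pq.subtract_background(img, (0, 4, 0, 4))
        assert np.all(out == 0.0)

    def test_background_pixels_near_zero(self, spot_field):
        img, labels = simkit.synth_puncta_image(spot_field)
        out = pq.subtract_background(img, (0, 8, 0, 8))
        bg = out[labels == 0]
        assert abs(np.median(bg)) < 1.0

    def test_idempotent_on_constants(self):
        img = np.full((16, 16), 3.0)
        once = pq.subtract_background(img, (0, 4, 0, 4))
        twice = pq.subtract_background(once, (0, 4, 0, 4))
        np.testing.assert_array_equal(once, twice)

    def test_negative_clipped(self):
        img = np.zeros((8, 8))
        img[0:2, 0:2] = 10.0  # rectangle mean > rest
        out = pq.subtract_background(img, (0, 2, 0, 2))
        assert (out >= 0).all()

    def test_rectangle_bounds_checked(self):
        with pytest.raises(pq.PunctaError):
            pq.subtract_background(np.zeros((8, 8)), (0, 10, 0, 4))

    def test_cell_overlap_warns(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[1, 1] = True
        with pytest.warns(UserWarning):
            pq.subtract_background(np.zeros((8, 8)), (0, 4, 0, 4), cell_mask=mask)


class TestSegmentation:
    def test_constant_image_empty_mask(self):
        mask = pq.segment_puncta(np.full((64, 64), 9.0), SegmentationParams())
        assert mask.max() == 0

    def test_planted_spots_recovered(self, spot_field):
        img, _ = simkit.synth_puncta_image(spot_field)
        mask = pq.segment_puncta(img, SegmentationParams())
        assert mask.max() == 20
        # centroids within 1 px of planted centers, one-to-one
        centroids = np.array(ndimage.center_of_mass(mask > 0, mask, range(1, 21)))
        used = set()
        for cy, cx in centroids:
            d = np.hypot(spot_field.centers[:, 0] - cy, spot_field.centers[:, 1] - cx)
            j = int(np.argmin(d))
            assert d[j] <= 1.0
            assert j not in used
            used.add(j)

    def test_single_pixel_impulses_removed_by_opening(self):
        rng = np.random.default_rng(0)
        img = np.zeros((64, 64))
        for r, c in rng.integers(5, 59, size=(10, 2)):
            img[r, c] = 1000.0
        mask = pq.segment_puncta(img, SegmentationParams())
        assert mask.max() == 0

    def test_zero_variance_filtered_image_empty(self):
        mask = pq.segment_puncta(np.zeros((32, 32)), SegmentationParams())
        assert mask.max() == 0

    def test_pipeline_order_matters(self, spot_field):
        # guard against silent reordering: thresholding before the LoG
        # filter produces a different mask on the same image
        img, _ = simkit.synth_puncta_image(spot_field)
        params = SegmentationParams()
        canonical = pq.segment_puncta(img, params)

        med = ndimage.median_filter(img, size=params.median_window, mode="reflect")
        hp = img - med
        thr = hp.mean() + params.threshold_k * hp.std()
        binary = hp > thr  # threshold first ...
        filtered = -ndimage.gaussian_laplace(binary.astype(float), params.log_sigma)
        permuted = ndimage.binary_opening(filtered > 0, structure=np.ones((3, 3)))
        from skimage import measure

        permuted_labels = measure.label(permuted, connectivity=2)
        assert not np.array_equal(canonical > 0, permuted_labels > 0)

    def test_requires_2d(self):
        with pytest.raises(pq.PunctaError):
            pq.segment_puncta(np.zeros((3, 16, 16)), SegmentationParams())

    def test_max_project(self):
        stack = np.stack([np.full((4, 4), 1.0), np.full((4, 4), 3.0)])
        np.testing.assert_array_equal(pq.max_project(stack), np.full((4, 4), 3.0))


class TestQuantify:
    def test_exact_construction(self):
        img = np.full((16, 16), 2.0)
        mask = np.zeros((16, 16), dtype=int)
        mask[4:8, 4:8] = 1
        img[mask == 1] = 10.0
        records, report = pq.quantify_puncta(img, mask)
        assert records[0].c_in == pytest.approx(10.0)
        assert report.c_out == pytest.approx(2.0)
        table = pq.enrichment(records, report)
        assert table["enrichment"].iloc[0] == pytest.approx(5.0)

    def test_empty_mask_report(self, caplog):
        img = np.full((8, 8), 3.0)
        with caplog.at_level("INFO"):
            records, report = pq.quantify_puncta(img, np.zeros((8, 8), int))
        assert records == []
        assert report.c_out == pytest.approx(3.0)
        assert report.n_puncta == 0

    def test_c_in_monotone_in_amplitude(self, rng):
        from .conftest import separated_centers

        centers = separated_centers(rng, 9, 15.0, 112.0, 20.0)
        amps = np.repeat([20.0, 50.0, 110.0], 3)
        truth = simkit.SpotFieldTruth(
            shape=(128, 128), centers=centers, amplitudes=amps,
            widths=np.full(9, 1.5), background=0.0, noise_sd=0.0,
        )
        img, _ = simkit.synth_puncta_image(truth)
        mask = pq.segment_puncta(img, SegmentationParams())
        records, _ = pq.quantify_puncta(img, mask)
        means = {}
        for r in records:
            d = np.hypot(centers[:, 0] - r.centroid[0], centers[:, 1] - r.centroid[1])
            means[int(np.argmin(d))] = r.c_in
        tiers = [np.mean([means[i] for i in range(lo, lo + 3) if i in means])
                 for lo in (0, 3, 6)]
        assert tiers[0] < tiers[1] < tiers[2]

    def test_c_in_exceeds_c_out_on_noiseless_spots(self, spot_field):
        noiseless = simkit.SpotFieldTruth(
            shape=spot_field.shape, centers=spot_field.centers,
            amplitudes=spot_field.amplitudes, widths=spot_field.widths,
            background=5.0, noise_sd=0.0,
        )
        img, _ = simkit.synth_puncta_image(noiseless)
        bgsub = pq.subtract_background(img, (0, 8, 0, 8))
        mask = pq.segment_puncta(bgsub, SegmentationParams())
        records, report = pq.quantify_puncta(bgsub, mask)
        assert len(records) == 20
        assert all(r.c_in > report.c_out for r in records)

    def test_constant_offset_invariance(self, spot_field):
        img, _ = simkit.synth_puncta_image(spot_field)
        rect = (0, 8, 0, 8)
        a = pq.subtract_background(img, rect)
        b = pq.subtract_background(img + 13.0, rect)
        mask_a = pq.segment_puncta(a, SegmentationParams())
        mask_b = pq.segment_puncta(b, SegmentationParams())
        np.testing.assert_array_equal(mask_a, mask_b)
        rec_a, rep_a = pq.quantify_puncta(a, mask_a)
        rec_b, rep_b = pq.quantify_puncta(b, mask_b)
        for ra, rb in zip(rec_a, rec_b):
            assert ra.c_in - rep_a.c_out == pytest.approx(rb.c_in - rep_b.c_out, abs=1e-6)


class TestSecondaryChannel:
    def test_constant_channel_b(self):
        mask = np.zeros((16, 16), dtype=int)
        mask[2:5, 2:5] = 1
        mask[10:13, 10:13] = 2
        img_b = np.full((16, 16), 6.0)
        out = pq.quantify_secondary_channel(mask, img_b, background_rectangle=(0, 2, 0, 2))
        assert (out["b_mean"] == 0.0).all()  # 6 - 6 background
        out2 = pq.quantify_secondary_channel(mask, img_b)
        assert (out2["b_mean"] == 6.0).all()

    def test_identity_channels_match_c_in(self, spot_field):
        img, _ = simkit.synth_puncta_image(spot_field)
        mask = pq.segment_puncta(img, SegmentationParams())
        records, _ = pq.quantify_puncta(img, mask)
        out = pq.quantify_secondary_channel(mask, img)
        by_id = dict(zip(out["punctum_id"], out["b_mean"]))
        for r in records:
            assert by_id[r.punctum_id] == pytest.approx(r.c_in)

    def test_proportional_channels_regress_to_slope_2(self, spot_field):
        noiseless = simkit.SpotFieldTruth(
            shape=spot_field.shape, centers=spot_field.centers,
            amplitudes=spot_field.amplitudes * np.linspace(0.5, 2.0, 20),
            widths=spot_field.widths, background=0.0, noise_sd=0.0,
        )
        img_a, img_b, _ = simkit.synth_two_channel(noiseless, b_scale=2.0)
        mask = pq.segment_puncta(img_a, SegmentationParams())
        rec_a, _ = pq.quantify_puncta(img_a, mask)
        out_b = pq.quantify_secondary_channel(mask, img_b)
        a_means = np.array([r.c_in for r in rec_a])
        b_means = out_b["b_mean"].to_numpy()
        slope = stats.linregress(a_means, b_means).slope
        assert slope == pytest.approx(2.0, rel=0.05)

    def test_shape_mismatch(self):
        with pytest.raises(pq.PunctaError):
            pq.quantify_secondary_channel(np.zeros((4, 4), int), np.zeros((5, 5)))


class TestEventConservation:
    def test_worked_conserved_event(self):
        ev = EventPair(pre=[(5.0, 10), (3.0, 20)], post=[(5.5, 20)])
        ok, ratio = pq.check_event_conservation(ev, tolerance=0.05)
        assert ev.total_pre == pytest.approx(110.0)
        assert ratio == pytest.approx(1.0)
        assert ok

    def test_half_total_not_conserved(self):
        ev = EventPair(pre=[(5.0, 10), (3.0, 20)], post=[(5.5, 10)])
        ok, ratio = pq.check_event_conservation(ev, tolerance=0.05)
        assert ratio == pytest.approx(0.5)
        assert not ok

    def test_relabeling_invariance(self):
        a = EventPair(pre=[(2.0, 5), (4.0, 7)], post=[(3.0, 11)])
        b = EventPair(pre=[(4.0, 7), (2.0, 5)], post=[(3.0, 11)])
        assert pq.check_event_conservation(a) == pq.check_event_conservation(b)

    def test_zero_pre_total_rejected(self):
        with pytest.raises(pq.PunctaError):
            pq.check_event_conservation(EventPair(pre=[(0.0, 5)], post=[(1.0, 1)]))

    def test_empty_side_rejected(self):
        with pytest.raises(pq.PunctaError):
            EventPair(pre=[], post=[(1.0, 1)])

    def test_rendered_fusion_conserves_total(self):
        # photon-conserving synthetic fusion: two spots merge into one of
        # the summed flux; total (mean x area) matches within 5%
        def field(centers, amps):
            truth = simkit.SpotFieldTruth(
                shape=(96, 96), centers=centers, amplitudes=amps,
                widths=np.full(len(amps), 1.5), background=0.0, noise_sd=0.0,
            )
            img, _ = simkit.synth_puncta_image(truth)
            mask = pq.segment_puncta(img, SegmentationParams())
            recs, _ = pq.quantify_puncta(img, mask)
            return [(r.c_in, r.area_px) for r in recs]

        pre = field(np.array([[40.0, 30.0], [40.0, 60.0]]), np.array([40.0, 40.0]))
        post = field(np.array([[40.0, 45.0]]), np.array([80.0]))
        ok, ratio = pq.check_event_conservation(EventPair(pre=pre, post=post),
                                                tolerance=0.05)
        assert ok, f"ratio {ratio}"


class TestRegionMean:
    def test_constant_polygon(self):
        img = np.zeros((32, 32))
        img[8:16, 8:16] = 7.0
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:16, 8:16] = True
        assert pq.region_mean_intensity(img, mask) == pytest.approx(7.0)

    def test_half_and_half(self):
        img = np.zeros((8, 8))
        img[:, :4] = 4.0
        img[:, 4:] = 8.0
        mask = np.ones((8, 8), dtype=bool)
        assert pq.region_mean_intensity(img, mask) == pytest.approx(6.0)

    def test_whole_image_polygon_on_spot_field(self, spot_field):
        img, _ = simkit.synth_puncta_image(spot_field)
        rect = (0, 8, 0, 8)
        mask = np.ones(img.shape, dtype=bool)
        got = pq.region_mean_intensity(img, mask, background_rectangle=rect)
        expected = pq.subtract_background(img, rect).mean()
        assert got == pytest.approx(expected)

    def test_polygon_vertices_accepted(self):
        img = np.full((32, 32), 5.0)
        poly = [(5.0, 5.0), (5.0, 20.0), (20.0, 20.0), (20.0, 5.0)]
        assert pq.region_mean_intensity(img, poly) == pytest.approx(5.0)

    def test_empty_polygon_rejected(self):
        with pytest.raises(pq.PunctaError):
            pq.region_mean_intensity(np.zeros((8, 8)), np.zeros((8, 8), dtype=bool))


class TestExtrapolation:
    def test_unity_geometry(self):
        g = CellGeometry(length=20.0, width=10.0, height=2.0, slice_thickness=2.0)
        out = pq.extrapolate_cell_counts({"cytoplasm": 5}, g)
        assert out["whole_cell_estimate"].iloc[0] == pytest.approx(5.0)

    def test_one_eighth_nuclear_volume(self):
        g = CellGeometry(length=20.0, width=10.0, height=8.0, slice_thickness=1.0)
        out = pq.extrapolate_cell_counts({"nucleus": 3}, g)
        assert out["whole_cell_estimate"].iloc[0] == pytest.approx(24.0)

    def test_halving_slice_doubles_volume_factor(self):
        g1 = CellGeometry(length=20.0, width=10.0, height=5.0, slice_thickness=1.0)
        g2 = CellGeometry(length=20.0, width=10.0, height=5.0, slice_thickness=0.5)
        f1 = pq.extrapolation_factors(g1)["cytoplasm"]
        f2 = pq.extrapolation_factors(g2)["cytoplasm"]
        assert f2 == pytest.approx(2.0 * f1)

    def test_thick_slice_floors_at_one(self):
        g = CellGeometry(length=20.0, width=10.0, height=2.0, slice_thickness=5.0)
        assert pq.extrapolation_factors(g)["cytoplasm"] == 1.0

    def test_pm_factor_reported(self):
        g = CellGeometry(length=20.0, width=10.0, height=5.0, slice_thickness=1.0)
        out = pq.extrapolate_cell_counts({"plasma_membrane": 10}, g)
        assert out["factor"].iloc[0] > 1.0

    def test_bad_geometry(self):
        with pytest.raises(pq.PunctaError):
            CellGeometry(length=0.0, width=10.0)
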