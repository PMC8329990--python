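"""SMLM pipeline: averaging, background, detection vs a flood-fill oracle,
area/density QC, step counting, calibration and copy-number estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import exhaustive_change_points, flood_fill_components
from evcq import CalibrationError, ConfigError, EvcqError, simgen, smlm


def make_image(data, psz=0.108):
    return smlm.Image(np.asarray(data, dtype=float), psz)


def make_stack(frames, psz=0.108, dt=1.0):
    return smlm.ImageStack(np.asarray(frames, dtype=float), psz, dt)


class TestAverageAndCrop:
    def test_mean_of_constant_frames(self):
        stack = make_stack(np.full((4, 8, 8), 100.0))
        assert (smlm.average_frames(stack).data == 100.0).all()

    def test_arithmetic_mean(self):
        frames = np.stack([np.full((4, 4), v) for v in (0.0, 2.0, 4.0, 6.0)])
        assert (smlm.average_frames(make_stack(frames)).data == 3.0).all()

    def test_variance_reduction_by_four(self, rng):
        sigma = 5.0
        frames = 100.0 + rng.normal(0, sigma, size=(4, 320, 320))
        avg = smlm.average_frames(make_stack(np.clip(frames, 0, None)))
        assert abs(avg.data.var() - sigma**2 / 4) / (sigma**2 / 4) < 0.1

    def test_insufficient_frames(self):
        with pytest.raises(EvcqError, match="insufficient frames"):
            smlm.average_frames(make_stack(np.zeros((2, 4, 4))), k=4)

    def test_crop_pixel_count(self):
        img = make_image(np.zeros((1852, 1852)), psz=0.108)
        crop = smlm.crop_center(img, 65.0)
        assert crop.shape == (601, 601)  # floor(65 / 0.108)

    def test_crop_full_field_identity(self):
        img = make_image(np.arange(100.0).reshape(10, 10), psz=1.0)
        crop = smlm.crop_center(img, 10.0)
        np.testing.assert_array_equal(crop.data, img.data)

    def test_crop_too_small_field(self):
        with pytest.raises(EvcqError, match="field too small"):
            smlm.crop_center(make_image(np.zeros((10, 10)), psz=1.0), 20.0)

    def test_corner_spot_excluded_by_crop(self, noiseless_config):
        cfg = noiseless_config(seed=1, width_px=400, height_px=400)
        stack, truth = simgen.simulate_ev_field(
            cfg, 30, simgen.CopyNumberDistribution.fixed(10)
        )
        img = smlm.average_frames(stack, k=1)
        crop = smlm.crop_center(img, 20.0)
        spots = smlm.detect_spots(crop, cfg.background_adu)
        # every detected centroid lies inside the crop; corner truth spots
        # (outside the 20 um central window) are absent
        w = crop.shape[1] * crop.pixel_size_um
        assert all(0 <= s.centroid_x_um <= w for s in spots)
        assert len(spots) < len(truth)


class TestBackground:
    def test_constant(self):
        assert smlm.estimate_background(make_image(np.full((32, 32), 50.0))) == 50.0

    def test_robust_to_single_hot_pixel(self):
        data = np.full((32, 32), 50.0)
        data[3, 7] = 1e6
        assert smlm.estimate_background(make_image(data)) == 50.0

    def test_poisson_background_estimate(self, rng):
        data = 100.0 + rng.poisson(20.0, size=(512, 512))
        est = smlm.estimate_background(make_image(data.astype(float)))
        assert abs(est - 120.0) <= 2.0


class TestDetectSpots:
    def test_bright_spot_detected_centroid_accurate(self, noiseless_config):
        cfg = noiseless_config(seed=2)
        stack, truth = simgen.simulate_ev_field(
            cfg, 5, simgen.CopyNumberDistribution.fixed(5), unit_peak_adu=20.0
        )  # peak 5x background
        img = smlm.average_frames(stack, k=1)
        spots = smlm.detect_spots(img, cfg.background_adu)
        assert len(spots) == 5
        half_px = 0.5 * cfg.pixel_size_um
        for _, t in truth.iterrows():
            d = min(
                np.hypot(s.centroid_x_um - t.x_um, s.centroid_y_um - t.y_um)
                for s in spots
            )
            assert d < half_px

    def test_peak_exactly_twice_background_not_detected(self):
        data = np.full((32, 32), 50.0)
        data[16, 16] = 100.0  # exactly 2x background: strict rule excludes it
        assert smlm.detect_spots(make_image(data), 50.0) == []
        data[16, 16] = 100.0 + 1e-9
        assert len(smlm.detect_spots(make_image(data), 50.0)) == 1

    def test_blank_image_empty(self):
        assert smlm.detect_spots(make_image(np.full((16, 16), 30.0)), 30.0) == []

    def test_invalid_background(self):
        with pytest.raises(ConfigError, match="invalid background"):
            smlm.detect_spots(make_image(np.zeros((4, 4))), 0.0)

    @pytest.mark.parametrize("connectivity", [1, 2])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(20):
            img = rng.poisson(8.0, size=(64, 64)).astype(float)
            rr, cc = rng.integers(4, 60, 6), rng.integers(4, 60, 6)
            for r, c in zip(rr, cc):
                img[r - 1 : r + 2, c - 1 : c + 2] += rng.uniform(10, 40)
            image = make_image(img, psz=0.1)
            spots = smlm.detect_spots(image, 10.0, connectivity=connectivity)
            oracle = flood_fill_components(img, 10.0, eight=(connectivity == 2))
            assert len(spots) == len(oracle)
            o_by_area = sorted(
                ((o["area_px"], o["peak"], o["integrated"], o["centroid_rc"]) for o in oracle)
            )
            s_by_area = sorted(
                (
                    (
                        s.n_pixels,
                        s.peak_intensity_adu,
                        s.integrated_intensity_adu,
                        (s.centroid_y_um / 0.1, s.centroid_x_um / 0.1),
                    )
                    for s in spots
                )
            )
            for (oa, op, oi, oc), (sa, sp_, si, sc) in zip(o_by_area, s_by_area):
                assert oa == sa
                assert np.isclose(op, sp_) and np.isclose(oi, si)
                assert np.allclose(oc, sc)

    def test_integrated_at_least_peak_for_retained(self, noiseless_config):
        cfg = noiseless_config(seed=3, shot_noise=True, read_noise_adu=3.0)
        stack, _ = simgen.simulate_ev_field(
            cfg, 10, simgen.CopyNumberDistribution.fixed(20)
        )
        img = smlm.average_frames(stack, k=1)
        bg = smlm.estimate_background(img)
        for s in smlm.filter_spots(smlm.detect_spots(img, bg)):
            if s.status == smlm.RETAINED:
                assert s.integrated_intensity_adu >= s.peak_intensity_adu >= 0


class TestFilterAndQC:
    def _spot(self, i, area):
        return smlm.SpotCall(i, 0.0, 0.0, area, 100.0, 200.0)

    def test_area_window_statuses(self):
        spots = smlm.filter_spots([self._spot(i, a) for i, a in enumerate([0.05, 0.5, 12.0])])
        assert [s.status for s in spots] == ["removed_small", "retained", "removed_large"]

    def test_boundaries_inclusive(self):
        spots = smlm.filter_spots([self._spot(0, 0.1), self._spot(1, 10.0)])
        assert all(s.status == smlm.RETAINED for s in spots)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-4, max_value=50.0), min_size=1, max_size=40))
    def test_status_conservation(self, areas):
        spots = smlm.filter_spots([self._spot(i, a) for i, a in enumerate(areas)])
        counts = {
            status: sum(s.status == status for s in spots)
            for status in ("retained", "removed_small", "removed_large")
        }
        assert sum(counts.values()) == len(areas)

    def test_density_qc_thresholds(self):
        area = 65.0 * 65.0
        ret = [self._spot(i, 1.0) for i in range(400)]
        assert smlm.qc_density(smlm.filter_spots(ret), area).passed
        ret = [self._spot(i, 1.0) for i in range(500)]
        qc = smlm.qc_density(smlm.filter_spots(ret), area)
        assert not qc.passed and qc.density_per_um2 > 0.1

    def test_density_qc_empty(self):
        qc = smlm.qc_density([], 100.0)
        assert qc.passed and qc.density_per_um2 == 0.0


class TestBleachSteps:
    def test_single_exact_step(self):
        assert smlm.count_bleach_steps([100, 100, 100, 0, 0, 0, 0, 0]) == 1

    def test_two_exact_steps(self):
        assert smlm.count_bleach_steps([200, 200, 200, 100, 100, 100, 0, 0]) == 2

    def test_trace_too_short(self):
        with pytest.raises(EvcqError, match="trace too short"):
            smlm.count_bleach_steps([100, 100, 0, 0, 0, 0])

    def test_upward_change_not_a_step(self):
        assert smlm.count_bleach_steps([0, 0, 0, 0, 100, 100, 100, 100]) == 0

    def test_incomplete_bleach_counts_pending_step(self):
        # one observed step but the trace plateaus far above background:
        # at least one fluorophore never bleached
        assert smlm.count_bleach_steps([200] * 4 + [100] * 4) == 2

    def test_constant_trace_no_steps(self):
        assert smlm.count_bleach_steps([100.0] * 12) == 0

    def test_segmentation_matches_exhaustive_search(self, rng):
        # DP exact segmentation must equal brute-force enumeration of all
        # change-point placements
        for _ in range(10):
            y = np.concatenate(
                [
                    rng.normal(300, 8, 6),
                    rng.normal(180, 8, 5),
                    rng.normal(0, 8, 7),
                ]
            )
            b, means, sigma = smlm.segment_trace(y, max_steps=2)
            sse_dp = sum(
                float(np.sum((y[b[k] : b[k + 1]] - means[k]) ** 2))
                for k in range(len(means))
            )
            assert np.isclose(sse_dp, exhaustive_change_points(y, len(means)))

    def test_snr10_classification_rates(self):
        traces1, _ = simgen.simulate_bleach_traces(
            200, 1, unit_adu=100, noise_sigma_adu=10, seed=31
        )
        acc = np.mean([smlm.count_bleach_steps(t) == 1 for t in traces1])
        assert acc >= 0.95
        traces3, _ = simgen.simulate_bleach_traces(
            200, 3, unit_adu=100, noise_sigma_adu=10, seed=32
        )
        rej = np.mean([smlm.count_bleach_steps(t) != 1 for t in traces3])
        assert rej >= 0.95

    def test_accepted_single_iff_one_step(self):
        for trace in (
            [100] * 4 + [0] * 4,
            [200] * 3 + [100] * 3 + [0] * 3,
            [100.0] * 12,
            [200] * 4 + [100] * 4,
        ):
            bt = smlm.analyze_bleach_trace(trace)
            assert bt.accepted_single == (bt.n_steps_detected == 1)


class TestCalibration:
    def _spot(self, i, peak):
        return smlm.SpotCall(i, 0, 0, 0.5, peak, peak * 2, status=smlm.RETAINED)

    def _single_trace(self, i, level):
        return smlm.analyze_bleach_trace([level] * 5 + [0.0] * 5, spot_id=i)

    def test_constant_singles(self):
        spots = [self._spot(i, 100.0) for i in range(100)]
        traces = [self._single_trace(i, 100.0) for i in range(100)]
        cal = smlm.calibrate_unit_intensity(spots, traces)
        assert cal.mean_unit_peak_adu == 100.0
        assert cal.cv_unit == 0.0 and cal.n_accepted == 100

    def test_doubles_rejected_by_step_count(self):
        spots = [self._spot(i, 100.0) for i in range(80)]
        traces = [self._single_trace(i, 100.0) for i in range(80)]
        for i in range(80, 100):  # two-step contaminants at double intensity
            spots.append(self._spot(i, 200.0))
            traces.append(
                smlm.analyze_bleach_trace([200.0] * 4 + [100.0] * 4 + [0.0] * 4, spot_id=i)
            )
        cal = smlm.calibrate_unit_intensity(spots, traces)
        assert cal.mean_unit_peak_adu == 100.0 and cal.n_accepted == 80

    def test_lognormal_units_unbiased(self, rng):
        # SE of the mean at cv 0.2, n=200 is 1.4%, so a single draw sits
        # inside 3% only at ~2 sigma; averaging 5 replicates makes the 3%
        # bound a >4-sigma test of unbiasedness
        s2 = np.log1p(0.2**2)
        estimates = []
        for _ in range(5):
            peaks = rng.lognormal(np.log(100) - s2 / 2, np.sqrt(s2), 200)
            spots = [self._spot(i, p) for i, p in enumerate(peaks)]
            traces = [self._single_trace(i, p) for i, p in enumerate(peaks)]
            cal = smlm.calibrate_unit_intensity(spots, traces)
            estimates.append(cal.mean_unit_peak_adu)
        assert abs(np.mean(estimates) - 100.0) / 100.0 < 0.03

    def test_underpowered(self):
        spots = [self._spot(i, 100.0) for i in range(10)]
        traces = [self._single_trace(i, 100.0) for i in range(10)]
        with pytest.raises(CalibrationError, match="underpowered"):
            smlm.calibrate_unit_intensity(spots, traces)


class TestCopyNumbers:
    CAL = smlm.UnitCalibration(100.0, 0.1, 50)

    def _spot(self, i, peak, status=smlm.RETAINED):
        return smlm.SpotCall(i, 0, 0, 0.5, peak, peak * 2, status=status)

    def test_exact_ratio_above_detection(self):
        (rec,) = smlm.estimate_copy_numbers([self._spot(0, 500.0)], self.CAL)
        assert rec.copy_number_est == 5.0 and not rec.below_detection

    def test_below_detection_flag(self):
        (rec,) = smlm.estimate_copy_numbers([self._spot(0, 120.0)], self.CAL)
        assert rec.copy_number_est == pytest.approx(1.2) and rec.below_detection

    def test_only_retained_converted(self):
        spots = [self._spot(0, 500.0), self._spot(1, 500.0, smlm.REMOVED_SMALL)]
        assert len(smlm.estimate_copy_numbers(spots, self.CAL)) == 1

    def test_invalid_calibration(self):
        with pytest.raises(CalibrationError, match="invalid calibration"):
            smlm.estimate_copy_numbers(
                [self._spot(0, 10.0)], smlm.UnitCalibration(0.0, 0.0, 50)
            )

    def test_noiseless_linearity_end_to_end(self, noiseless_config):
        # rendered copies 1..10 convert back to exact integers; the retained
        # above-detection set is {3..10}
        ests = []
        for k in range(1, 11):
            cfg = noiseless_config(seed=40 + k)
            stack, _ = simgen.simulate_ev_field(
                cfg, 2, simgen.CopyNumberDistribution.fixed(k),
                unit_peak_adu=100.0, snap_to_pixel=True, min_sep_factor=12.0,
            )
            img = smlm.average_frames(stack, k=1)
            spots = smlm.filter_spots(smlm.detect_spots(img, cfg.background_adu))
            ests += smlm.estimate_copy_numbers(spots, self.CAL)
        above = sorted({round(r.copy_number_est) for r in ests if not r.below_detection})
        assert above == list(range(3, 11))
        for r in ests:
            assert r.copy_number_est == pytest.approx(round(r.copy_number_est), abs=1e-9)

    def test_condition_mean_monotone_in_detection_limit(self, rng):
        peaks = rng.lognormal(5.0, 0.6, 300)
        spots = [self._spot(i, p) for i, p in enumerate(peaks)]
        means = []
        for limit in (1.0, 2.0, 3.0, 5.0, 8.0):
            recs = smlm.estimate_copy_numbers(spots, self.CAL, detection_limit=limit)
            means.append(smlm.summarize_condition(recs, "x").mean_copy_number)
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))


class TestSummary:
    def test_mean_of_two(self):
        recs = [
            smlm.CopyNumberRecord(0, 5.0, False),
            smlm.CopyNumberRecord(1, 15.0, False),
        ]
        s = smlm.summarize_condition(recs, "c")
        assert s.mean_copy_number == 10.0
        assert s.histogram_counts.sum() == s.n_above_detection == 2

    def test_all_below_detection_errors(self):
        recs = [smlm.CopyNumberRecord(0, 1.0, True)]
        with pytest.raises(EvcqError, match="empty condition"):
            smlm.summarize_condition(recs, "c")
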