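"""Opacity metrics: nuclear intensities, threshold calibration, percent opaque."""

import logging

import numpy as np
import pytest

from lensopacity import (
    NUCLEAR_MERIDIANS,
    ReflexExclusion,
    SliceImage,
    calibrate_threshold,
    eye_cortical_metrics,
    eye_nuclear_metrics,
    percent_opaque,
    slice_nuclear_metrics,
)

from conftest import random_band_mask
from oracles import (
    nuclear_metrics_oracle,
    percent_opaque_oracle,
    pooled_max_oracle,
    pooled_percent_oracle,
)


def make_slice(pixels, angle=90.0, eye_id="e", group="nuclear"):
    return SliceImage(pixels=np.asarray(pixels), meridian_angle=angle, eye_id=eye_id, group=group)


def random_slice(rng, shape=(40, 40), angle=90.0, group="nuclear"):
    return make_slice(rng.integers(0, 256, shape).astype(np.uint8), angle=angle, group=group)


class TestNuclearSlice:
    def test_constant_image(self):
        image = make_slice(np.full((20, 20), 17, dtype=np.uint8))
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        m = slice_nuclear_metrics(image, mask)
        assert (m.max_intensity, m.mean_intensity, m.n_pixels) == (17.0, 17.0, 100)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(8):
            image = random_slice(rng)
            mask = rng.random((40, 40)) < 0.3
            if not mask.any():
                continue
            m = slice_nuclear_metrics(image, mask)
            omax, omean, on = nuclear_metrics_oracle(image.pixels, mask)
            assert m.max_intensity == omax
            assert m.mean_intensity == pytest.approx(omean, abs=1e-12)
            assert m.n_pixels == on

    def test_excluded_reflex_does_not_drive_maximum(self):
        pixels = np.full((20, 20), 40, dtype=np.uint8)
        pixels[10, 10] = 255
        mask = np.ones((20, 20), bool)
        reflex = np.zeros((20, 20), bool)
        reflex[10, 10] = True
        m = slice_nuclear_metrics(make_slice(pixels), mask, ReflexExclusion([reflex]))
        assert m.max_intensity == 40.0

    def test_max_invariant_under_changes_inside_exclusion(self, rng):
        pixels = rng.integers(0, 100, (30, 30)).astype(np.uint8)
        mask = np.ones((30, 30), bool)
        reflex = rng.random((30, 30)) < 0.2
        before = slice_nuclear_metrics(make_slice(pixels), mask, ReflexExclusion([reflex]))
        tampered = pixels.copy()
        tampered[reflex] = 255
        after = slice_nuclear_metrics(make_slice(tampered), mask, ReflexExclusion([reflex]))
        assert before.max_intensity == after.max_intensity
        assert before.mean_intensity == after.mean_intensity

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            slice_nuclear_metrics(make_slice(np.zeros((10, 10), np.uint8)), np.zeros((10, 10), bool))


class TestNuclearEye:
    def _four(self, values, rng=None):
        out = []
        for angle, value in zip(NUCLEAR_MERIDIANS, values):
            pixels = np.full((20, 20), value, dtype=np.uint8)
            mask = np.ones((20, 20), bool)
            out.append((make_slice(pixels, angle=angle), mask, None))
        return out

    def test_identical_constant_slices(self):
        eye = eye_nuclear_metrics(self._four([12, 12, 12, 12]))
        assert eye.agg_max == 12.0 and eye.agg_mean == 12.0

    def test_aggregate_is_mean_of_per_slice_maxima(self):
        eye = eye_nuclear_metrics(self._four([10, 20, 30, 40]))
        assert eye.agg_max == 25.0

    def test_matches_bruteforce_over_four_slices(self, rng):
        slices = [
            (random_slice(rng, angle=a), rng.random((40, 40)) < 0.4, None)
            for a in NUCLEAR_MERIDIANS
        ]
        eye = eye_nuclear_metrics(slices)
        maxima, means = [], []
        for image, mask, _ in slices:
            omax, omean, _ = nuclear_metrics_oracle(image.pixels, mask)
            maxima.append(omax)
            means.append(omean)
        assert eye.agg_max == pytest.approx(sum(maxima) / 4, abs=1e-12)
        assert eye.agg_mean == pytest.approx(sum(means) / 4, abs=1e-12)

    def test_missing_meridian_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            eye_nuclear_metrics(self._four([10, 20, 30, 40])[:3])

    def test_duplicate_meridian_rejected(self):
        slices = self._four([10, 20, 30, 40])
        slices[1] = (make_slice(np.zeros((20, 20), np.uint8), angle=45.3), np.ones((20, 20), bool), None)
        with pytest.raises(ValueError, match="duplicate"):
            eye_nuclear_metrics(slices)

    def test_off_grid_angle_rejected(self):
        slices = self._four([10, 20, 30, 40])
        slices[0] = (make_slice(np.zeros((20, 20), np.uint8), angle=60.0), np.ones((20, 20), bool), None)
        with pytest.raises(ValueError, match="meridian"):
            eye_nuclear_metrics(slices)


class TestThresholdCalibration:
    def test_all_zero_cohort_gives_zero(self):
        cal = calibrate_threshold([np.zeros(50)])
        assert cal.threshold == 0.0 and cal.n_eyes == 1

    def test_pooled_maximum_matches_oracle(self, rng):
        for _ in range(6):
            eyes = [rng.integers(0, 200, rng.integers(5, 80)) for _ in range(rng.integers(1, 8))]
            cal = calibrate_threshold(eyes)
            assert cal.threshold == pooled_max_oracle(eyes)
            pooled = np.concatenate([np.asarray(e).ravel() for e in eyes])
            assert cal.control_median == float(np.median(pooled))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least one control eye"):
            calibrate_threshold([])

    def test_eye_without_pixels_rejected(self):
        with pytest.raises(ValueError, match="at least one pixel"):
            calibrate_threshold([np.array([1, 2]), np.array([])])


class TestPercentOpaque:
    def test_pixels_at_threshold_are_clear(self):
        image = make_slice(np.full((10, 10), 34, np.uint8), group="control")
        assert percent_opaque(image, np.ones((10, 10), bool), 34) == 0.0

    def test_saturated_mask_is_fully_opaque(self):
        image = make_slice(np.full((10, 10), 255, np.uint8), group="cortical")
        assert percent_opaque(image, np.ones((10, 10), bool), 34) == 100.0

    def test_matches_counting_oracle(self, rng):
        for _ in range(8):
            image = random_slice(rng, group="cortical")
            mask = rng.random((40, 40)) < 0.4
            if not mask.any():
                continue
            thr = float(rng.integers(0, 255))
            assert percent_opaque(image, mask, thr) == percent_opaque_oracle(
                image.pixels, mask, thr
            )

    def test_non_increasing_in_threshold(self, rng):
        image = random_slice(rng, group="cortical")
        mask = rng.random((40, 40)) < 0.5
        pcts = [percent_opaque(image, mask, t) for t in range(0, 256, 15)]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))

    def test_non_decreasing_under_added_opacity(self, rng):
        pixels = rng.integers(0, 120, (30, 30)).astype(int)
        mask = rng.random((30, 30)) < 0.5
        bump = np.zeros((30, 30), int)
        bump[mask] = rng.integers(0, 100, int(mask.sum()))
        brighter = np.clip(pixels + bump, 0, 255)
        base = make_slice(pixels.astype(np.uint8), group="cortical")
        more = make_slice(brighter.astype(np.uint8), group="cortical")
        for thr in (10, 60, 130):
            assert percent_opaque(more, mask, thr) >= percent_opaque(base, mask, thr)
        m0 = slice_nuclear_metrics(base, mask)
        m1 = slice_nuclear_metrics(more, mask)
        assert m1.max_intensity >= m0.max_intensity
        assert m1.mean_intensity >= m0.mean_intensity


class TestEyeCortical:
    def test_clear_stack_scores_zero_everywhere(self, rng):
        slices = []
        for _ in range(5):
            mask = random_band_mask(rng)
            pixels = rng.integers(0, 30, mask.shape).astype(np.uint8)
            slices.append((make_slice(pixels, group="cortical"), mask, None))
        m = eye_cortical_metrics(slices, threshold=34)
        assert all(p == 0.0 for p in m.percent_opaque.values())

    def test_pooling_weights_slices_by_area(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        dark = make_slice(np.zeros((20, 20), np.uint8), group="cortical")
        bright = make_slice(np.full((20, 20), 255, np.uint8), group="cortical")
        m = eye_cortical_metrics([(dark, mask, None), (bright, mask, None)], threshold=34)
        assert m.percent_opaque[1.0] == 50.0

    def test_mean_aggregation_switch(self):
        small = np.zeros((20, 20), bool)
        small[9:11, 9:11] = True  # 4 px
        big = np.zeros((20, 20), bool)
        big[2:18, 2:18] = True  # 256 px
        bright = make_slice(np.full((20, 20), 255, np.uint8), group="cortical")
        dark = make_slice(np.zeros((20, 20), np.uint8), group="cortical")
        slices = [(bright, small, None), (dark, big, None)]
        pooled = eye_cortical_metrics(slices, threshold=34, fractions=(1.0,))
        averaged = eye_cortical_metrics(slices, threshold=34, fractions=(1.0,), aggregation="mean")
        assert pooled.percent_opaque[1.0] == pytest.approx(100.0 * 4 / 260)
        assert averaged.percent_opaque[1.0] == 50.0

    def test_pooled_fractions_match_bruteforce(self, rng):
        from lensopacity import mask_centroid, peripheral_fraction_mask

        slices = []
        for _ in range(6):
            mask = random_band_mask(rng, shape=(60, 60), r_in=(6, 10), r_out=(16, 25))
            pixels = rng.integers(0, 256, mask.shape).astype(np.uint8)
            slices.append((make_slice(pixels, group="cortical"), mask, None))
        thr = 120.0
        m = eye_cortical_metrics(slices, threshold=thr)
        for fraction in (1.0, 0.5, 1 / 3, 0.25):
            oracle_slices = []
            for image, mask, _ in slices:
                sub = peripheral_fraction_mask(mask, mask_centroid(mask), fraction)
                oracle_slices.append((image.pixels, sub))
            assert m.percent_opaque[float(fraction)] == pytest.approx(
                pooled_percent_oracle(oracle_slices, thr), abs=1e-12
            )

    def test_empty_slice_skipped_with_warning(self, caplog):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        empty = np.zeros((20, 20), bool)
        bright = make_slice(np.full((20, 20), 255, np.uint8), group="cortical")
        with caplog.at_level(logging.WARNING, logger="lensopacity.metrics"):
            m = eye_cortical_metrics([(bright, mask, None), (bright, empty, None)], threshold=34)
        assert m.percent_opaque[1.0] == 100.0
        assert any("empty" in rec.message for rec in caplog.records)

    def test_all_slices_empty_rejected(self):
        empty = np.zeros((20, 20), bool)
        bright = make_slice(np.full((20, 20), 255, np.uint8), group="cortical")
        with pytest.raises(ValueError, match="empty"):
            eye_cortical_metrics([(bright, empty, None)], threshold=34)
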