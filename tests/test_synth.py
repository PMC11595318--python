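"""Synthetic eye-pair generator: geometry, determinism, gaze statistics."""

import numpy as np
import pytest
from scipy import ndimage

from strabiscreen.errors import ApertureError
from strabiscreen.synth import (
    EyeAppearance,
    GazeSample,
    StrabismusProfile,
    generate_clip,
    generate_dataset,
    load_dataset,
    realized_active_fraction,
    render_eye,
    render_pair,
    sample_gaze_sequence,
    save_dataset,
)


def darkest_region_centroid(img: np.ndarray, appearance: EyeAppearance):
    """Independent oracle: centroid of the darkest connected region, found
    by thresholding halfway between pupil and iris intensity and labelling."""
    thr = (appearance.pupil_level + appearance.iris_level) / 2.0
    mask = img < thr
    labels, n = ndimage.label(mask)
    assert n >= 1
    means = ndimage.mean(img, labels, index=range(1, n + 1))
    darkest = int(np.argmin(means)) + 1
    cy, cx = ndimage.center_of_mass(labels == darkest)
    return cx, cy


class TestRenderEye:
    @pytest.mark.parametrize(
        "center,size",
        [((0.5, 0.5), 128), ((0.3, 0.5), 128), ((0.6, 0.45), 96)],
    )
    def test_darkest_region_centroid_matches_pupil(
        self, quiet_appearance, center, size
    ):
        img = render_eye(quiet_appearance, center, size)
        cx, cy = darkest_region_centroid(img, quiet_appearance)
        assert abs(cx - center[0] * size) <= 1.0
        assert abs(cy - center[1] * size) <= 1.0

    def test_noisy_render_is_bitwise_deterministic(self):
        app = EyeAppearance(noise_sd=0.05)
        a = render_eye(app, (0.45, 0.5), 64, seed=99)
        b = render_eye(app, (0.45, 0.5), 64, seed=99)
        assert np.array_equal(a, b)

    def test_pupil_outside_aperture_rejected(self, quiet_appearance):
        with pytest.raises(ApertureError, match="aperture"):
            render_eye(quiet_appearance, (0.5, 0.05), 64)

    def test_minimum_size_enforced(self, quiet_appearance):
        with pytest.raises(ValueError):
            render_eye(quiet_appearance, (0.5, 0.5), 16)


class TestAppearanceValidation:
    def test_intensity_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            EyeAppearance(pupil_level=0.9, iris_level=0.5, sclera_level=0.95)

    def test_deviation_requires_deviated_eye(self):
        with pytest.raises(ValueError):
            GazeSample(gaze_x=0.0, gaze_y=0.0, deviation_x=0.1, deviated_eye="none")


class TestGazeSequences:
    def test_no_profile_means_no_deviation(self):
        samples = sample_gaze_sequence(25, None, seed=3)
        assert all(s.deviated_eye == "none" for s in samples)
        assert all(s.deviation_x == 0.0 and s.deviation_y == 0.0 for s in samples)

    def test_deviation_magnitude_exact_with_nasal_sign(self):
        profile = StrabismusProfile(
            deviation_magnitude=0.2,
            deviation_direction="eso",
            deviated_eye="right",
            active_window=(0, 11),
        )
        samples = sample_gaze_sequence(12, profile, seed=5)
        for s in samples:
            # the deviation fields themselves are exact
            assert (s.deviation_x, s.deviation_y) == (-0.2, 0.0)
            lx, ly = s.offset("left")
            rx, ry = s.offset("right")
            # nasal for the right eye is -x; vertical offsets stay shared
            assert rx - lx == pytest.approx(-0.2, abs=1e-12)
            assert ry == ly

    def test_partial_window_counts_and_fraction(self):
        # a 9-frame clip deviated during frames 3..5 has 3 affected frames,
        # i.e. a third of the clip
        profile = StrabismusProfile(
            deviation_magnitude=0.1, deviated_eye="left", active_window=(3, 5)
        )
        samples = sample_gaze_sequence(9, profile, seed=0)
        active = [s.frame_index for s in samples if s.deviated_eye == "left"]
        assert active == [3, 4, 5]
        assert round(realized_active_fraction(samples), 2) == 0.33

    def test_window_outside_range_raises(self):
        profile = StrabismusProfile(
            deviation_magnitude=0.1, deviated_eye="left", active_window=(3, 9)
        )
        with pytest.raises(ValueError, match="active_window"):
            sample_gaze_sequence(9, profile, seed=0)

    def test_shared_gaze_mean_near_zero(self):
        samples = sample_gaze_sequence(10_000, None, gaze_spread=0.06, seed=11)
        xs = np.array([s.gaze_x for s in samples])
        ys = np.array([s.gaze_y for s in samples])
        for v in (xs, ys):
            se = v.std(ddof=1) / np.sqrt(len(v))
            assert abs(v.mean()) < 3 * se


class TestPairsAndDatasets:
    def test_normal_pair_offsets_identical(self, quiet_appearance):
        gaze = GazeSample(gaze_x=0.08, gaze_y=-0.05)
        pair = render_pair(gaze, quiet_appearance, 64)
        assert pair.true_left_pupil == pair.true_right_pupil
        assert pair.label == "normal"

    def test_deviation_recovered_from_rendered_pair(self, quiet_appearance):
        profile = StrabismusProfile(
            deviation_magnitude=0.1, deviation_direction="eso", deviated_eye="right"
        )
        dev = profile.deviation_vector()
        gaze = GazeSample(
            gaze_x=0.05, gaze_y=0.0, deviation_x=dev[0], deviation_y=dev[1],
            deviated_eye="right",
        )
        size = 96
        pair = render_pair(gaze, quiet_appearance, size)
        # exact (to machine epsilon) in normalized units before rendering
        diff = np.subtract(pair.true_right_pupil, pair.true_left_pupil)
        assert np.allclose(diff, dev, atol=1e-12)
        # and within 1 px after render-then-centroid recovery
        lx, ly = darkest_region_centroid(pair.left_image, quiet_appearance)
        rx, ry = darkest_region_centroid(pair.right_image, quiet_appearance)
        assert abs((rx - lx) - dev[0] * size) <= 1.0
        assert abs((ry - ly) - dev[1] * size) <= 1.0

    def test_dataset_class_mix_is_exact(self):
        app = EyeAppearance(noise_sd=0.01)
        profile = StrabismusProfile(deviation_magnitude=0.12, deviated_eye="left")
        all_normal = generate_dataset(10, 0.0, app, seed=1, size_px=64)
        assert all(p.label == "normal" for p in all_normal)
        mixed = generate_dataset(10, 0.5, app, profile, seed=1, size_px=64)
        assert sum(p.label == "strabismus_active" for p in mixed) == 5

    def test_dataset_deterministic_under_seed(self):
        app = EyeAppearance(noise_sd=0.02)
        a = generate_dataset(8, 0.0, app, seed=42, size_px=48)
        b = generate_dataset(8, 0.0, app, seed=42, size_px=48)
        for pa, pb in zip(a, b):
            assert pa.true_left_pupil == pb.true_left_pupil
            assert np.array_equal(pa.left_image, pb.left_image)
            assert np.array_equal(pa.right_image, pb.right_image)

    def test_invalid_dataset_arguments(self):
        app = EyeAppearance()
        with pytest.raises(ValueError):
            generate_dataset(0, 0.0, app)
        with pytest.raises(ValueError):
            generate_dataset(5, 1.5, app)

    def test_clip_labels_follow_active_window(self):
        app = EyeAppearance(noise_sd=0.0)
        profile = StrabismusProfile(
            deviation_magnitude=0.1, deviated_eye="right", active_window=(2, 4)
        )
        clip = generate_clip(8, profile, app, size_px=48, seed=9)
        labels = [p.label for p in clip]
        assert labels[2:5] == ["strabismus_active"] * 3
        assert all(l == "strabismus_inactive" for l in labels[:2] + labels[5:])

    def test_save_and_load_roundtrip(self, tmp_path):
        app = EyeAppearance(noise_sd=0.02)
        pairs = generate_dataset(4, 0.0, app, seed=7, size_px=48)
        save_dataset(pairs, tmp_path, seed=7)
        loaded = load_dataset(tmp_path)
        assert len(loaded) == 4
        for orig, back in zip(pairs, loaded):
            assert back.true_left_pupil == pytest.approx(orig.true_left_pupil)
            assert back.true_right_pupil == pytest.approx(orig.true_right_pupil)
            # images pass through 8-bit quantization
            assert np.max(np.abs(back.left_image - orig.left_image)) <= 1.0 / 255.0
            assert back.label == orig.label
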