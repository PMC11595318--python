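"""Screening statistics: the discrepancy distance, threshold calibration,
classification rules and video screening."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strabiscreen.crossdata import CrossModelPair
from strabiscreen.errors import SizeMismatchError
from strabiscreen.screening import (
    CalibrationStats,
    DistanceRecord,
    ModelBundle,
    aggregate_stats,
    calibrate,
    classify,
    classify_frames,
    euclidean_distance,
    frame_distances,
    screen_video,
)
from strabiscreen.synth import EyeAppearance, GazeSample, compose_face_frames, render_pair

# the six published normal-video per-eye mean distances used for threshold
# calibration in the original video study
NORMAL_LEFT_MEANS = [5.70, 5.36, 4.24, 5.02, 5.92, 5.57]
NORMAL_RIGHT_MEANS = [9.08, 6.57, 7.11, 6.64, 5.54, 9.34]


class _Stub:
    """Regressor stub: constant normalized output, fixed input size."""

    def __init__(self, point, input_size_px=128):
        self.point = point
        self.input_size_px = input_size_px

    def predict(self, crop):
        return self.point


def _stub_bundle(cross_pt, direct_pt, size=128):
    return ModelBundle(
        direct=_Stub(direct_pt, size),
        cross=CrossModelPair(
            left_input=_Stub(cross_pt, size), right_input=_Stub(cross_pt, size)
        ),
    )


class TestEuclideanDistance:
    def test_three_four_five(self):
        assert euclidean_distance((0, 0), (3, 4)) == 5.0

    def test_identity(self):
        assert euclidean_distance((2.5, -1.0), (2.5, -1.0)) == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance((0, math.nan), (1, 1))

    def test_matches_bruteforce_on_random_pairs(self, rng):
        pts = rng.normal(0, 50, size=(1000, 4))
        for x1, y1, x2, y2 in pts:
            brute = math.sqrt((x2 - x1) ** 2 + (y2 - y1) ** 2)
            assert abs(euclidean_distance((x1, y1), (x2, y2)) - brute) <= 1e-12


class TestCalibrate:
    def test_published_video_study_thresholds(self):
        stats = calibrate(NORMAL_LEFT_MEANS, NORMAL_RIGHT_MEANS, K=1.5, L=1.5)
        assert round(stats.mu_left, 2) == 5.30
        assert round(stats.sigma_left, 2) == 0.60
        assert round(stats.theta_left, 2) == 6.21
        assert round(stats.mu_right, 2) == 7.38
        assert round(stats.sigma_right, 2) == 1.51
        assert round(stats.theta_right, 2) == 9.64

    def test_threshold_is_exact_function_of_full_precision_moments(self):
        stats = calibrate(NORMAL_LEFT_MEANS, NORMAL_RIGHT_MEANS)
        assert stats.theta_left == stats.mu_left + stats.K * stats.sigma_left
        assert stats.theta_right == stats.mu_right + stats.L * stats.sigma_right
        # note: recomputing from the 2-dp displayed moments would give 6.20,
        # not the correct 6.21 — full precision matters

    def test_still_image_group_thresholds(self):
        # construct two-point samples whose sample mean/SD equal the
        # published normal-group moments exactly: {mu - s/sqrt2, mu + s/sqrt2}
        def two_points(mu, sigma):
            return [mu - sigma / math.sqrt(2), mu + sigma / math.sqrt(2)]

        stats = calibrate(
            two_points(9.66, 3.11), two_points(21.97, 4.09), unit_kind="image"
        )
        assert stats.theta_left == pytest.approx(14.325)
        assert stats.theta_right == pytest.approx(28.105)

    def test_constant_values_give_sigma_zero(self):
        stats = calibrate([4.2, 4.2, 4.2], [1.0, 1.0, 1.0], K=3.0)
        assert stats.sigma_left == 0.0
        assert stats.theta_left == 4.2
        assert stats.theta_right == 1.0

    def test_fewer_than_two_units_rejected(self):
        with pytest.raises(ValueError, match="2"):
            calibrate([1.0], [2.0])

    def test_order_invariance(self):
        a = calibrate(NORMAL_LEFT_MEANS, NORMAL_RIGHT_MEANS)
        b = calibrate(NORMAL_LEFT_MEANS[::-1], NORMAL_RIGHT_MEANS[::-1])
        assert a.theta_left == b.theta_left and a.theta_right == b.theta_right

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_equivariance(self, scale):
        base = calibrate(NORMAL_LEFT_MEANS, NORMAL_RIGHT_MEANS)
        scaled = calibrate(
            [scale * v for v in NORMAL_LEFT_MEANS],
            [scale * v for v in NORMAL_RIGHT_MEANS],
        )
        assert scaled.mu_left == pytest.approx(scale * base.mu_left, rel=1e-12)
        assert scaled.sigma_left == pytest.approx(scale * base.sigma_left, rel=1e-9)
        assert scaled.theta_left == pytest.approx(scale * base.theta_left, rel=1e-9)


class TestClassify:
    @pytest.fixture()
    def video_stats(self):
        return calibrate(NORMAL_LEFT_MEANS, NORMAL_RIGHT_MEANS)

    @pytest.mark.parametrize(
        "d_left,d_right,expected",
        [
            (5.82, 10.12, ("normal", "strabismus", "strabismus")),
            (8.19, 8.94, ("strabismus", "normal", "strabismus")),
            (6.18, 7.80, ("normal", "normal", "normal")),  # intermittent miss
            (17.92, 25.79, ("strabismus", "strabismus", "strabismus")),
            (0.0, 0.0, ("normal", "normal", "normal")),
        ],
    )
    def test_published_per_video_calls(self, video_stats, d_left, d_right, expected):
        call = classify(d_left, d_right, video_stats)
        assert (call.left_class, call.right_class, call.final_class) == expected

    def test_tie_with_threshold_is_normal(self, video_stats):
        call = classify(video_stats.theta_left, video_stats.theta_right, video_stats)
        assert call.final_class == "normal"

    def test_negative_distance_rejected(self, video_stats):
        with pytest.raises(ValueError):
            classify(-1.0, 0.0, video_stats)

    @given(
        dl=st.floats(0, 30), dr=st.floats(0, 30),
        el=st.floats(0, 5), er=st.floats(0, 5),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_classification_monotone(self, dl, dr, el, er):
        # shrinking either distance can never turn a normal call strabismic
        stats = calibrate(NORMAL_LEFT_MEANS, NORMAL_RIGHT_MEANS)
        bigger = classify(dl + el, dr + er, stats)
        if bigger.final_class == "normal":
            assert classify(dl, dr, stats).final_class == "normal"


class TestAggregateStats:
    def test_constant_records(self):
        records = [DistanceRecord(i, 3.3, 7.7) for i in range(4)]
        left, right = aggregate_stats(records)
        assert (left.mean, left.sd, left.min, left.max) == (3.3, 0.0, 3.3, 3.3)
        assert right.mean == 7.7

    def test_small_example(self):
        records = [DistanceRecord(i, d, 2 * d) for i, d in enumerate([1.0, 2.0, 3.0])]
        left, right = aggregate_stats(records)
        assert (left.mean, left.min, left.max) == (2.0, 1.0, 3.0)
        assert right.mean == 4.0

    def test_matches_bruteforce(self, rng):
        vals = rng.uniform(0, 20, size=(500, 2))
        records = [DistanceRecord(i, l, r) for i, (l, r) in enumerate(vals)]
        left, right = aggregate_stats(records)
        for stats, col in ((left, vals[:, 0]), (right, vals[:, 1])):
            assert stats.mean == pytest.approx(col.mean(), abs=1e-9)
            assert stats.sd == pytest.approx(col.std(ddof=1), abs=1e-9)
            assert stats.min == pytest.approx(col.min(), abs=1e-9)
            assert stats.max == pytest.approx(col.max(), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_stats([])


class TestFrameDistances:
    def test_identical_estimates_give_zero(self):
        bundle = _stub_bundle((0.4, 0.6), (0.4, 0.6))
        crop = np.zeros((128, 128))
        rec = frame_distances(crop, crop, bundle)
        assert rec.d_left == rec.d_right == 0.0

    def test_known_offset_scales_to_input_pixels(self):
        # normalized estimates (0,0) vs (0.3,0.4) are 0.5 apart -> 64 px at 128
        bundle = _stub_bundle((0.0, 0.0), (0.3, 0.4))
        crop = np.zeros((128, 128))
        rec = frame_distances(crop, crop, bundle)
        assert rec.d_left == pytest.approx(64.0)
        assert rec.d_right == pytest.approx(64.0)

    def test_model_size_disagreement_rejected(self, study):
        with pytest.raises(SizeMismatchError):
            ModelBundle(
                direct=_Stub((0, 0), 128),
                cross=CrossModelPair(_Stub((0, 0), 64), _Stub((0, 0), 64)),
            )


def _normal_clip(n, size=64, seed=0):
    rng = np.random.default_rng(seed)
    app = EyeAppearance(noise_sd=0.01)
    pairs = []
    for i in range(n):
        g = np.clip(rng.normal(0, 0.05, 2), -0.12, 0.12)
        pairs.append(
            render_pair(
                GazeSample(gaze_x=float(g[0]), gaze_y=float(g[1]), frame_index=i),
                app, size, seed=int(rng.integers(2**31)),
            )
        )
    return pairs


class TestScreenVideo:
    @pytest.fixture()
    def stub_bundle(self):
        return _stub_bundle((0.5, 0.5), (0.5, 0.5), size=64)

    @pytest.fixture()
    def loose_stats(self):
        return calibrate([1.0, 1.2, 0.9], [1.0, 1.1, 0.8], unit_kind="video_mean")

    def test_retention_percentage_counts_filtered_frames(self, stub_bundle, loose_stats):
        pairs = _normal_clip(10)
        # five frames get a right eye scaled enough to fail the area filter
        scales = [1.0, 1.12, 1.0, 1.12, 1.0, 1.12, 1.0, 1.12, 1.0, 1.12]
        frames = compose_face_frames(pairs, right_scale=scales)
        result = screen_video(frames, "synthetic", stub_bundle, loose_stats)
        assert result.n_retained == 5
        assert result.frames_pct == 50.0

    def test_no_retained_frames_is_unscreenable(self, stub_bundle, loose_stats):
        frames = compose_face_frames(_normal_clip(4), right_scale=[1.2] * 4)
        result = screen_video(frames, "synthetic", stub_bundle, loose_stats)
        assert result.final_class == "unscreenable"
        assert result.frames_pct == 0.0

    def test_calibration_input_size_must_match_models(self, stub_bundle):
        stats = calibrate([1.0, 1.1], [1.0, 1.1], input_size_px=128)
        frames = compose_face_frames(_normal_clip(2))
        with pytest.raises(SizeMismatchError, match="128"):
            screen_video(frames, "synthetic", stub_bundle, stats)

    def test_per_frame_mode_matches_classify(self, loose_stats):
        records = [DistanceRecord(0, 0.5, 0.5), DistanceRecord(1, 9.0, 0.5)]
        calls = classify_frames(records, loose_stats)
        assert calls[0].final_class == "normal"
        assert calls[1].final_class == "strabismus"
        assert calls[1].left_class == "strabismus"


class TestEndToEndScreening:
    def test_normal_and_deviated_clips_separate(self, study):
        # every strabismic clip's per-eye means exceed every normal clip's:
        # the deviation corrupts both the deviated eye's direct-vs-cross
        # comparison and the fellow eye's cross estimate
        strab_lo = min(
            min(r.left_stats.mean, r.right_stats.mean) for r in study.strab_results
        )
        normal_hi = max(
            max(r.left_stats.mean, r.right_stats.mean) for r in study.normal_results
        )
        assert strab_lo > normal_hi

    def test_deviated_clips_flagged(self, study):
        assert all(r.final_class == "strabismus" for r in study.strab_results)

    def test_calibration_units_are_video_means(self, study):
        assert study.stats.unit_kind == "video_mean"
        assert study.stats.n_units == 20
        assert study.stats.input_size_px == study.bundle.input_size_px

    def test_full_retention_without_jitter(self, study):
        assert all(r.frames_pct == 100.0 for r in study.normal_results)
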