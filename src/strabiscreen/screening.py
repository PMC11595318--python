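"""The screening statistic and decision rule.

For each eye, two independent estimates of the same pupil exist: the direct
estimate (from that eye's own crop) and the cross estimate (from the other
eye's crop).  Their Euclidean distance D is small when the eyes move in
synchrony and grows when one eye deviates — the discrepancy statistic at
the heart of the method.

Decision rule: from non-strabismic calibration data compute per-eye mean mu
and sample standard deviation sigma of D, and set the threshold
Theta = mu + K * sigma (K = 1.5 by default, separately as L for the right
eye).  A unit (frame, image, or per-video mean) is classified strabismic
for an eye iff its distance strictly exceeds that eye's Theta; the final
call is strabismic iff either eye is.  Video screening filters frames
through the eye-size criterion, averages D over retained frames and
compares the per-video means to Theta, mirroring how the thresholds were
calibrated (per-video means of normal clips).

All distances are expressed in model-input pixel units (normalized
estimates x input_size_px), so thresholds are tied to the input size used;
calibration and screening must agree on it and this is enforced.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .crossdata import CrossModelPair
from .errors import SizeMismatchError, UnscreenableError
from .extraction import (
    DetectorFn,
    Frame,
    crop_and_resize,
    detect_eyes,
    retention_pct,
    size_ratio_accept,
)
from .regression import TrainedRegressor

NORMAL = "normal"
STRABISMUS = "strabismus"
UNSCREENABLE = "unscreenable"

UnitKind = Literal["video_mean", "frame", "image"]


def euclidean_distance(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Straight-line separation of two points in a shared frame."""
    x1, y1 = p1
    x2, y2 = p2
    if not all(math.isfinite(v) for v in (x1, y1, x2, y2)):
        raise ValueError("euclidean_distance requires finite points")
    return math.hypot(x2 - x1, y2 - y1)


@dataclass(frozen=True)
class DistanceRecord:
    """Per-frame discrepancies: cross vs direct estimate, one per eye,
    in model-input pixel units."""

    frame_id: int
    d_left: float
    d_right: float

    def __post_init__(self) -> None:
        if self.d_left < 0 or self.d_right < 0:
            raise ValueError("distances must be non-negative")


@dataclass
class ModelBundle:
    """The three regressors screening needs, with a consistent input size."""

    direct: TrainedRegressor
    cross: CrossModelPair

    def __post_init__(self) -> None:
        sizes = {
            self.direct.input_size_px,
            self.cross.left_input.input_size_px,
            self.cross.right_input.input_size_px,
        }
        if len(sizes) != 1:
            raise SizeMismatchError(
                f"direct and cross models disagree on input size: {sorted(sizes)}"
            )

    @property
    def input_size_px(self) -> int:
        return self.direct.input_size_px


def frame_distances(
    left_crop: np.ndarray,
    right_crop: np.ndarray,
    bundle: ModelBundle,
    frame_id: int = 0,
) -> DistanceRecord:
    """Compute (d_left, d_right) for one size-filtered, resized pair.

    d_right compares the right pupil's two estimates in the right crop's
    frame: the cross estimate from the left crop against the direct
    estimate from the right crop; d_left is the mirror.  Distances are
    normalized-space distances scaled by the model input size.
    """
    s = bundle.input_size_px
    cross_right = bundle.cross.left_input.predict(left_crop)  # right pupil, right frame
    cross_left = bundle.cross.right_input.predict(right_crop)  # left pupil, left frame
    direct_left = bundle.direct.predict(left_crop)
    direct_right = bundle.direct.predict(right_crop)
    d_left = euclidean_distance(cross_left, direct_left) * s
    d_right = euclidean_distance(cross_right, direct_right) * s
    return DistanceRecord(frame_id=frame_id, d_left=d_left, d_right=d_right)


@dataclass(frozen=True)
class CalibrationStats:
    """Per-eye mu, sigma and threshold Theta = mu + multiplier * sigma."""

    mu_left: float
    sigma_left: float
    theta_left: float
    mu_right: float
    sigma_right: float
    theta_right: float
    K: float
    L: float
    n_units: int
    unit_kind: UnitKind
    input_size_px: int | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationStats":
        return cls(**json.loads(text))


def calibrate(
    left_values: Sequence[float],
    right_values: Sequence[float],
    K: float = 1.5,
    L: float = 1.5,
    unit_kind: UnitKind = "video_mean",
    input_size_px: int | None = None,
) -> CalibrationStats:
    """Fit per-eye thresholds from normal-group distance values.

    ``mu`` is the arithmetic mean, ``sigma`` the sample (n-1) standard
    deviation, and Theta = mu + K*sigma (L for the right eye), all kept at
    full precision; round only for display.
    """
    left = np.asarray(left_values, dtype=np.float64)
    right = np.asarray(right_values, dtype=np.float64)
    if len(left) < 2 or len(right) < 2:
        raise ValueError("calibration needs at least 2 units per eye (SD undefined)")
    mu_l, mu_r = float(left.mean()), float(right.mean())
    sd_l = float(np.std(left, ddof=1))
    sd_r = float(np.std(right, ddof=1))
    return CalibrationStats(
        mu_left=mu_l,
        sigma_left=sd_l,
        theta_left=mu_l + K * sd_l,
        mu_right=mu_r,
        sigma_right=sd_r,
        theta_right=mu_r + L * sd_r,
        K=K,
        L=L,
        n_units=len(left),
        unit_kind=unit_kind,
        input_size_px=input_size_px,
    )


@dataclass(frozen=True)
class FrameClassification:
    """Per-eye and combined normal/strabismus call for one unit."""

    frame_id: int
    left_class: str
    right_class: str
    final_class: str


def classify(
    d_left: float, d_right: float, stats: CalibrationStats, frame_id: int = 0
) -> FrameClassification:
    """Apply the threshold rule to one pair of distances.

    An eye is called strabismic iff its distance strictly exceeds its
    threshold (a tie counts as normal: the normal rule is 'less than' the
    threshold); the final call is strabismic iff either eye is.
    """
    if d_left < 0 or d_right < 0:
        raise ValueError("distances must be non-negative")
    left = STRABISMUS if d_left > stats.theta_left else NORMAL
    right = STRABISMUS if d_right > stats.theta_right else NORMAL
    final = STRABISMUS if STRABISMUS in (left, right) else NORMAL
    return FrameClassification(frame_id, left, right, final)


@dataclass(frozen=True)
class EyeStats:
    mean: float
    sd: float
    min: float
    max: float


def aggregate_stats(records: Sequence[DistanceRecord]) -> tuple[EyeStats, EyeStats]:
    """Per-eye (mean, sd, min, max) over a set of distance records; the SD
    convention (sample, n-1) matches calibration."""
    if len(records) == 0:
        raise ValueError("no distance records to aggregate")

    def _stats(values: np.ndarray) -> EyeStats:
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        return EyeStats(float(values.mean()), sd, float(values.min()), float(values.max()))

    lefts = np.array([r.d_left for r in records])
    rights = np.array([r.d_right for r in records])
    return _stats(lefts), _stats(rights)


@dataclass
class VideoScreeningResult:
    """One screened video: retention, per-eye distance stats and the calls."""

    video_id: str
    n_frames: int
    n_retained: int
    frames_pct: float
    left_stats: EyeStats | None
    right_stats: EyeStats | None
    left_class: str
    right_class: str
    final_class: str
    records: list[DistanceRecord] = field(default_factory=list)

    def to_row(self) -> dict:
        """Flat row matching the per-video report layout (retention,
        per-eye mean/SD/min/max, three classification columns)."""
        row: dict = {"video_id": self.video_id, "frames_pct": self.frames_pct}
        for side, st in (("left", self.left_stats), ("right", self.right_stats)):
            for name in ("mean", "sd", "min", "max"):
                row[f"{side}_{name}"] = getattr(st, name) if st else float("nan")
        row.update(
            left_class=self.left_class,
            right_class=self.right_class,
            final_class=self.final_class,
        )
        return row


def collect_distances(
    frames: Iterable[Frame],
    detector: DetectorFn | str,
    bundle: ModelBundle,
) -> tuple[list[DistanceRecord], int]:
    """Run detection, the size filter and the discrepancy statistic over a
    frame sequence; returns (records for retained frames, total frames)."""
    s = bundle.input_size_px
    records: list[DistanceRecord] = []
    n_total = 0
    for frame in frames:
        n_total += 1
        pair = detect_eyes(frame, detector)
        if pair is None:
            continue
        if not size_ratio_accept(pair):
            continue
        left_crop, _ = crop_and_resize(
            frame.image, pair.left.clipped(frame.image.shape), s, allow_any_size=True
        )
        right_crop, _ = crop_and_resize(
            frame.image, pair.right.clipped(frame.image.shape), s, allow_any_size=True
        )
        records.append(frame_distances(left_crop, right_crop, bundle, frame.frame_id))
    return records, n_total


def screen_video(
    frames: Iterable[Frame],
    detector: DetectorFn | str,
    bundle: ModelBundle,
    stats: CalibrationStats,
    video_id: str = "video",
) -> VideoScreeningResult:
    """Screen a frame sequence end to end.

    Every frame runs through detection and the eye-size filter; retained
    frames contribute a distance record.  The per-eye classification
    compares the per-video MEAN distance to the calibrated threshold, as in
    calibration on per-video means.  If no frame is retained the result is
    explicitly 'unscreenable' rather than silently normal.
    """
    if (
        stats.input_size_px is not None
        and stats.input_size_px != bundle.input_size_px
    ):
        raise SizeMismatchError(
            f"calibration was computed at input size {stats.input_size_px} but the "
            f"models run at {bundle.input_size_px}; distances would not be comparable"
        )
    records, n_total = collect_distances(frames, detector, bundle)
    if n_total == 0:
        raise ValueError("empty frame sequence")
    if not records:
        return VideoScreeningResult(
            video_id=video_id,
            n_frames=n_total,
            n_retained=0,
            frames_pct=0.0,
            left_stats=None,
            right_stats=None,
            left_class=UNSCREENABLE,
            right_class=UNSCREENABLE,
            final_class=UNSCREENABLE,
        )
    left_stats, right_stats = aggregate_stats(records)
    call = classify(left_stats.mean, right_stats.mean, stats)
    return VideoScreeningResult(
        video_id=video_id,
        n_frames=n_total,
        n_retained=len(records),
        frames_pct=retention_pct(len(records), n_total),
        left_stats=left_stats,
        right_stats=right_stats,
        left_class=call.left_class,
        right_class=call.right_class,
        final_class=call.final_class,
        records=records,
    )


def classify_frames(
    records: Sequence[DistanceRecord], stats: CalibrationStats
) -> list[FrameClassification]:
    """Additional per-frame mode: classify each distance record on its own
    (the per-video report classifies means instead)."""
    return [classify(r.d_left, r.d_right, stats, r.frame_id) for r in records]


def screen_image(
    left_crop: np.ndarray,
    right_crop: np.ndarray,
    bundle: ModelBundle,
    stats: CalibrationStats,
) -> tuple[DistanceRecord, FrameClassification]:
    """Still-image screening: one distance record, classified per image."""
    rec = frame_distances(left_crop, right_crop, bundle)
    return rec, classify(rec.d_left, rec.d_right, stats)


def results_to_frame(results: Sequence[VideoScreeningResult]) -> pd.DataFrame:
    """Per-video report table, one row per clip."""
    return pd.DataFrame([r.to_row() for r in results])
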