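"""Eye-region extraction: detector adapters, the eye-size similarity filter
and crop/resize coordinate transforms.

The screening method itself is detector-agnostic: any adapter that maps a
frame to named left/right eye bounding boxes (or ``None`` when fewer than
two eyes are visible) can drive it.  The bundled ``synthetic`` adapter reads
ground-truth boxes from frame metadata, which is how the synthetic pipeline
exercises the full path; a facial-landmark detector can be registered under
another name without touching the rest of the package.

The size filter implements the acceptance rule that the two eye regions'
pixel areas must be within 0.90-1.10 of each other, applied symmetrically:
both area_L/area_R and area_R/area_L must fall inside the inclusive bounds,
so the decision cannot depend on which eye is the numerator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from .errors import DetectorError

RATIO_LO = 0.90
RATIO_HI = 1.10


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box with half-open extent [x, x+w) x [y, y+h)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("bounding box must have positive width and height")

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        return self.x + self.w / 2.0, self.y + self.h / 2.0

    def clipped(self, frame_shape: tuple[int, int]) -> "BBox":
        """Clip to frame bounds (shape is (height, width))."""
        h, w = frame_shape[:2]
        x0, y0 = max(self.x, 0), max(self.y, 0)
        x1, y1 = min(self.x + self.w, w), min(self.y + self.h, h)
        if x1 <= x0 or y1 <= y0:
            raise ValueError("bounding box lies entirely outside the frame")
        return BBox(x0, y0, x1 - x0, y1 - y0)


@dataclass
class EyePairRegions:
    """Both eyes' boxes in one frame plus their area ratio."""

    frame_id: int
    left: BBox
    right: BBox

    @property
    def ratio(self) -> float:
        """left area / right area."""
        if self.left.area == 0 or self.right.area == 0:
            raise ValueError("zero-area eye box")
        return self.left.area / self.right.area


@dataclass(frozen=True)
class CropTransform:
    """Mapping between full-frame pixels and crop-normalized coordinates.

    The crop is the square of side ``side`` with top-left corner
    (x0, y0) in the frame, resampled to ``target_px``.  Normalized
    coordinates are fractions of the square's side, so they are independent
    of the resample size.
    """

    x0: float
    y0: float
    side: float
    target_px: int

    def to_norm(self, p: tuple[float, float]) -> tuple[float, float]:
        return (p[0] - self.x0) / self.side, (p[1] - self.y0) / self.side

    def to_frame(self, p_norm: tuple[float, float]) -> tuple[float, float]:
        return self.x0 + p_norm[0] * self.side, self.y0 + p_norm[1] * self.side

    def to_model_px(self, p_norm: tuple[float, float]) -> tuple[float, float]:
        """Normalized point -> model-input pixel units."""
        return p_norm[0] * self.target_px, p_norm[1] * self.target_px


@dataclass
class Frame:
    """A video/image frame plus the metadata a detector adapter may use."""

    image: np.ndarray
    frame_id: int = 0
    meta: dict = field(default_factory=dict)


DetectorFn = Callable[[Frame], EyePairRegions | None]

_DETECTORS: dict[str, DetectorFn] = {}


def register_detector(name: str) -> Callable[[DetectorFn], DetectorFn]:
    def deco(fn: DetectorFn) -> DetectorFn:
        _DETECTORS[name] = fn
        return fn

    return deco


def get_detector(name: str) -> DetectorFn:
    try:
        return _DETECTORS[name]
    except KeyError:
        raise DetectorError(
            f"no detector named {name!r}; registered: {sorted(_DETECTORS)}"
        ) from None


@register_detector("synthetic")
def synthetic_metadata_detector(frame: Frame) -> EyePairRegions | None:
    """Oracle adapter: reads ground-truth boxes from ``frame.meta``."""
    left = frame.meta.get("left_bbox")
    right = frame.meta.get("right_bbox")
    if left is None or right is None:
        return None
    return EyePairRegions(frame.frame_id, BBox(*left), BBox(*right))


def detect_eyes(frame: Frame, detector: DetectorFn | str) -> EyePairRegions | None:
    """Run a detector adapter; returns both boxes or None, never one eye."""
    if frame.image is None or frame.image.size == 0:
        raise ValueError("empty frame")
    fn = get_detector(detector) if isinstance(detector, str) else detector
    try:
        pair = fn(frame)
    except Exception as exc:  # adapter failure is not "no face found"
        raise DetectorError(f"detector adapter failed on frame {frame.frame_id}: {exc}") from exc
    return pair


def size_ratio_accept(
    pair: EyePairRegions, lo: float = RATIO_LO, hi: float = RATIO_HI
) -> bool:
    """True iff the eye-area ratio is acceptable, bounds inclusive.

    Both the ratio and its reciprocal are tested against [lo, hi] so the
    rule is order-independent (the effective acceptance band on
    area_L/area_R is [1/hi, hi] for the default bounds).
    """
    r = pair.ratio
    return (lo <= r <= hi) and (lo <= 1.0 / r <= hi)


def retention_pct(n_accepted: int, n_total: int) -> float:
    """Percentage of frames retained by the size filter."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    return 100.0 * n_accepted / n_total


def crop_and_resize(
    image: np.ndarray,
    bbox: BBox,
    target_px: int = 128,
    allow_any_size: bool = False,
) -> tuple[np.ndarray, CropTransform]:
    """Cut a square region around ``bbox`` and resample it to ``target_px``.

    A non-square box is squared by expanding its shorter side about the box
    centre.  Resampling is bilinear.  Raises if the squared box leaves the
    frame, or if ``target_px`` is outside the supported 72-196 range and
    ``allow_any_size`` is False.
    """
    if not allow_any_size and not (72 <= target_px <= 196):
        raise ValueError(
            f"target_px {target_px} outside [72, 196]; pass allow_any_size=True to override"
        )
    h, w = image.shape[:2]
    side = float(max(bbox.w, bbox.h))
    cx, cy = bbox.center
    x0, y0 = cx - side / 2.0, cy - side / 2.0
    if x0 < 0 or y0 < 0 or x0 + side > w or y0 + side > h:
        raise ValueError(
            f"squared crop ({x0:.1f}, {y0:.1f}, side {side:.1f}) exceeds the "
            f"{w}x{h} frame"
        )
    ix0, iy0 = int(round(x0)), int(round(y0))
    iside = int(round(side))
    patch = image[iy0 : iy0 + iside, ix0 : ix0 + iside]
    if patch.shape[0] != iside or patch.shape[1] != iside:
        raise ValueError("crop window exceeds frame bounds")
    if iside == target_px:
        crop = patch.astype(np.float64, copy=True)
    else:
        crop = _sk_resize(
            patch.astype(np.float64),
            (target_px, target_px),
            order=1,
            mode="edge",
            anti_aliasing=iside > target_px,
            preserve_range=True,
        )
    return crop, CropTransform(float(ix0), float(iy0), float(iside), target_px)


# ---------------------------------------------------------------------------
# frame iteration: directories of images, or video files via imageio

_FRAME_EXTS = {".png", ".jpg", ".jpeg"}


def _natural_key(p: Path) -> list:
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", p.name)]


def iter_frames(source: str | Path) -> Iterator[Frame]:
    """Yield frames from a directory of images or a video file.

    For a directory, images are read in natural filename order; if a
    ``boxes.json`` sidecar is present (written by the synthetic pipeline) its
    per-frame left/right boxes are attached to ``Frame.meta``.  Video files
    are opened through imageio, which requires a suitable plugin for the
    container format.
    """
    import json

    src = Path(source)
    if src.is_dir():
        boxes = {}
        sidecar = src / "boxes.json"
        if sidecar.exists():
            boxes = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        paths = sorted(
            (p for p in src.iterdir() if p.suffix.lower() in _FRAME_EXTS),
            key=_natural_key,
        )
        for i, p in enumerate(paths):
            with Image.open(p) as im:
                arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
            meta = {}
            if i in boxes:
                meta = {
                    "left_bbox": tuple(boxes[i]["left"]),
                    "right_bbox": tuple(boxes[i]["right"]),
                }
            yield Frame(arr, frame_id=i, meta=meta)
        return
    try:
        import imageio.v3 as iio

        for i, rgb in enumerate(iio.imiter(src)):
            arr = np.asarray(rgb, dtype=np.float64)
            if arr.ndim == 3:
                arr = arr.mean(axis=2)
            yield Frame(arr / 255.0, frame_id=i)
    except Exception as exc:
        raise IOError(
            f"could not read video {src}: {exc}. Install an imageio plugin for "
            "this container, or supply a directory of extracted frames."
        ) from exc
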