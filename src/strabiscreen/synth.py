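"""Synthetic paired eye-crop generator.

Renders grayscale left/right eye crops with known pupil positions and
correlated binocular gaze, plus an injectable per-eye deviation standing in
for strabismus.  The generator is the package's replacement for photographic
gaze datasets: it produces exactly the quantities the screening method needs
(two size-matched crops per frame, ground-truth pupil points, a per-frame
normal/deviated label) under a single fixed coordinate convention.

Coordinate convention (used package-wide): 0-based pixel coordinates, x
rightward, y downward, origin at the crop top-left; crop-normalized
coordinates are pixel / crop size, so the crop centre is (0.5, 0.5).  Left
and right crops are rendered in the same, non-mirrored orientation; the
nasal direction is +x for the left eye and -x for the right eye, which is
what gives the eso/exo deviation directions a sign.

Gaze and deviation offsets are expressed directly in crop-normalized units:
a ``GazeSample`` with ``gaze_x = 0.1`` puts both pupils 0.1 crop-widths to
the right of centre, and a deviation of magnitude m displaces exactly one
eye's pupil by m in normalized units.  This makes the deviation magnitude
exactly recoverable from the rendered geometry.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ApertureError

Side = Literal["left", "right"]
DeviatedEye = Literal["left", "right", "none"]
Direction = Literal["eso", "exo", "hyper", "hypo"]

LABEL_NORMAL = "normal"
LABEL_ACTIVE = "strabismus_active"
LABEL_INACTIVE = "strabismus_inactive"


@dataclass(frozen=True)
class EyeAppearance:
    """Rendering parameters of one simulated subject's eyes.

    All radii are fractions (iris of the crop width, pupil of the iris
    radius); intensity levels are grayscale values in [0, 1] and must obey
    pupil < iris < sclera so the pupil is always the darkest structure.
    ``eyelid_aperture_frac`` is the vertical fraction of the crop left
    uncovered by the simulated lids, centred on the crop middle row.
    """

    iris_radius_frac: float = 0.34
    pupil_radius_frac: float = 0.45
    sclera_level: float = 0.92
    iris_level: float = 0.45
    pupil_level: float = 0.08
    noise_sd: float = 0.03
    eyelid_aperture_frac: float = 0.70

    def __post_init__(self) -> None:
        if not (0.0 < self.iris_radius_frac <= 0.5):
            raise ValueError("iris_radius_frac must be in (0, 0.5]")
        if not (0.0 < self.pupil_radius_frac <= 1.0):
            raise ValueError("pupil_radius_frac must be in (0, 1]")
        for name in ("sclera_level", "iris_level", "pupil_level"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (self.pupil_level < self.iris_level < self.sclera_level):
            raise ValueError(
                "intensity ordering violated: need pupil_level < iris_level < sclera_level"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 < self.eyelid_aperture_frac <= 1.0):
            raise ValueError("eyelid_aperture_frac must be in (0, 1]")

    @property
    def pupil_radius_norm(self) -> float:
        """Pupil radius as a fraction of the crop width."""
        return self.iris_radius_frac * self.pupil_radius_frac

    def aperture_band(self) -> tuple[float, float]:
        """Normalized y-range [lo, hi] of the visible (lid-free) band."""
        half = self.eyelid_aperture_frac / 2.0
        return 0.5 - half, 0.5 + half


@dataclass(frozen=True)
class GazeSample:
    """Shared binocular gaze plus an optional single-eye deviation.

    ``gaze_x``/``gaze_y`` are crop-normalized offsets from the crop centre,
    common to both eyes (the synchronized component of eye movement).
    ``deviation_x``/``deviation_y`` are added to exactly one eye's offset;
    they must be zero when ``deviated_eye`` is "none".
    """

    gaze_x: float
    gaze_y: float
    deviation_x: float = 0.0
    deviation_y: float = 0.0
    deviated_eye: DeviatedEye = "none"
    frame_index: int = 0

    def __post_init__(self) -> None:
        for name in ("gaze_x", "gaze_y"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1]")
        if self.deviated_eye == "none" and (self.deviation_x or self.deviation_y):
            raise ValueError("deviation must be (0, 0) when deviated_eye is 'none'")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    def offset(self, side: Side) -> tuple[float, float]:
        """Total normalized pupil offset from crop centre for one eye."""
        dx = dy = 0.0
        if self.deviated_eye == side:
            dx, dy = self.deviation_x, self.deviation_y
        return self.gaze_x + dx, self.gaze_y + dy


@dataclass(frozen=True)
class StrabismusProfile:
    """Description of a simulated deviation: magnitude, direction, laterality
    and — for clips — which frames it is active in.

    ``active_window`` is an inclusive (start_frame, end_frame) range; when
    given it overrides ``active_fraction``.  With no window, a contiguous
    window of round(active_fraction * n_frames) frames is placed at a seeded
    random position, emulating intermittent deviation episodes.
    """

    deviation_magnitude: float
    deviation_direction: Direction = "eso"
    deviated_eye: Side = "right"
    active_fraction: float = 1.0
    active_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.deviation_magnitude < 0:
            raise ValueError("deviation_magnitude must be >= 0")
        if self.deviation_direction not in ("eso", "exo", "hyper", "hypo"):
            raise ValueError("deviation_direction must be one of eso/exo/hyper/hypo")
        if self.deviated_eye not in ("left", "right"):
            raise ValueError("deviated_eye must be 'left' or 'right'")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in [0, 1]")
        if self.active_window is not None:
            s, e = self.active_window
            if s > e:
                raise ValueError("active_window start must be <= end")

    def deviation_vector(self) -> tuple[float, float]:
        """Signed (dx, dy) for the deviated eye under the nasal convention
        (+x nasal for the left eye, -x nasal for the right eye; y is down,
        so hypertropia is -y)."""
        m = self.deviation_magnitude
        nasal = 1.0 if self.deviated_eye == "left" else -1.0
        if self.deviation_direction == "eso":
            return nasal * m, 0.0
        if self.deviation_direction == "exo":
            return -nasal * m, 0.0
        if self.deviation_direction == "hyper":
            return 0.0, -m
        return 0.0, m

    def resolve_active_frames(self, n_frames: int, rng: np.random.Generator) -> set[int]:
        if self.active_window is not None:
            s, e = self.active_window
            if s < 0 or e >= n_frames:
                raise ValueError(
                    f"active_window {self.active_window} outside frame range [0, {n_frames})"
                )
            return set(range(s, e + 1))
        n_active = int(round(self.active_fraction * n_frames))
        if n_active == 0:
            return set()
        start = int(rng.integers(0, n_frames - n_active + 1))
        return set(range(start, start + n_active))


@dataclass
class RenderedEyePair:
    """One frame's worth of data: both crops, ground truth and label."""

    left_image: np.ndarray
    right_image: np.ndarray
    true_left_pupil: tuple[float, float]
    true_right_pupil: tuple[float, float]
    gaze: GazeSample
    label: str = LABEL_NORMAL

    def __post_init__(self) -> None:
        if self.left_image.shape != self.right_image.shape:
            raise ValueError("left and right crops must share dimensions")

    @property
    def size_px(self) -> int:
        return self.left_image.shape[0]


def render_eye(
    appearance: EyeAppearance,
    pupil_center: tuple[float, float],
    size_px: int,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one grayscale eye crop with the pupil at ``pupil_center``.

    The crop is a sclera-level background with a concentric iris/pupil disc
    pair drawn with analytic one-pixel edge antialiasing, simulated lids
    covering the rows outside the aperture band, and optional additive
    Gaussian pixel noise clipped to [0, 1].  For a fixed seed the output is
    bitwise deterministic.  The darkest connected region of the result is
    the pupil disc, whose intensity centroid lies within one pixel of
    ``pupil_center * size_px``.
    """
    if size_px < 32:
        raise ValueError("size_px must be >= 32")
    cx, cy = pupil_center
    if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0):
        raise ApertureError(
            f"pupil_center {pupil_center} outside the crop [0,1]^2"
        )
    lo, hi = appearance.aperture_band()
    pr = appearance.pupil_radius_norm
    if not (lo + pr <= cy <= hi - pr):
        raise ApertureError(
            f"pupil_center {pupil_center} violates the eyelid aperture constraint: "
            f"the pupil (radius {pr:.3f}) must lie fully inside the visible band "
            f"y in [{lo:.3f}, {hi:.3f}]"
        )
    if not (pr <= cx <= 1.0 - pr):
        raise ApertureError(
            f"pupil_center {pupil_center} places the pupil partly outside the crop"
        )

    yy, xx = np.mgrid[0:size_px, 0:size_px].astype(np.float64)
    # pixel centres at integer coordinates; pupil centre in pixel units
    px, py = cx * size_px, cy * size_px
    dist = np.hypot(xx - px, yy - py)

    img = np.full((size_px, size_px), appearance.sclera_level, dtype=np.float64)
    iris_r = appearance.iris_radius_frac * size_px
    pupil_r = pr * size_px
    # analytic 1-px antialiased coverage of each disc
    a_iris = np.clip(iris_r - dist + 0.5, 0.0, 1.0)
    img = img * (1.0 - a_iris) + appearance.iris_level * a_iris
    a_pupil = np.clip(pupil_r - dist + 0.5, 0.0, 1.0)
    img = img * (1.0 - a_pupil) + appearance.pupil_level * a_pupil

    # lids: everything outside the aperture band reverts to background level
    band = (yy >= lo * size_px) & (yy <= hi * size_px)
    img = np.where(band, img, appearance.sclera_level)

    if appearance.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, appearance.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def sample_gaze_sequence(
    n_frames: int,
    profile: StrabismusProfile | None = None,
    gaze_spread: float = 0.06,
    seed: int = 0,
    max_offset: float = 0.15,
) -> list[GazeSample]:
    """Draw a reproducible sequence of correlated binocular gaze samples.

    Shared gaze offsets are N(0, gaze_spread) per axis, clipped to
    ``±max_offset`` (keeping pupils inside the eyelid aperture for the
    default appearance).  The profile's deviation vector is added to exactly
    one eye in the frames its active window covers.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    active: set[int] = set()
    dev = (0.0, 0.0)
    if profile is not None and profile.deviation_magnitude > 0:
        active = profile.resolve_active_frames(n_frames, rng)
        dev = profile.deviation_vector()
    gaze = np.clip(rng.normal(0.0, gaze_spread, (n_frames, 2)), -max_offset, max_offset)
    samples = []
    for i in range(n_frames):
        if i in active:
            samples.append(
                GazeSample(
                    gaze_x=float(gaze[i, 0]),
                    gaze_y=float(gaze[i, 1]),
                    deviation_x=dev[0],
                    deviation_y=dev[1],
                    deviated_eye=profile.deviated_eye,  # type: ignore[union-attr]
                    frame_index=i,
                )
            )
        else:
            samples.append(
                GazeSample(gaze_x=float(gaze[i, 0]), gaze_y=float(gaze[i, 1]), frame_index=i)
            )
    return samples


def realized_active_fraction(samples: Sequence[GazeSample]) -> float:
    """Fraction of frames in which a deviation is applied."""
    n_active = sum(1 for s in samples if s.deviated_eye != "none")
    return n_active / len(samples)


def render_pair(
    gaze: GazeSample,
    appearance: EyeAppearance,
    size_px: int = 128,
    seed: int = 0,
    label: str | None = None,
) -> RenderedEyePair:
    """Render both crops of one frame from a gaze sample.

    Pupil positions are (0.5, 0.5) plus each eye's total offset; for a
    normal frame both eyes therefore share the same crop-normalized offset
    exactly.
    """
    lx, ly = gaze.offset("left")
    rx, ry = gaze.offset("right")
    true_left = (0.5 + lx, 0.5 + ly)
    true_right = (0.5 + rx, 0.5 + ry)
    rng = np.random.default_rng(seed)
    left = render_eye(appearance, true_left, size_px, rng=rng)
    right = render_eye(appearance, true_right, size_px, rng=rng)
    if label is None:
        label = LABEL_NORMAL if gaze.deviated_eye == "none" else LABEL_ACTIVE
    return RenderedEyePair(left, right, true_left, true_right, gaze, label)


def generate_clip(
    n_frames: int,
    profile: StrabismusProfile | None,
    appearance: EyeAppearance,
    size_px: int = 128,
    gaze_spread: float = 0.06,
    seed: int = 0,
) -> list[RenderedEyePair]:
    """Render a clip (frame sequence); frames inside the profile's active
    window are labelled active, the rest inactive (or normal without a
    profile)."""
    ss = np.random.SeedSequence(seed)
    gaze_seed, noise_seed = ss.spawn(2)
    samples = sample_gaze_sequence(
        n_frames, profile, gaze_spread=gaze_spread, seed=int(gaze_seed.generate_state(1)[0] % 2**31)
    )
    noise_rng = np.random.default_rng(noise_seed)
    pairs = []
    for s in samples:
        if profile is None or profile.deviation_magnitude == 0:
            label = LABEL_NORMAL
        else:
            label = LABEL_ACTIVE if s.deviated_eye != "none" else LABEL_INACTIVE
        frame_seed = int(noise_rng.integers(0, 2**31))
        pairs.append(render_pair(s, appearance, size_px, seed=frame_seed, label=label))
    return pairs


def generate_dataset(
    n_pairs: int,
    class_mix: float,
    appearance: EyeAppearance,
    profile: StrabismusProfile | None = None,
    seed: int = 0,
    size_px: int = 128,
    gaze_spread: float = 0.06,
) -> list[RenderedEyePair]:
    """Generate ``n_pairs`` independent eye pairs with an exact class mix.

    Exactly round(n_pairs * class_mix) pairs carry the profile's deviation
    (always active — each pair is an independent still); the rest are
    normal.  The result is shuffled deterministically under ``seed``.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be > 0")
    if not 0.0 <= class_mix <= 1.0:
        raise ValueError("class_mix must be in [0, 1]")
    n_strab = int(round(n_pairs * class_mix))
    if n_strab > 0 and profile is None:
        raise ValueError("class_mix > 0 requires a StrabismusProfile")
    rng = np.random.default_rng(seed)
    gaze = np.clip(rng.normal(0.0, gaze_spread, (n_pairs, 2)), -0.15, 0.15)
    dev = profile.deviation_vector() if profile is not None else (0.0, 0.0)
    pairs: list[RenderedEyePair] = []
    for i in range(n_pairs):
        strabismic = i < n_strab
        if strabismic:
            g = GazeSample(
                gaze_x=float(gaze[i, 0]),
                gaze_y=float(gaze[i, 1]),
                deviation_x=dev[0],
                deviation_y=dev[1],
                deviated_eye=profile.deviated_eye,  # type: ignore[union-attr]
                frame_index=i,
            )
            label = LABEL_ACTIVE
        else:
            g = GazeSample(gaze_x=float(gaze[i, 0]), gaze_y=float(gaze[i, 1]), frame_index=i)
            label = LABEL_NORMAL
        pair_seed = int(rng.integers(0, 2**31))
        pairs.append(render_pair(g, appearance, size_px, seed=pair_seed, label=label))
    order = rng.permutation(n_pairs)
    return [pairs[j] for j in order]


def sample_appearance(rng: np.random.Generator) -> EyeAppearance:
    """Draw a per-subject appearance: iris size, contrast, lid aperture and
    pixel-noise level vary the way different faces, cameras and lighting
    would.  Both eyes of a subject share the draw."""
    # ranges keep the pupil fully visible at the generator's maximum
    # gaze-plus-deviation offset (0.30 normalized horizontally, 0.15 vertically)
    return EyeAppearance(
        iris_radius_frac=float(rng.uniform(0.26, 0.36)),
        pupil_radius_frac=float(rng.uniform(0.32, 0.50)),
        sclera_level=float(rng.uniform(0.82, 0.97)),
        iris_level=float(rng.uniform(0.35, 0.55)),
        pupil_level=float(rng.uniform(0.02, 0.15)),
        noise_sd=float(rng.uniform(0.01, 0.07)),
        eyelid_aperture_frac=float(rng.uniform(0.68, 0.78)),
    )


# ---------------------------------------------------------------------------
# face-frame composition: paste a rendered pair onto a canvas with known
# bounding boxes, so the full detect -> filter -> crop path can run on
# synthetic data

def compose_face_frames(
    pairs: Sequence[RenderedEyePair],
    margin: int = 8,
    gap: int = 16,
    right_scale: Sequence[float] | None = None,
) -> list:
    """Build Frame objects with ground-truth eye boxes in their metadata.

    Each frame is a light canvas holding the left crop and the right crop
    side by side.  ``right_scale`` optionally rescales the right eye's box
    per frame (e.g. to make some frames fail the eye-size filter); pupil
    positions are crop-normalized, hence invariant under the rescale.
    """
    from skimage.transform import resize as _resize

    from .extraction import Frame

    frames = []
    for i, pair in enumerate(pairs):
        s = pair.size_px
        f = 1.0 if right_scale is None else float(right_scale[i])
        s_r = max(8, int(round(s * f)))
        right = pair.right_image
        if s_r != s:
            right = _resize(
                right, (s_r, s_r), order=1, mode="edge",
                anti_aliasing=s_r < s, preserve_range=True,
            )
        h = max(s, s_r) + 2 * margin
        w = s + s_r + gap + 2 * margin
        canvas = np.full((h, w), 0.85, dtype=np.float64)
        canvas[margin : margin + s, margin : margin + s] = pair.left_image
        rx = margin + s + gap
        canvas[margin : margin + s_r, rx : rx + s_r] = right
        frames.append(
            Frame(
                canvas,
                frame_id=i,
                meta={
                    "left_bbox": (margin, margin, s, s),
                    "right_bbox": (rx, margin, s_r, s_r),
                },
            )
        )
    return frames


def save_frames(frames: Sequence, out_dir: str | Path) -> Path:
    """Write composed frames as PNGs plus a ``boxes.json`` sidecar that the
    directory frame iterator re-attaches to metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    boxes = {}
    for fr in frames:
        arr = np.clip(np.rint(fr.image * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / f"frame{fr.frame_id:05d}.png")
        if "left_bbox" in fr.meta:
            boxes[fr.frame_id] = {
                "left": list(fr.meta["left_bbox"]),
                "right": list(fr.meta["right_bbox"]),
            }
    (out / "boxes.json").write_text(json.dumps(boxes))
    return out


# ---------------------------------------------------------------------------
# dataset persistence: PNG crops + one CSV annotation table + JSON sidecar

ANNOTATION_COLUMNS = [
    "pair_id",
    "frame_index",
    "eye",
    "image_path",
    "pupil_x_norm",
    "pupil_y_norm",
    "label",
]


def save_dataset(
    pairs: Iterable[RenderedEyePair],
    out_dir: str | Path,
    seed: int | None = None,
    params: dict | None = None,
) -> Path:
    """Write crops as PNGs plus ``annotations.csv`` and ``metadata.json``.

    Returns the annotation-table path.
    """
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, pair in enumerate(pairs):
        for eye, img, pupil in (
            ("left", pair.left_image, pair.true_left_pupil),
            ("right", pair.right_image, pair.true_right_pupil),
        ):
            rel = f"images/pair{pid:05d}_{eye}.png"
            arr = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out / rel)
            rows.append(
                dict(
                    pair_id=pid,
                    frame_index=pair.gaze.frame_index,
                    eye=eye,
                    image_path=rel,
                    pupil_x_norm=pupil[0],
                    pupil_y_norm=pupil[1],
                    label=pair.label,
                )
            )
    table = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    csv_path = out / "annotations.csv"
    table.to_csv(csv_path, index=False)
    meta = {"seed": seed, "params": params or {}, "n_pairs": int(table.pair_id.nunique())}
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    return csv_path


def load_dataset(data_dir: str | Path) -> list[RenderedEyePair]:
    """Re-load a saved dataset into RenderedEyePair objects (8-bit images)."""
    data_dir = Path(data_dir)
    table = pd.read_csv(data_dir / "annotations.csv")
    pairs = []
    for pid, grp in table.groupby("pair_id", sort=True):
        by_eye = {r.eye: r for r in grp.itertuples()}
        if set(by_eye) != {"left", "right"}:
            raise ValueError(f"pair {pid} does not have exactly one left and one right row")
        imgs = {}
        for eye, rec in by_eye.items():
            with Image.open(data_dir / rec.image_path) as im:
                imgs[eye] = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
        left, right = by_eye["left"], by_eye["right"]
        label = left.label
        gaze = GazeSample(
            gaze_x=float(np.clip(left.pupil_x_norm - 0.5, -1, 1)),
            gaze_y=float(np.clip(left.pupil_y_norm - 0.5, -1, 1)),
            frame_index=int(left.frame_index),
        )
        pairs.append(
            RenderedEyePair(
                imgs["left"],
                imgs["right"],
                (float(left.pupil_x_norm), float(left.pupil_y_norm)),
                (float(right.pupil_x_norm), float(right.pupil_y_norm)),
                gaze,
                label,
            )
        )
    return pairs
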