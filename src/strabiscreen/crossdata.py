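"""Cross-eye training-set construction and cross-model training.

The cross-eye regressors learn to predict the *opposite* eye's pupil
position from one eye's crop, exploiting the synchronization of binocular
movement.  Each size-matched eye pair yields exactly two training samples:
the left crop labelled with the right pupil, and the right crop labelled
with the left pupil.  Targets live in the opposite eye's own
crop-normalized frame, which is what makes the downstream discrepancy
statistic (cross vs direct estimate of the same pupil) well defined: both
estimates of, say, the right pupil are coordinates in the right crop's
frame.

Targets come either from a trained direct-eye regressor (the path used when
the source data carry no pupil annotations) or from ground truth (strictly
better when available, e.g. for synthetic data).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FilterError
from .extraction import RATIO_HI, RATIO_LO
from .regression import PupilRegressor, RegressorConfig, TrainedRegressor, build_model, train
from .synth import RenderedEyePair

Source = Literal["direct_model", "ground_truth"]

GROUND_TRUTH = "ground_truth"


@dataclass
class EyePairSample:
    """A size-filtered pair of crops with (optional) ground-truth pupils."""

    left_crop: np.ndarray
    right_crop: np.ndarray
    true_left: tuple[float, float] | None = None
    true_right: tuple[float, float] | None = None
    ratio: float = 1.0
    frame_id: int = 0

    @classmethod
    def from_rendered(cls, pair: RenderedEyePair, frame_id: int = 0) -> "EyePairSample":
        return cls(
            left_crop=pair.left_image,
            right_crop=pair.right_image,
            true_left=pair.true_left_pupil,
            true_right=pair.true_right_pupil,
            ratio=1.0,
            frame_id=frame_id,
        )


@dataclass
class CrossSample:
    """One cross-eye training sample: a crop of one eye labelled with the
    contralateral pupil position (in the contralateral crop's frame)."""

    input_crop: np.ndarray
    input_side: Literal["left", "right"]
    target_point: tuple[float, float]
    source: Source

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in self.target_point):
            raise ValueError("cross-sample target must be finite")


def build_cross_samples(
    pairs: Sequence[EyePairSample],
    labeler: TrainedRegressor | str,
) -> list[CrossSample]:
    """Turn filtered eye pairs into cross-eye samples, two per pair.

    ``labeler`` is either a trained direct-eye regressor, applied to the
    opposite crop to estimate the target pupil, or the string
    ``"ground_truth"`` to use the pairs' true pupil positions.  Pairs whose
    stored area ratio falls outside the size filter's bounds are rejected:
    the filter is mandatory upstream.
    """
    use_truth = isinstance(labeler, str)
    if use_truth and labeler != GROUND_TRUTH:
        raise ValueError(f"string labeler must be {GROUND_TRUTH!r}, got {labeler!r}")
    out: list[CrossSample] = []
    for pair in pairs:
        r = pair.ratio
        if not (RATIO_LO <= r <= RATIO_HI and RATIO_LO <= 1.0 / r <= RATIO_HI):
            raise FilterError(
                f"pair {pair.frame_id} has area ratio {r:.4f} outside the "
                f"[{RATIO_LO}, {RATIO_HI}] size filter; filter pairs before "
                "building cross samples"
            )
        if use_truth:
            if pair.true_left is None or pair.true_right is None:
                raise ValueError(
                    f"pair {pair.frame_id} lacks ground-truth pupils; "
                    "use a direct-model labeler"
                )
            t_left, t_right = pair.true_left, pair.true_right
            source: Source = "ground_truth"
        else:
            t_left = labeler.predict(pair.left_crop)
            t_right = labeler.predict(pair.right_crop)
            source = "direct_model"
        out.append(CrossSample(pair.left_crop, "left", t_right, source))
        out.append(CrossSample(pair.right_crop, "right", t_left, source))
    return out


@dataclass
class CrossModelPair:
    """The two cross-eye regressors: one per input side.

    ``left_input`` consumes left-eye crops and emits right-pupil estimates;
    ``right_input`` is the mirror."""

    left_input: TrainedRegressor
    right_input: TrainedRegressor


def train_cross_models(
    samples: Sequence[CrossSample],
    config: RegressorConfig | None = None,
) -> CrossModelPair:
    """Train the per-side cross-eye regressors from a cross-sample set.

    Both input sides must be represented.  The right-input model trains with
    a shifted seed so the two networks do not share an initialization.
    """
    if config is None:
        config = RegressorConfig.cross_default()
    by_side: dict[str, list[tuple[np.ndarray, tuple[float, float]]]] = {
        "left": [],
        "right": [],
    }
    for s in samples:
        by_side[s.input_side].append((s.input_crop, s.target_point))
    for side, subset in by_side.items():
        if not subset:
            raise ValueError(f"no {side}-input cross samples; both sides are required")
    left_model = train(build_model(config), by_side["left"], config)
    right_cfg = RegressorConfig.from_dict({**config.to_dict(), "seed": config.seed + 1})
    right_model = train(build_model(right_cfg), by_side["right"], right_cfg)
    return CrossModelPair(left_input=left_model, right_input=right_model)


# ---------------------------------------------------------------------------
# persistence: same CSV+PNG layout as the synthetic datasets, with the
# input_side and source columns added

CROSS_COLUMNS = [
    "sample_id",
    "input_side",
    "image_path",
    "target_x_norm",
    "target_y_norm",
    "source",
]


def save_cross_samples(samples: Sequence[CrossSample], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        rel = f"images/cross{i:05d}_{s.input_side}.png"
        arr = np.clip(np.rint(s.input_crop * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / rel)
        rows.append(
            dict(
                sample_id=i,
                input_side=s.input_side,
                image_path=rel,
                target_x_norm=s.target_point[0],
                target_y_norm=s.target_point[1],
                source=s.source,
            )
        )
    csv_path = out / "cross_samples.csv"
    pd.DataFrame(rows, columns=CROSS_COLUMNS).to_csv(csv_path, index=False)
    return csv_path


def load_cross_samples(data_dir: str | Path) -> list[CrossSample]:
    data_dir = Path(data_dir)
    table = pd.read_csv(data_dir / "cross_samples.csv")
    samples = []
    for rec in table.itertuples():
        with Image.open(data_dir / rec.image_path) as im:
            crop = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
        samples.append(
            CrossSample(
                crop,
                rec.input_side,
                (float(rec.target_x_norm), float(rec.target_y_norm)),
                rec.source,
            )
        )
    return samples
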