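"""End-to-end synthetic study: train, calibrate, screen, score.

This driver reproduces the whole method on generated data: it trains a
direct-eye regressor and the two cross-eye regressors on normal
(non-deviated) synthetic pairs, calibrates the per-eye thresholds on
held-out normal clips, then screens fresh normal and strabismic clips and
reports sensitivity and specificity.  It is what the worked examples, the
acceptance machinery and several integration tests run.

Study conditions (the defaults below) are desk-scale: 3000 training pairs
rendered at 64 px with per-subject appearance variation, tiny-backbone
models trained for 80 epochs with the method's best optimizer/loss
combinations, 20 calibration clips and 20 + 20 test clips of 60 frames
each, and a persistent horizontal deviation of 0.15 crop widths (several
times the normal-pair residual scale) in the strabismic clips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .crossdata import (
    GROUND_TRUTH,
    CrossModelPair,
    EyePairSample,
    build_cross_samples,
    train_cross_models,
)
from .regression import (
    MseReport,
    RegressorConfig,
    TrainedRegressor,
    build_model,
    eval_samples,
    evaluate,
    train,
)
from .screening import (
    NORMAL,
    STRABISMUS,
    CalibrationStats,
    ModelBundle,
    VideoScreeningResult,
    calibrate,
    collect_distances,
    screen_video,
)
from .synth import (
    GazeSample,
    RenderedEyePair,
    StrabismusProfile,
    compose_face_frames,
    generate_clip,
    render_pair,
    sample_appearance,
)


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of the synthetic end-to-end study."""

    seed: int = 0
    input_size_px: int = 64
    n_train_pairs: int = 3000
    n_eval_pairs: int = 300
    n_calib_clips: int = 20
    n_normal_clips: int = 20
    n_strab_clips: int = 20
    frames_per_clip: int = 60
    deviation: float = 0.15
    gaze_spread: float = 0.06
    # desk-scale epochs preserving the published 250:325 direct-to-cross
    # training ratio (each cross model also sees half the direct model's
    # sample count, so it needs the longer schedule)
    epochs_direct: int = 80
    epochs_cross: int = 104


@dataclass
class StudyResult:
    direct: TrainedRegressor
    cross: CrossModelPair
    bundle: ModelBundle
    stats: CalibrationStats
    direct_report: MseReport
    cross_report: MseReport
    normal_results: list[VideoScreeningResult]
    strab_results: list[VideoScreeningResult]
    sensitivity: float
    specificity: float

    def summary(self) -> dict:
        return {
            "direct_holdout_mse_px2": self.direct_report.mse,
            "cross_holdout_mse_px2": self.cross_report.mse,
            "theta_left": self.stats.theta_left,
            "theta_right": self.stats.theta_right,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def generate_normal_pairs(
    n_pairs: int, size_px: int, seed: int, gaze_spread: float = 0.06
) -> list[RenderedEyePair]:
    """Independent normal pairs, each from its own simulated subject
    (appearance re-drawn per pair)."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        app = sample_appearance(rng)
        g = np.clip(rng.normal(0.0, gaze_spread, 2), -0.15, 0.15)
        gaze = GazeSample(gaze_x=float(g[0]), gaze_y=float(g[1]), frame_index=i)
        pairs.append(
            render_pair(gaze, app, size_px, seed=int(rng.integers(0, 2**31)))
        )
    return pairs


def _strab_profile(rng: np.random.Generator, deviation: float) -> StrabismusProfile:
    return StrabismusProfile(
        deviation_magnitude=deviation,
        deviation_direction=str(rng.choice(["eso", "exo"])),
        deviated_eye=str(rng.choice(["left", "right"])),
        active_fraction=1.0,
    )


def generate_study_clips(
    n_clips: int,
    frames_per_clip: int,
    size_px: int,
    seed: int,
    deviation: float = 0.0,
    gaze_spread: float = 0.06,
) -> list[list[RenderedEyePair]]:
    """Clips from distinct simulated subjects; a positive ``deviation``
    makes every clip strabismic (persistent, random laterality/direction)."""
    rng = np.random.default_rng(seed)
    clips = []
    for _ in range(n_clips):
        app = sample_appearance(rng)
        profile = _strab_profile(rng, deviation) if deviation > 0 else None
        clips.append(
            generate_clip(
                frames_per_clip,
                profile,
                app,
                size_px=size_px,
                gaze_spread=gaze_spread,
                seed=int(rng.integers(0, 2**31)),
            )
        )
    return clips


def train_study_models(
    pairs: Sequence[RenderedEyePair],
    input_size_px: int,
    epochs_direct: int,
    epochs_cross: int,
    seed: int,
) -> tuple[TrainedRegressor, CrossModelPair]:
    """Train the direct model (both eyes' crops) and the two cross models
    (ground-truth opposite-pupil targets) on normal pairs."""
    # batch 32: the MAE-driven optimizers need the extra gradient steps per
    # epoch to converge reliably at this sample count
    size_kw = dict(
        backbone="tiny",
        input_size_px=input_size_px,
        allow_any_input_size=True,
        batch_size=32,
    )
    direct_cfg = RegressorConfig.direct_default(
        epochs=epochs_direct, seed=seed, **size_kw
    )
    direct_samples = []
    for p in pairs:
        direct_samples.append((p.left_image, p.true_left_pupil))
        direct_samples.append((p.right_image, p.true_right_pupil))
    direct = train(build_model(direct_cfg), direct_samples, direct_cfg)

    cross_cfg = RegressorConfig.cross_default(
        epochs=epochs_cross, seed=seed + 1, **size_kw
    )
    cross_samples = build_cross_samples(
        [EyePairSample.from_rendered(p, i) for i, p in enumerate(pairs)],
        GROUND_TRUTH,
    )
    cross = train_cross_models(cross_samples, cross_cfg)
    return direct, cross


def calibrate_on_clips(
    clips: Sequence[Sequence[RenderedEyePair]],
    bundle: ModelBundle,
    K: float = 1.5,
    L: float = 1.5,
) -> CalibrationStats:
    """Per-video-mean calibration on normal clips."""
    left_means, right_means = [], []
    for clip in clips:
        frames = compose_face_frames(clip)
        records, _ = collect_distances(frames, "synthetic", bundle)
        left_means.append(float(np.mean([r.d_left for r in records])))
        right_means.append(float(np.mean([r.d_right for r in records])))
    return calibrate(
        left_means,
        right_means,
        K=K,
        L=L,
        unit_kind="video_mean",
        input_size_px=bundle.input_size_px,
    )


def screen_clips(
    clips: Sequence[Sequence[RenderedEyePair]],
    bundle: ModelBundle,
    stats: CalibrationStats,
    prefix: str = "clip",
) -> list[VideoScreeningResult]:
    return [
        screen_video(
            compose_face_frames(clip), "synthetic", bundle, stats, f"{prefix}{i:03d}"
        )
        for i, clip in enumerate(clips)
    ]


def run_study(cfg: StudyConfig) -> StudyResult:
    """Execute the full synthetic study and score the screener."""
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(6)]
    train_pairs = generate_normal_pairs(
        cfg.n_train_pairs, cfg.input_size_px, seeds[0], cfg.gaze_spread
    )
    direct, cross = train_study_models(
        train_pairs, cfg.input_size_px, cfg.epochs_direct, cfg.epochs_cross, seeds[1]
    )
    bundle = ModelBundle(direct=direct, cross=cross)

    eval_pairs = generate_normal_pairs(
        cfg.n_eval_pairs, cfg.input_size_px, seeds[2], cfg.gaze_spread
    )
    direct_report = evaluate(
        eval_samples(
            direct,
            [p.left_image for p in eval_pairs] + [p.right_image for p in eval_pairs],
            [p.true_left_pupil for p in eval_pairs]
            + [p.true_right_pupil for p in eval_pairs],
        )
    )
    cross_report = evaluate(
        eval_samples(
            cross.left_input,
            [p.left_image for p in eval_pairs],
            [p.true_right_pupil for p in eval_pairs],
        )
        + eval_samples(
            cross.right_input,
            [p.right_image for p in eval_pairs],
            [p.true_left_pupil for p in eval_pairs],
        )
    )

    calib_clips = generate_study_clips(
        cfg.n_calib_clips, cfg.frames_per_clip, cfg.input_size_px, seeds[3],
        gaze_spread=cfg.gaze_spread,
    )
    stats = calibrate_on_clips(calib_clips, bundle)

    normal_clips = generate_study_clips(
        cfg.n_normal_clips, cfg.frames_per_clip, cfg.input_size_px, seeds[4],
        gaze_spread=cfg.gaze_spread,
    )
    strab_clips = generate_study_clips(
        cfg.n_strab_clips, cfg.frames_per_clip, cfg.input_size_px, seeds[5],
        deviation=cfg.deviation, gaze_spread=cfg.gaze_spread,
    )
    normal_results = screen_clips(normal_clips, bundle, stats, "normal")
    strab_results = screen_clips(strab_clips, bundle, stats, "strab")

    sensitivity = float(
        np.mean([r.final_class == STRABISMUS for r in strab_results])
    )
    specificity = float(np.mean([r.final_class == NORMAL for r in normal_results]))
    return StudyResult(
        direct=direct,
        cross=cross,
        bundle=bundle,
        stats=stats,
        direct_report=direct_report,
        cross_report=cross_report,
        normal_results=normal_results,
        strab_results=strab_results,
        sensitivity=sensitivity,
        specificity=specificity,
    )
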