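"""Synthetic end-to-end benchmarks of tracking accuracy and pupil detection.

Two headline quantities are recomputed from scratch on the synthetic
generator:

* accuracy_benchmark — across-subject mean angular gaze error of the full
  calibrate-then-track pipeline: 8 synthetic subjects with distinct
  invertible quadratic true maps, a 9-mark x 60-frame calibration per
  subject (1 px nystagmus jitter, 5% blinks, default sensor noise), then a
  5x5 display grid with 20 frames per point; blink frames excluded.

* detection_benchmark — fraction of non-blink frames (default 1,000, default
  noise, uniformly random gazes) whose detected pupil center lies within
  5 px of the rendered ground truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .calibration import build_calibration
from .evaluation import evaluate_session
from .gaze import fit_from_calibration, track_session
from .geometry import DisplayGeometry
from .pupil import PupilDetector, detect_session
from .synthetic import (SceneConfig, render_frame,
                        simulate_calibration_session,
                        simulate_tracking_session, subject_true_map)

__all__ = ["accuracy_benchmark", "detection_benchmark"]


def accuracy_benchmark(n_subjects: int = 8, seed: int = 1,
                       jitter_sigma_px: float = 1.0, blink_prob: float = 0.05,
                       grid_n: int = 5, frames_per_point: int = 20,
                       frames_per_mark: int = 60) -> dict:
    """Across-subject mean angular error (degrees) of the full pipeline.

    Subject identities (their true gaze->pupil maps) use seeds 1..n_subjects;
    all rendering randomness derives from `seed`.
    """
    geometry = DisplayGeometry()
    detector = PupilDetector()
    xs = np.linspace(geometry.width_px * 0.1, geometry.width_px * 0.9, grid_n)
    ys = np.linspace(geometry.height_px * 0.1, geometry.height_px * 0.9, grid_n)
    path = [(float(x), float(y)) for y in ys for x in xs
            for _ in range(frames_per_point)]

    subject_means = []
    n_frames = 0
    for subject in range(1, n_subjects + 1):
        cfg = SceneConfig(
            true_map_coeffs=tuple(subject_true_map(subject)),
            jitter_sigma_px=jitter_sigma_px, blink_prob=blink_prob,
            seed=(seed * 1_000_003 + subject * 101) % (2 ** 31))
        cal_session = simulate_calibration_session(
            cfg, frames_per_mark=frames_per_mark, display=geometry)
        obs = detect_session(cal_session, detector)
        calibration = build_calibration(obs, cal_session.manifest)
        model = fit_from_calibration(calibration, geometry)

        eval_cfg = dataclasses.replace(
            cfg, seed=(seed * 2_000_029 + subject * 211) % (2 ** 31))
        session = simulate_tracking_session(eval_cfg, path, display=geometry)
        gaze = track_session(session, calibration, model, detector)
        report = evaluate_session(gaze, session.manifest, geometry)
        subject_means.append(report.session_mean_deg)
        n_frames += report.n_frames
    return {
        "mean_error_deg": float(np.mean(subject_means)),
        "subject_means_deg": subject_means,
        "n_frames": n_frames,
        "n_subjects": n_subjects,
    }


def detection_benchmark(n_frames: int = 1000, seed: int = 1,
                        tolerance_px: float = 5.0) -> dict:
    """Percentage of non-blink frames with center error <= tolerance_px."""
    geometry = DisplayGeometry()
    cfg = SceneConfig(seed=seed)
    detector = PupilDetector()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_frames):
        gaze = (rng.uniform(0, geometry.width_px),
                rng.uniform(0, geometry.height_px))
        frame = render_frame(cfg, gaze, blink=False, rng=rng,
                             display=geometry)
        obs = detector.detect(frame)
        if obs.is_blink:
            continue
        err = np.hypot(obs.center_px[0] - frame.truth.pupil_xy[0],
                       obs.center_px[1] - frame.truth.pupil_xy[1])
        hits += err <= tolerance_px
    return {"detection_rate_pct": 100.0 * hits / n_frames,
            "n_frames": n_frames, "tolerance_px": tolerance_px}
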