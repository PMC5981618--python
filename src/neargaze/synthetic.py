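"""Synthetic near-eye infrared frame renderer with ground-truth annotation.

Emulates the imaging regime of a head-mounted dark-pupil IR tracker: a dark
elliptical pupil inside a darker-than-sclera iris, bright corneal glints,
eyelid-occlusion blinks, frame-to-frame nystagmus jitter of the pupil
center, and additive sensor noise.  The true gaze->pupil-center relation is
a known, mildly non-linear (quadratic) invertible map, so calibration-model
recovery is a well-posed test.

Everything is deterministic given (config, inputs, seed): identical calls
produce bit-identical frames and manifests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from ._quad import apply_quad_map
from .geometry import CalibrationMark, DisplayGeometry, default_mark_layout

__all__ = [
    "SceneConfig",
    "FrameTruth",
    "EyeFrame",
    "Session",
    "default_true_map",
    "subject_true_map",
    "render_frame",
    "simulate_calibration_session",
    "simulate_tracking_session",
]

# 8-bit intensity palette (before noise): dark pupil under IR illumination.
SCLERA, IRIS, PUPIL, GLINT, EYELID = 200.0, 120.0, 20.0, 250.0, 160.0

# Fraction of the vertical pupil semi-axis below the pupil center still covered
# by the eyelid band during a blink; t = 0.6 occludes ~86% of the pupil area.
_BLINK_COVER_T = 0.6

_FRAME_RATE_HZ = 60.0


def _centered_quad(neutral: tuple[float, float],
                   gains: tuple[float, float],
                   quads: Sequence[float],
                   display: DisplayGeometry) -> np.ndarray:
    """Expand a display-center-relative quadratic into raw-coordinate coeffs.

    px = nx + gx*(X-cx) + qa*(X-cx)^2 + qb*(Y-cy)^2 + qe*(X-cx)(Y-cy), and
    likewise for py, where (cx, cy) is the display center.  Returns the 12
    coefficients of the equivalent raw-coordinate quadratic.
    """
    cx, cy = display.width_px / 2.0, display.height_px / 2.0
    out = np.zeros(12)
    for axis in range(2):
        n = neutral[axis]
        g = gains[axis]
        qa, qb, qe = quads[3 * axis: 3 * axis + 3]
        a, b, e = qa, qb, qe
        c = (g if axis == 0 else 0.0) - 2 * qa * cx - qe * cy
        d = (g if axis == 1 else 0.0) - 2 * qb * cy - qe * cx
        f = (n - (g * cx if axis == 0 else g * cy)
             + qa * cx * cx + qb * cy * cy + qe * cx * cy)
        out[6 * axis: 6 * axis + 6] = (a, b, c, d, e, f)
    return out


def default_true_map(display: DisplayGeometry | None = None) -> np.ndarray:
    """Default ground-truth display->pupil quadratic map.

    Gains give an eye moveable region of roughly +/-87 px horizontally and
    +/-68 px vertically around the neutral pupil position (320, 240) in a
    640x480 frame — the horizontal excursion exceeds the vertical one, as it
    does for a real eye.  Quadratic terms add a few px of smooth optical
    distortion, keeping the map invertible over the display rectangle.
    """
    display = display or DisplayGeometry()
    return _centered_quad(
        neutral=(320.0, 240.0),
        gains=(0.17, 0.19),
        quads=(1.5e-5, -0.8e-5, 0.6e-5,   # px: qa, qb, qe
               -0.7e-5, 1.2e-5, -0.5e-5),  # py
        display=display,
    )


def subject_true_map(seed: int, display: DisplayGeometry | None = None) -> np.ndarray:
    """A per-subject ground-truth map: default gains/curvature jittered ~10%."""
    display = display or DisplayGeometry()
    rng = np.random.default_rng(seed)
    neutral = (320.0 + rng.uniform(-10, 10), 240.0 + rng.uniform(-8, 8))
    gains = (0.17 * rng.uniform(0.9, 1.1), 0.19 * rng.uniform(0.9, 1.1))
    quads = tuple(rng.uniform(-2e-5, 2e-5) for _ in range(4)) + \
        tuple(rng.uniform(-1e-5, 1e-5) for _ in range(2))
    quads = (quads[0], quads[1], quads[4], quads[2], quads[3], quads[5])
    return _centered_quad(neutral, gains, quads, display)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic eye scene.

    Defaults state the nominal recording conditions: a 640x480 eye camera,
    pupil semi-axis 30 px, 1 px nystagmus jitter, 5% blink probability, two
    corneal glints, and sigma = 6 grey-level sensor noise.
    """

    frame_width: int = 640
    frame_height: int = 480
    true_map_coeffs: tuple[float, ...] = field(
        default_factory=lambda: tuple(default_true_map()))
    pupil_radius_px: float = 30.0
    iris_radius_px: float = 80.0
    jitter_sigma_px: float = 1.0
    blink_prob: float = 0.05
    glint_count: int = 2
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma_px < 0:
            raise ValueError("jitter_sigma_px must be >= 0")
        if not 0.0 <= self.blink_prob <= 1.0:
            raise ValueError("blink_prob must be in [0, 1]")
        if self.pupil_radius_px <= 0:
            raise ValueError("pupil_radius_px must be > 0")
        if len(self.true_map_coeffs) != 12:
            raise ValueError("true_map_coeffs must have 12 entries")

    def true_pupil_center(self, gaze_x: float, gaze_y: float) -> tuple[float, float]:
        """Noise-free pupil-center image position for a display gaze point."""
        px, py = apply_quad_map(np.asarray(self.true_map_coeffs), gaze_x, gaze_y)
        return float(px[0]), float(py[0])


@dataclass(frozen=True)
class FrameTruth:
    pupil_xy: tuple[float, float]
    gaze_xy: tuple[float, float]
    blink: bool


@dataclass
class EyeFrame:
    """One grayscale near-eye frame with optional ground-truth annotation."""

    image: np.ndarray  # uint8, (height, width)
    timestamp_ms: float = 0.0
    truth: FrameTruth | None = None


@dataclass
class Session:
    """A rendered recording: frames plus a manifest describing each frame.

    Manifest columns: frame_path, timestamp_ms, mark_index (NaN for free
    tracking), true_gaze_x/y, true_pupil_x/y, blink (0/1).
    """

    frames: list[EyeFrame]
    manifest: pd.DataFrame
    config: SceneConfig

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for frame, path in zip(self.frames, self.manifest["frame_path"]):
            iio.imwrite(out / path, frame.image)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        return out

    @staticmethod
    def load(session_dir: str | Path) -> "Session":
        d = Path(session_dir)
        manifest = pd.read_csv(d / "manifest.csv")
        frames = []
        for _, row in manifest.iterrows():
            img = iio.imread(d / row["frame_path"])
            truth = FrameTruth(
                pupil_xy=(row["true_pupil_x"], row["true_pupil_y"]),
                gaze_xy=(row["true_gaze_x"], row["true_gaze_y"]),
                blink=bool(row["blink"]),
            )
            frames.append(EyeFrame(image=img, timestamp_ms=row["timestamp_ms"],
                                   truth=truth))
        return Session(frames=frames, manifest=manifest, config=SceneConfig())


_GRID_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _pixel_grid(w: int, h: int) -> tuple[np.ndarray, np.ndarray]:
    if (w, h) not in _GRID_CACHE:
        yy, xx = np.mgrid[0:h, 0:w]
        _GRID_CACHE[(w, h)] = (xx.astype(float), yy.astype(float))
    return _GRID_CACHE[(w, h)]


def render_frame(config: SceneConfig, gaze: Sequence[float], *,
                 blink: bool = False,
                 rng: np.random.Generator | None = None,
                 display: DisplayGeometry | None = None,
                 timestamp_ms: float = 0.0) -> EyeFrame:
    """Render one annotated frame for a display gaze point.

    The pupil is drawn as a filled dark ellipse at true_map(gaze) + jitter;
    its minor axis shrinks with eccentricity from the image center
    (perspective foreshortening of an off-axis circular pupil).  A blink
    replaces at least 80% of the pupil with an eyelid band.
    """
    display = display or DisplayGeometry()
    gx, gy = float(gaze[0]), float(gaze[1])
    if not display.contains(gx, gy):
        raise ValueError(f"gaze ({gx}, {gy}) outside the display rectangle")
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    cx0, cy0 = config.true_pupil_center(gx, gy)
    jx, jy = (rng.normal(0.0, config.jitter_sigma_px, size=2)
              if config.jitter_sigma_px > 0 else (0.0, 0.0))
    cx, cy = cx0 + jx, cy0 + jy

    w, h = config.frame_width, config.frame_height
    xx, yy = _pixel_grid(w, h)
    img = np.full((h, w), SCLERA)

    # iris moves rigidly with the pupil
    iris = (xx - cx) ** 2 + (yy - cy) ** 2 <= config.iris_radius_px ** 2
    img[iris] = IRIS

    # foreshortened pupil ellipse: minor axis along the radial direction
    icx, icy = w / 2.0, h / 2.0
    dx, dy = cx - icx, cy - icy
    dist = np.hypot(dx, dy)
    dmax = np.hypot(icx, icy)
    minor_scale = 1.0 - 0.2 * (dist / dmax) ** 2
    theta = np.arctan2(dy, dx) if dist > 1e-9 else 0.0
    a_ax = config.pupil_radius_px            # tangential semi-axis
    b_ax = config.pupil_radius_px * minor_scale  # radial semi-axis
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    pupil = (u / b_ax) ** 2 + (v / a_ax) ** 2 <= 1.0
    img[pupil] = PUPIL

    # corneal glints: small bright disks riding on the pupil/iris
    glint_offsets = [(-10.0, -8.0), (12.0, 6.0), (-4.0, 12.0), (8.0, -12.0)]
    for k in range(config.glint_count):
        ox, oy = glint_offsets[k % len(glint_offsets)]
        g = (xx - (cx + ox)) ** 2 + (yy - (cy + oy)) ** 2 <= 4.0 ** 2
        img[g] = GLINT

    if blink:
        # eyelid band from the image top down past the pupil center
        lid_edge = cy + _BLINK_COVER_T * a_ax
        img[yy <= lid_edge] = EYELID

    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = FrameTruth(pupil_xy=(cx, cy), gaze_xy=(gx, gy), blink=blink)
    return EyeFrame(image=img, timestamp_ms=timestamp_ms, truth=truth)


def _session_from_plan(config: SceneConfig,
                       plan: list[tuple[float, float, object]],
                       display: DisplayGeometry,
                       rng: np.random.Generator) -> Session:
    frames: list[EyeFrame] = []
    rows = []
    dt = 1000.0 / _FRAME_RATE_HZ
    for i, (gx, gy, mark_index) in enumerate(plan):
        blink = bool(rng.random() < config.blink_prob)
        frame = render_frame(config, (gx, gy), blink=blink, rng=rng,
                             display=display, timestamp_ms=i * dt)
        frames.append(frame)
        t = frame.truth
        rows.append({
            "frame_path": f"frame_{i:05d}.png",
            "timestamp_ms": frame.timestamp_ms,
            "mark_index": mark_index,
            "true_gaze_x": t.gaze_xy[0], "true_gaze_y": t.gaze_xy[1],
            "true_pupil_x": t.pupil_xy[0], "true_pupil_y": t.pupil_xy[1],
            "blink": int(t.blink),
        })
    manifest = pd.DataFrame(rows, columns=[
        "frame_path", "timestamp_ms", "mark_index", "true_gaze_x",
        "true_gaze_y", "true_pupil_x", "true_pupil_y", "blink"])
    return Session(frames=frames, manifest=manifest, config=config)


def simulate_calibration_session(config: SceneConfig,
                                 marks: Sequence[CalibrationMark] | None = None,
                                 frames_per_mark: int = 60,
                                 display: DisplayGeometry | None = None) -> Session:
    """Render a nine-mark calibration recording: 60 frames per mark by default.

    Each mark contributes `frames_per_mark` frames at its gaze position with
    independent jitter and blink draws, emulating a 2 s fixation dwell.
    """
    display = display or DisplayGeometry()
    marks = list(marks) if marks is not None else default_mark_layout(display)
    if not marks:
        raise ValueError("marks must be non-empty")
    rng = np.random.default_rng(config.seed)
    plan = [(m.position_px[0], m.position_px[1], m.index)
            for m in marks for _ in range(frames_per_mark)]
    return _session_from_plan(config, plan, display, rng)


def simulate_tracking_session(config: SceneConfig,
                              gaze_path: Sequence[Sequence[float]],
                              display: DisplayGeometry | None = None,
                              seed: int | None = None) -> Session:
    """Render a free-gaze recording: one frame per gaze-path point."""
    display = display or DisplayGeometry()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    plan = [(float(p[0]), float(p[1]), np.nan) for p in gaze_path]
    return _session_from_plan(config, plan, display, rng)
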