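"""Angular-accuracy evaluation of tracked sessions.

Per-frame error is the visual angle alpha = atan(h / H) between estimated
and true gaze, with h the planar offset on the display (cm, anisotropic
pixel pitch) and H the viewing distance.  Reports aggregate per zone
(calibration-style sessions), per axis (horizontal/vertical, each converted
through its own pixel pitch), and over the whole session.  Blink frames
never enter any average.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import build_calibration
from .classification import BLINK
from .geometry import DisplayGeometry
from .gaze import fit_from_calibration, track_session
from .pupil import PupilDetector, detect_session
from .synthetic import SceneConfig, Session, simulate_calibration_session, \
    simulate_tracking_session

__all__ = ["EvalReport", "evaluate_session", "per_frame_errors",
           "repeated_use_protocol"]


@dataclass
class EvalReport:
    """Session-level angular-error summary.

    per_zone_deg maps zone index -> mean angular error over that zone's
    frames (only for sessions whose manifest carries mark indices);
    per_axis_deg is (horizontal, vertical) mean error with each axis
    converted through its own pixel pitch; session_mean_deg averages over
    all measurable (non-blink, truth-matched) frames.
    """

    session_mean_deg: float
    per_axis_deg: tuple[float, float]
    per_zone_deg: dict[int, float] = field(default_factory=dict)
    n_frames: int = 0
    n_blinks_excluded: int = 0

    def to_text(self) -> str:
        lines = [f"frames evaluated: {self.n_frames}",
                 f"blink frames excluded: {self.n_blinks_excluded}",
                 f"session mean error: {self.session_mean_deg:.4f} deg",
                 f"horizontal mean error: {self.per_axis_deg[0]:.4f} deg",
                 f"vertical mean error: {self.per_axis_deg[1]:.4f} deg"]
        for z in sorted(self.per_zone_deg):
            lines.append(f"zone {z}: {self.per_zone_deg[z]:.4f} deg")
        return "\n".join(lines) + "\n"

    def per_zone_frame(self) -> pd.DataFrame:
        """Per-zone table in the usual layout: zones 1-9 then the average."""
        rows = [{"zone": str(z), "mean_error_deg": e}
                for z, e in sorted(self.per_zone_deg.items())]
        rows.append({"zone": "average", "mean_error_deg": self.session_mean_deg})
        return pd.DataFrame(rows)


def per_frame_errors(gaze: pd.DataFrame, manifest: pd.DataFrame,
                     geometry: DisplayGeometry | None = None) -> pd.DataFrame:
    """Per-frame angular errors for all measurable frames.

    Returns columns frame_path, mark_index, err_deg, err_h_deg, err_v_deg.
    Raises if any non-blink gaze row has no truth row to match.
    """
    g = geometry or DisplayGeometry()
    measurable = gaze[gaze["coarse_zone"].astype(str) != BLINK]
    merged = measurable.merge(manifest, on="frame_path", how="left")
    missing = merged[merged["true_gaze_x"].isna()]["frame_path"].tolist()
    if missing:
        raise ValueError(f"gaze rows without matching truth: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    dx_cm = (merged["gaze_x"] - merged["true_gaze_x"]) * g.px_pitch_x_cm
    dy_cm = (merged["gaze_y"] - merged["true_gaze_y"]) * g.px_pitch_y_cm
    H = g.viewing_distance_cm
    out = pd.DataFrame({
        "frame_path": merged["frame_path"],
        "mark_index": merged.get("mark_index"),
        "err_deg": np.degrees(np.arctan(np.hypot(dx_cm, dy_cm) / H)),
        "err_h_deg": np.degrees(np.arctan(np.abs(dx_cm) / H)),
        "err_v_deg": np.degrees(np.arctan(np.abs(dy_cm) / H)),
    })
    return out


def evaluate_session(gaze: pd.DataFrame, manifest: pd.DataFrame,
                     geometry: DisplayGeometry | None = None) -> EvalReport:
    """Aggregate per-frame angular errors into an EvalReport."""
    errs = per_frame_errors(gaze, manifest, geometry)
    if errs.empty:
        raise ValueError("no measurable frames: session is all blinks")
    n_blinks = int((gaze["coarse_zone"].astype(str) == BLINK).sum())
    per_zone: dict[int, float] = {}
    if errs["mark_index"].notna().any():
        for z, grp in errs[errs["mark_index"].notna()].groupby(
                errs["mark_index"].astype("Int64")):
            per_zone[int(z)] = float(grp["err_deg"].mean())
    return EvalReport(
        session_mean_deg=float(errs["err_deg"].mean()),
        per_axis_deg=(float(errs["err_h_deg"].mean()),
                      float(errs["err_v_deg"].mean())),
        per_zone_deg=per_zone,
        n_frames=int(len(errs)),
        n_blinks_excluded=n_blinks)


def _eval_grid(geometry: DisplayGeometry, n: int = 5,
               margin_frac: float = 0.1) -> list[tuple[float, float]]:
    xs = np.linspace(geometry.width_px * margin_frac,
                     geometry.width_px * (1 - margin_frac), n)
    ys = np.linspace(geometry.height_px * margin_frac,
                     geometry.height_px * (1 - margin_frac), n)
    return [(float(x), float(y)) for y in ys for x in xs]


def repeated_use_protocol(config: SceneConfig, n_sessions: int = 4,
                          rewear_offset_px: float = 2.0,
                          frames_per_point: int = 8,
                          grid_n: int = 4,
                          frames_per_mark: int = 60,
                          geometry: DisplayGeometry | None = None,
                          detector: PupilDetector | None = None,
                          seed: int = 0) -> dict:
    """Calibration-free reuse: calibrate once, track several later sessions.

    One calibration session is rendered and a gaze model fitted.  Then
    `n_sessions` fresh tracking sessions are rendered with new seeds and a
    per-session constant "re-wear" shift of the true pupil positions (the
    headset never sits in exactly the same place twice), all evaluated
    against the single fixed model.  Returns per-session and overall mean
    errors in degrees.
    """
    geometry = geometry or DisplayGeometry()
    detector = detector or PupilDetector()
    rng = np.random.default_rng(seed)

    cal_session = simulate_calibration_session(
        config, frames_per_mark=frames_per_mark, display=geometry)
    obs = detect_session(cal_session, detector)
    calibration = build_calibration(obs, cal_session.manifest)
    model = fit_from_calibration(calibration, geometry)

    grid = _eval_grid(geometry, n=grid_n)
    path = [p for p in grid for _ in range(frames_per_point)]
    session_means = []
    for s in range(n_sessions):
        angle = rng.uniform(0, 2 * math.pi)
        shift = (rewear_offset_px * math.cos(angle),
                 rewear_offset_px * math.sin(angle))
        coeffs = np.asarray(config.true_map_coeffs, dtype=float)
        coeffs = coeffs.copy()
        coeffs[5] += shift[0]   # constant term of the x map
        coeffs[11] += shift[1]  # constant term of the y map
        sess_cfg = dataclasses.replace(config, true_map_coeffs=tuple(coeffs),
                                       seed=int(rng.integers(2 ** 31)))
        session = simulate_tracking_session(sess_cfg, path, display=geometry)
        gaze = track_session(session, calibration, model, detector)
        report = evaluate_session(gaze, session.manifest, geometry)
        session_means.append(report.session_mean_deg)
    return {"session_means_deg": session_means,
            "overall_mean_deg": float(np.mean(session_means)),
            "rewear_offset_px": rewear_offset_px}


def write_report(report: EvalReport, path: str | Path,
                 zone_csv: str | Path | None = None) -> None:
    Path(path).write_text(report.to_text())
    if zone_csv is not None and report.per_zone_deg:
        report.per_zone_frame().to_csv(zone_csv, index=False)
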