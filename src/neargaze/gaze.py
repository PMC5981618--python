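"""Second-order polynomial mapping from pupil centers to display gaze.

The fine gaze stage is a pair of full bivariate quadratics

    D(x) = a*x^2 + b*y^2 + c*x + d*y + e*x*y + f
    D(y) = g*x^2 + h*y^2 + i*x + j*y + k*x*y + l

with (x, y) the pupil center in image pixels and D the gaze point in
display pixels.  The 12 coefficients are fitted by ordinary least squares
on the nine (MC'_i, mark position) calibration pairs — six unknowns per
axis, nine equations.  At run time a frame is gated for blinks, classified
into a coarse zone, and mapped through the polynomial; the polynomial
output is always the final gaze, the coarse label only annotates
confidence (ok / zone_mismatch) and gates blinks.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._quad import apply_quad_map, quad_design
from .calibration import CalibrationSet
from .classification import BLINK, CoarseLabel, NearestCenterZoneClassifier, classify_coarse
from .geometry import DisplayGeometry, default_mark_layout
from .pupil import PupilDetector, detect_session
from .synthetic import EyeFrame, Session

__all__ = ["PolynomialGazeRegressor", "GazeModel", "GazeEstimate",
           "fit_gaze_model", "predict_gaze", "estimate", "track_session"]


class PolynomialGazeRegressor(BaseEstimator, RegressorMixin):
    """Least-squares second-order 2-D -> 2-D gaze regressor.

    Fits two independent 6-coefficient quadratics (one per display axis) to
    (pupil center, display target) pairs.  Raw pixel coordinates are used
    without normalization; a condition-number warning is emitted above 1e8.

    Attributes (after fit)
    ----------------------
    coeffs_x_, coeffs_y_ : ndarray, shape (6,)
        Coefficients (a..f) and (g..l) in the order [x^2, y^2, x, y, xy, 1].
    residual_px_ : float
        RMS residual at the calibration points, in display pixels.
    """

    def __init__(self, cond_warn: float = 1e8):
        self.cond_warn = cond_warn

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2) pupil centers")
        if y.shape != X.shape:
            raise ValueError("y must be (n, 2) display targets")
        if len(X) < 6:
            raise ValueError(f"need >= 6 calibration pairs, got {len(X)}")
        A = quad_design(X[:, 0], X[:, 1])
        rank = np.linalg.matrix_rank(A)
        if rank < 6:
            raise ValueError(
                f"degenerate calibration geometry: design matrix rank {rank} < 6 "
                "(pupil centers are collinear or otherwise non-generic)")
        cond = np.linalg.cond(A)
        if cond > self.cond_warn:
            warnings.warn(f"ill-conditioned gaze fit: cond(A) = {cond:.3g}",
                          RuntimeWarning, stacklevel=2)
        coeffs, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.coeffs_x_ = coeffs[:, 0]
        self.coeffs_y_ = coeffs[:, 1]
        resid = A @ coeffs - y
        self.residual_px_ = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "coeffs_x_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        coeffs = np.concatenate([self.coeffs_x_, self.coeffs_y_])
        gx, gy = apply_quad_map(coeffs, X[:, 0], X[:, 1])
        return np.column_stack([gx, gy])


@dataclass
class GazeModel:
    """A fitted gaze map: 12 coefficients plus the display geometry."""

    coeffs_x: np.ndarray
    coeffs_y: np.ndarray
    geometry: DisplayGeometry
    fit_residual_px: float
    calibration_checksum: str = ""

    def predict(self, centers) -> np.ndarray:
        coeffs = np.concatenate([np.asarray(self.coeffs_x),
                                 np.asarray(self.coeffs_y)])
        X = np.atleast_2d(np.asarray(centers, dtype=float))
        gx, gy = apply_quad_map(coeffs, X[:, 0], X[:, 1])
        return np.column_stack([gx, gy])

    def save(self, path: str | Path) -> None:
        g = self.geometry
        doc = {
            "coeffs_x": [float(v) for v in self.coeffs_x],
            "coeffs_y": [float(v) for v in self.coeffs_y],
            "geometry": {"width_px": g.width_px, "height_px": g.height_px,
                         "width_cm": g.width_cm, "height_cm": g.height_cm,
                         "viewing_distance_cm": g.viewing_distance_cm},
            "fit_residual_px": float(self.fit_residual_px),
            "calibration_checksum": self.calibration_checksum,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @staticmethod
    def load(path: str | Path) -> "GazeModel":
        doc = yaml.safe_load(Path(path).read_text())
        return GazeModel(
            coeffs_x=np.asarray(doc["coeffs_x"], dtype=float),
            coeffs_y=np.asarray(doc["coeffs_y"], dtype=float),
            geometry=DisplayGeometry(**doc["geometry"]),
            fit_residual_px=float(doc["fit_residual_px"]),
            calibration_checksum=doc.get("calibration_checksum", ""))


@dataclass(frozen=True)
class GazeEstimate:
    """Final per-frame gaze: fine point, coarse label, and a confidence tag.

    confidence is "blink" (no point), "ok" (fine point's nearest zone agrees
    with the coarse label) or "zone_mismatch" (they disagree; the fine point
    is still the returned gaze).
    """

    point: tuple[float, float] | None
    coarse: CoarseLabel
    confidence: str


def fit_gaze_model(pairs: Sequence[tuple[Sequence[float], Sequence[float]]],
                   geometry: DisplayGeometry | None = None,
                   calibration_checksum: str = "") -> GazeModel:
    """Fit the quadratic gaze map from (MC'_i, mark position) pairs."""
    geometry = geometry or DisplayGeometry()
    centers = np.asarray([p[0] for p in pairs], dtype=float)
    targets = np.asarray([p[1] for p in pairs], dtype=float)
    reg = PolynomialGazeRegressor().fit(centers, targets)
    return GazeModel(coeffs_x=reg.coeffs_x_, coeffs_y=reg.coeffs_y_,
                     geometry=geometry, fit_residual_px=reg.residual_px_,
                     calibration_checksum=calibration_checksum)


def fit_from_calibration(calibration: CalibrationSet,
                         geometry: DisplayGeometry | None = None,
                         marks=None) -> GazeModel:
    """Fit the gaze map from a CalibrationSet and the mark layout."""
    geometry = geometry or DisplayGeometry()
    marks = marks if marks is not None else default_mark_layout(geometry)
    by_index = {m.index: m.position_px for m in marks}
    pairs = [(calibration.zones[z].filtered_mean, by_index[z])
             for z in calibration.zone_ids()]
    checksum = hashlib.sha256(
        np.ascontiguousarray(calibration.mean_centers()).tobytes()).hexdigest()[:16]
    return fit_gaze_model(pairs, geometry, calibration_checksum=checksum)


def predict_gaze(model: GazeModel, center: Sequence[float]) -> tuple[float, float]:
    """Evaluate the fitted map at one pupil center; never clamped."""
    out = model.predict([center])[0]
    return float(out[0]), float(out[1])


def _zone_of_display_point(point, marks) -> int:
    d = [np.hypot(point[0] - m.position_px[0], point[1] - m.position_px[1])
         for m in marks]
    return marks[int(np.argmin(d))].index


def estimate(frame: EyeFrame, calibration: CalibrationSet, model: GazeModel,
             detector: PupilDetector | None = None) -> GazeEstimate:
    """Full per-frame pipeline: detect, gate blinks, classify, map."""
    obs = (detector or PupilDetector()).detect(frame)
    if obs.is_blink:
        return GazeEstimate(point=None, coarse=CoarseLabel(zone=None),
                            confidence="blink")
    coarse = classify_coarse(obs, calibration)
    point = predict_gaze(model, obs.center_px)
    marks = default_mark_layout(model.geometry)
    fine_zone = _zone_of_display_point(point, marks)
    conf = "ok" if fine_zone == coarse.zone else "zone_mismatch"
    return GazeEstimate(point=point, coarse=coarse, confidence=conf)


def track_session(session: Session, calibration: CalibrationSet,
                  model: GazeModel,
                  detector: PupilDetector | None = None,
                  observations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Batch tracking: gaze CSV rows for every frame of a session.

    Columns: frame_path, gaze_x, gaze_y, coarse_zone ("1".."9" or "blink"),
    confidence.  Detection can be supplied precomputed via `observations`.
    """
    obs = observations if observations is not None \
        else detect_session(session, detector)
    clf = NearestCenterZoneClassifier.from_calibration(calibration)
    marks = default_mark_layout(model.geometry)
    rows = []
    for _, r in obs.iterrows():
        if r["blink"] == 1 or not np.isfinite(r["pupil_x"]):
            rows.append({"frame_path": r["frame_path"], "gaze_x": np.nan,
                         "gaze_y": np.nan, "coarse_zone": BLINK,
                         "confidence": "blink"})
            continue
        center = (r["pupil_x"], r["pupil_y"])
        zone = int(clf.predict([center])[0])
        point = predict_gaze(model, center)
        fine_zone = _zone_of_display_point(point, marks)
        rows.append({"frame_path": r["frame_path"],
                     "gaze_x": point[0], "gaze_y": point[1],
                     "coarse_zone": str(zone),
                     "confidence": "ok" if fine_zone == zone else "zone_mismatch"})
    return pd.DataFrame(rows, columns=["frame_path", "gaze_x", "gaze_y",
                                       "coarse_zone", "confidence"])
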