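"""Pupil-center detection and blink flagging on dark-pupil IR frames.

The detector follows the classic model-based pipeline for head-mounted
trackers: smooth, localize the darkest compact region, extract sub-pixel
edge points around it, and fit an ellipse by random-sample consensus so
that glints, eyelid edges and noise on the boundary are rejected as
outliers.  The pupil center is the center of the consensus ellipse.

A frame is flagged as a blink when the dark region is too small, the fit
has too little inlier support, or the fitted boundary is covered by inliers
over too small an angular range (an eyelid hides most of the pupil arc).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import EllipseModel, find_contours, label, ransac, regionprops

from .synthetic import EyeFrame, Session

__all__ = ["PupilObservation", "PupilDetector", "detect_pupil", "detect_session"]


@dataclass(frozen=True)
class PupilObservation:
    """Detected pupil for one frame.

    center_px is sub-pixel (x, y) in image coordinates; quality is the
    inlier fraction of the consensus ellipse fit in [0, 1]; is_blink marks
    frames without a usable pupil.
    """

    center_px: tuple[float, float] | None
    ellipse: tuple[tuple[float, float], tuple[float, float], float] | None
    quality: float
    is_blink: bool


_BLINK = PupilObservation(center_px=None, ellipse=None, quality=0.0, is_blink=True)


class PupilDetector:
    """Consensus ellipse-fit pupil detector.

    Parameters
    ----------
    expected_radius_px : float
        Nominal pupil semi-axis; sets the minimum-area blink threshold and
        the minimum acceptable frame size.
    min_area_frac : float
        Blink if the dark region's area falls below this fraction of the
        nominal pupil area (pi * expected_radius^2).
    q_min : float
        Blink if the inlier fraction of the ellipse fit falls below this.
    coverage_min : float
        Blink if inlier edge points cover less than this fraction of the
        fitted ellipse's angular range (eyelid leaves only a short arc).
    residual_threshold_px : float
        Inlier distance for the consensus fit.
    smooth_sigma : float
        Gaussian pre-smoothing applied to the working region.
    seed : int
        Internal RNG seed of the consensus fit; fixed for reproducibility.
    """

    def __init__(self, expected_radius_px: float = 30.0,
                 min_area_frac: float = 0.30, q_min: float = 0.4,
                 coverage_min: float = 0.65,
                 residual_threshold_px: float = 1.5,
                 smooth_sigma: float = 2.0, max_trials: int = 40,
                 seed: int = 0):
        self.expected_radius_px = expected_radius_px
        self.min_area_frac = min_area_frac
        self.q_min = q_min
        self.coverage_min = coverage_min
        self.residual_threshold_px = residual_threshold_px
        self.smooth_sigma = smooth_sigma
        self.max_trials = max_trials
        self.seed = seed

    # -- public API --------------------------------------------------------

    def detect(self, frame: EyeFrame | np.ndarray) -> PupilObservation:
        img = frame.image if isinstance(frame, EyeFrame) else frame
        img = np.asarray(img)
        if img.ndim != 2 or img.size == 0:
            raise ValueError("frame must be a non-empty single-channel image")
        if min(img.shape) < 4 * self.expected_radius_px:
            raise ValueError(
                f"frame {img.shape} smaller than twice the expected pupil "
                f"diameter ({4 * self.expected_radius_px:.0f} px)")

        region = self._coarse_localize(img)
        if region is None:
            return _BLINK
        roi, (x0, y0), thr, area = region
        if area < self.min_area_frac * np.pi * self.expected_radius_px ** 2:
            return _BLINK

        pts = self._edge_points(roi, thr)
        if pts is None or len(pts) < 10:
            return _BLINK
        fit = self._consensus_fit(pts)
        if fit is None:
            return _BLINK
        model, quality, coverage = fit
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
        center = (float(xc + x0), float(yc + y0))
        is_blink = quality < self.q_min or coverage < self.coverage_min
        if is_blink:
            return PupilObservation(center_px=None, ellipse=None,
                                    quality=float(quality), is_blink=True)
        h, w = img.shape
        if not (0 <= center[0] < w and 0 <= center[1] < h):
            return _BLINK
        return PupilObservation(
            center_px=center,
            ellipse=(center, (float(a), float(b)), float(theta)),
            quality=float(quality), is_blink=False)

    def blink_test(self, dark_area_px: float, fit_quality: float,
                   coverage: float = 1.0) -> bool:
        """Blink iff the dark area, fit support, or arc coverage is too low."""
        return (dark_area_px < self.min_area_frac * np.pi * self.expected_radius_px ** 2
                or fit_quality < self.q_min or coverage < self.coverage_min)

    # -- pipeline stages ---------------------------------------------------

    def _coarse_localize(self, img: np.ndarray):
        """Find the darkest compact region; return its padded ROI.

        Works on a 4x-downsampled, lightly smoothed copy; the threshold sits
        between the pupil intensity (image minimum) and the bulk of the
        image, so it tolerates palette and illumination changes.
        """
        small = ndimage.uniform_filter(img[::4, ::4].astype(float), size=3)
        lo, med = float(small.min()), float(np.median(small))
        if med - lo < 20:  # no dark structure at all (blank / fully lidded)
            return None
        thr = lo + 0.35 * (med - lo)
        mask = small < thr
        lab = label(mask)
        props = regionprops(lab)
        if not props:
            return None
        best = max(props, key=lambda p: p.area)
        r0, c0, r1, c1 = best.bbox
        pad = 12
        y0 = max(0, r0 * 4 - pad)
        y1 = min(img.shape[0], r1 * 4 + pad)
        x0 = max(0, c0 * 4 - pad)
        x1 = min(img.shape[1], c1 * 4 + pad)
        roi = ndimage.gaussian_filter(img[y0:y1, x0:x1].astype(float),
                                      self.smooth_sigma)
        area_px = float(best.area) * 16  # downsample factor 4 in each axis
        return roi, (x0, y0), thr, area_px

    def _edge_points(self, roi: np.ndarray, thr: float) -> np.ndarray | None:
        """Sub-pixel boundary points of the dark region (longest contour)."""
        contours = find_contours(roi, thr)
        if not contours:
            return None
        contour = max(contours, key=len)
        # (row, col) -> (x, y); drop points on the ROI border (clipped edges)
        pts = contour[:, ::-1]
        h, w = roi.shape
        interior = ((pts[:, 0] > 1) & (pts[:, 0] < w - 2)
                    & (pts[:, 1] > 1) & (pts[:, 1] < h - 2))
        pts = pts[interior]
        if len(pts) > 120:  # cap work in the consensus loop
            pts = pts[:: len(pts) // 120 + 1]
        return pts

    def _consensus_fit(self, pts: np.ndarray):
        """RANSAC ellipse fit; returns (model, inlier fraction, arc coverage)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model, inliers = ransac(
                    pts, EllipseModel, min_samples=5,
                    residual_threshold=self.residual_threshold_px,
                    max_trials=self.max_trials,
                    rng=np.random.default_rng(self.seed))
            except Exception:
                return None
        if model is None or inliers is None or inliers.sum() < 5:
            return None
        a, b = model.axis_lengths
        if a <= 0 or b <= 0 or max(a, b) > 8 * self.expected_radius_px:
            return None
        quality = float(inliers.sum()) / len(pts)
        xc, yc = model.center
        ang = np.arctan2(pts[inliers, 1] - yc, pts[inliers, 0] - xc)
        nbins = 24
        occupied = np.unique(((ang + np.pi) / (2 * np.pi) * nbins).astype(int)
                             % nbins)
        coverage = len(occupied) / nbins
        return model, quality, coverage


def detect_pupil(frame: EyeFrame | np.ndarray,
                 detector: PupilDetector | None = None) -> PupilObservation:
    """Detect the pupil in one frame with default parameters."""
    return (detector or PupilDetector()).detect(frame)


def detect_session(session: Session,
                   detector: PupilDetector | None = None) -> pd.DataFrame:
    """Run detection over every frame of a session.

    Returns the observations table: frame_path, pupil_x, pupil_y, quality,
    blink (0/1) — the batch interface consumed by calibration and tracking.
    """
    detector = detector or PupilDetector()
    rows = []
    for frame, path in zip(session.frames, session.manifest["frame_path"]):
        obs = detector.detect(frame)
        rows.append({
            "frame_path": path,
            "pupil_x": obs.center_px[0] if obs.center_px else np.nan,
            "pupil_y": obs.center_px[1] if obs.center_px else np.nan,
            "quality": obs.quality,
            "blink": int(obs.is_blink),
        })
    return pd.DataFrame(rows)


def write_observations(obs: pd.DataFrame, path: str | Path) -> None:
    obs.to_csv(path, index=False)
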