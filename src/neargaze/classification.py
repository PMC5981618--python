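"""Coarse 10-class stage: nine display zones plus "blink".

Each frame is assigned either to one of the nine coarse gaze zones
(associated with the nine calibration marks) or to the blink class.  The
default backend is geometric and training-free: a blink-flagged
observation is labelled BLINK, otherwise the zone whose filtered mean
center MC'_i is nearest (Euclidean) to the detected pupil center wins,
ties broken toward the lowest zone index.

An optional learned backend classifies the raw frame pixels directly with
a small multilayer perceptron on downsampled images; it exists to exercise
the same 10-class contract from images alone and is trained only on
synthetic sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .calibration import CalibrationSet
from .pupil import PupilObservation
from .synthetic import Session

__all__ = ["BLINK", "CoarseLabel", "NearestCenterZoneClassifier",
           "classify_coarse", "LearnedCoarseClassifier",
           "train_learned_backend"]

BLINK = "blink"


@dataclass(frozen=True)
class CoarseLabel:
    """Zone 1..9 or the blink sentinel; exactly one of the two."""

    zone: int | None

    @property
    def is_blink(self) -> bool:
        return self.zone is None

    def __str__(self) -> str:
        return BLINK if self.zone is None else str(self.zone)


class NearestCenterZoneClassifier(BaseEstimator, ClassifierMixin):
    """Nearest-mean-center zone classifier over pupil-center coordinates.

    fit() takes the filtered calibration centers (one per zone); predict()
    maps pupil centers to the nearest zone.  Deterministic: equal distances
    resolve to the lowest zone index.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_zones, 2) pupil centers")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        order = np.argsort(y)
        self.classes_ = y[order]
        self.centers_ = X[order]
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "centers_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = np.linalg.norm(X[:, None, :] - self.centers_[None, :, :], axis=2)
        # argmin returns the first minimum; classes_ ascending => lowest index
        return self.classes_[np.argmin(d, axis=1)]

    @classmethod
    def from_calibration(cls, calibration: CalibrationSet) -> "NearestCenterZoneClassifier":
        return cls().fit(calibration.mean_centers(),
                         np.array(calibration.zone_ids()))


def classify_coarse(observation: PupilObservation,
                    calibration: CalibrationSet) -> CoarseLabel:
    """Coarse label for one observation: blink gate, then nearest MC'_i."""
    if set(calibration.zone_ids()) != set(range(1, 10)):
        raise ValueError(f"calibration must cover zones 1..9, has "
                         f"{calibration.zone_ids()}")
    if observation.is_blink:
        return CoarseLabel(zone=None)
    clf = NearestCenterZoneClassifier.from_calibration(calibration)
    zone = int(clf.predict([observation.center_px])[0])
    return CoarseLabel(zone=zone)


class LearnedCoarseClassifier(BaseEstimator, ClassifierMixin):
    """Small learned 10-class backend operating on raw frame pixels.

    Frames are downsampled to `input_size` x `input_size` (the full-size
    frames carry far more resolution than the 10-way decision needs) and
    classified with a single-hidden-layer MLP.  Labels are zone strings
    "1".."9" and "blink".
    """

    def __init__(self, input_size: int = 28, hidden: int = 64,
                 max_iter: int = 400, random_state: int = 0):
        self.input_size = input_size
        self.hidden = hidden
        self.max_iter = max_iter
        self.random_state = random_state

    def _features(self, frames) -> np.ndarray:
        feats = [resize(np.asarray(f.image if hasattr(f, "image") else f,
                                   dtype=float) / 255.0,
                        (self.input_size, self.input_size),
                        anti_aliasing=True).ravel()
                 for f in frames]
        return np.asarray(feats)

    def fit(self, frames, y):
        y = np.asarray([str(v) for v in y])
        required = {str(z) for z in range(1, 10)} | {BLINK}
        missing = required - set(y)
        if missing:
            raise ValueError(f"training data missing classes: {sorted(missing)}")
        X = self._features(frames)
        self.mlp_ = MLPClassifier(hidden_layer_sizes=(self.hidden,),
                                  max_iter=self.max_iter,
                                  random_state=self.random_state)
        self.mlp_.fit(X, y)
        self.classes_ = self.mlp_.classes_
        return self

    def predict(self, frames):
        check_is_fitted(self, "mlp_")
        return self.mlp_.predict(self._features(frames))


def session_labels(session: Session) -> np.ndarray:
    """True coarse labels of a calibration session: mark index or blink."""
    m = session.manifest
    labels = np.where(m["blink"].to_numpy() == 1, BLINK,
                      m["mark_index"].astype("Int64").astype(str))
    return labels.astype(str)


def train_learned_backend(session: Session,
                          labels=None, **kwargs) -> LearnedCoarseClassifier:
    """Train the learned backend on a (synthetic) calibration session."""
    if labels is None:
        labels = session_labels(session)
    return LearnedCoarseClassifier(**kwargs).fit(session.frames, labels)
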