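"""Display/viewing geometry for a near-eye gaze tracker.

The display is a millimetre-scale OLED optically magnified to a virtual image
(default 35 x 25 cm at a viewing distance H = 50 cm, addressed as 1024 x 720
display pixels).  All gaze positions live on this display plane; angular
accuracy is the visual angle alpha with tan(alpha) = h / H, where h is the
planar offset (cm) between estimated and true gaze.

Coordinates are 0-based, origin top-left, x rightward, y downward, for both
the eye-camera image plane and the display plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "DisplayGeometry",
    "CalibrationMark",
    "AngularError",
    "default_mark_layout",
    "px_offset_to_cm",
    "angular_error",
    "load_geometry",
]


@dataclass(frozen=True)
class DisplayGeometry:
    """Geometry of the virtual display plane.

    Parameters
    ----------
    width_px, height_px : int
        Addressable display resolution in pixels.
    width_cm, height_cm : float
        Physical size of the virtual image, in cm.
    viewing_distance_cm : float
        Distance H from the eye to the display plane, in cm.
    """

    width_px: int = 1024
    height_px: int = 720
    width_cm: float = 35.0
    height_cm: float = 25.0
    viewing_distance_cm: float = 50.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm",
                     "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DisplayGeometry.{name} must be > 0")

    @property
    def px_pitch_x_cm(self) -> float:
        """Horizontal pixel pitch, cm per display pixel (anisotropic)."""
        return self.width_cm / self.width_px

    @property
    def px_pitch_y_cm(self) -> float:
        return self.height_cm / self.height_px

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x <= self.width_px and 0 <= y <= self.height_px


@dataclass(frozen=True)
class CalibrationMark:
    """One of the nine on-screen calibration targets."""

    index: int
    position_px: tuple[float, float]

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 9:
            raise ValueError(f"mark index must be in 1..9, got {self.index}")


@dataclass(frozen=True)
class AngularError:
    """Angular gaze error: visual angle (degrees) and planar offset h (cm)."""

    degrees: float
    offset_cm: float


# Nine-mark layout, row-major top-left to bottom-right, on the 1024x720 display.
_MARK_POSITIONS: tuple[tuple[int, int], ...] = (
    (112, 60), (512, 60), (924, 60),
    (112, 360), (512, 360), (924, 360),
    (112, 660), (512, 660), (924, 660),
)


def default_mark_layout(geometry: DisplayGeometry | None = None) -> list[CalibrationMark]:
    """The standard nine-mark calibration layout, indexed 1..9 row-major.

    Marks sit on a 3 x 3 grid with a ~100 px margin from the display border so
    that each mark is fully visible together with its concentric ring stimulus.
    """
    geometry = geometry or DisplayGeometry()
    marks = [CalibrationMark(i + 1, (float(x), float(y)))
             for i, (x, y) in enumerate(_MARK_POSITIONS)]
    for m in marks:
        if not geometry.contains(*m.position_px):
            raise ValueError(f"mark {m.index} at {m.position_px} outside display")
    return marks


def px_offset_to_cm(dx_px: float, dy_px: float,
                    geometry: DisplayGeometry | None = None) -> float:
    """Euclidean length, in cm on the display plane, of a pixel offset.

    The pixel pitch is anisotropic (width_cm/width_px horizontally,
    height_cm/height_px vertically), so the two components are converted
    separately before the norm.
    """
    g = geometry or DisplayGeometry()
    return math.hypot(dx_px * g.px_pitch_x_cm, dy_px * g.px_pitch_y_cm)


def angular_error(estimate: Sequence[float], truth: Sequence[float],
                  geometry: DisplayGeometry | None = None) -> AngularError:
    """Visual-angle error between two display points.

    alpha = atan(h / H) with h the planar offset in cm and H the viewing
    distance; reported in degrees.
    """
    g = geometry or DisplayGeometry()
    h = px_offset_to_cm(estimate[0] - truth[0], estimate[1] - truth[1], g)
    deg = math.degrees(math.atan(h / g.viewing_distance_cm))
    return AngularError(degrees=deg, offset_cm=h)


def load_geometry(path: str | Path | None = None) -> DisplayGeometry:
    """Read geometry from a YAML config; missing keys fall back to defaults."""
    if path is None:
        return DisplayGeometry()
    data = yaml.safe_load(Path(path).read_text()) or {}
    defaults = DisplayGeometry()
    return DisplayGeometry(
        width_px=int(data.get("width_px", defaults.width_px)),
        height_px=int(data.get("height_px", defaults.height_px)),
        width_cm=float(data.get("width_cm", defaults.width_cm)),
        height_cm=float(data.get("height_cm", defaults.height_cm)),
        viewing_distance_cm=float(data.get("viewing_distance_cm",
                                           defaults.viewing_distance_cm)),
    )
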