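"""Nine-mark calibration: per-mark pupil samples and outlier-trimmed means.

During calibration the user fixates each of nine on-screen marks while the
eye camera records ~60 frames per mark.  Nystagmus and residual detection
error scatter the detected pupil centers C_i(x_j, y_j) around the fixation
mean; occasional gross errors (partial blinks, glint confusion) land far
away.  For each mark the raw mean MC_i is computed, samples whose Euclidean
distance to MC_i exceeds a threshold T are removed, and the mean of the
survivors is the filtered center MC'_i used to fit the gaze map.

The filter is single-pass by design: one rejection round, one re-mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["ZoneCalibration", "CalibrationSet", "collect_samples",
           "filter_and_mean", "build_calibration"]


@dataclass
class ZoneCalibration:
    """Filtered pupil-center statistics for one calibration zone."""

    zone: int
    samples: np.ndarray          # (n, 2) detected centers, blink-free
    raw_mean: np.ndarray         # MC_i
    filtered_mean: np.ndarray    # MC'_i
    threshold_px: float          # T actually applied
    kept: int
    rejected: int


@dataclass
class CalibrationSet:
    """Per-zone calibration results for all nine zones."""

    zones: dict[int, ZoneCalibration]
    threshold_spec: str = "adaptive"  # "adaptive" or the absolute T used
    source_checksum: str = ""

    def mean_centers(self) -> np.ndarray:
        """Filtered means MC'_1..MC'_9 stacked in zone order, shape (9, 2)."""
        return np.array([self.zones[z].filtered_mean
                         for z in sorted(self.zones)])

    def zone_ids(self) -> list[int]:
        return sorted(self.zones)

    def median_pupil_spread(self) -> float:
        """Median per-zone sample spread; a scale for downstream thresholds."""
        return float(np.median([
            np.median(np.linalg.norm(zc.samples - zc.raw_mean, axis=1))
            for zc in self.zones.values()]))

    def save(self, path: str | Path) -> None:
        doc = {
            "threshold_spec": self.threshold_spec,
            "source_checksum": self.source_checksum,
            "zones": {
                int(z): {
                    "filtered_mean": [float(v) for v in zc.filtered_mean],
                    "raw_mean": [float(v) for v in zc.raw_mean],
                    "threshold_px": float(zc.threshold_px),
                    "kept": int(zc.kept), "rejected": int(zc.rejected),
                } for z, zc in self.zones.items()},
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @staticmethod
    def load(path: str | Path) -> "CalibrationSet":
        doc = yaml.safe_load(Path(path).read_text())
        zones = {}
        for z, d in doc["zones"].items():
            z = int(z)
            fm = np.asarray(d["filtered_mean"], dtype=float)
            zones[z] = ZoneCalibration(
                zone=z, samples=fm[None, :],  # samples not serialized
                raw_mean=np.asarray(d["raw_mean"], dtype=float),
                filtered_mean=fm, threshold_px=float(d["threshold_px"]),
                kept=int(d["kept"]), rejected=int(d["rejected"]))
        return CalibrationSet(zones=zones,
                              threshold_spec=doc.get("threshold_spec", "adaptive"),
                              source_checksum=doc.get("source_checksum", ""))


def collect_samples(observations: pd.DataFrame,
                    manifest: pd.DataFrame) -> dict[int, np.ndarray]:
    """Group non-blink detected centers by calibration mark index.

    Blink-flagged observations are excluded before any averaging; a zone
    with no usable observation is a hard failure (the mark was never seen
    with an open eye).
    """
    merged = observations.merge(
        manifest[["frame_path", "mark_index"]], on="frame_path", how="inner")
    merged = merged[merged["mark_index"].notna()]
    if merged.empty:
        raise ValueError("no calibration frames: manifest has no mark indices")
    out: dict[int, np.ndarray] = {}
    for zone, grp in merged.groupby(merged["mark_index"].astype(int)):
        good = grp[(grp["blink"] == 0) & grp["pupil_x"].notna()]
        if good.empty:
            raise ValueError(f"zone {zone}: every frame was a blink or "
                             "detection failure")
        out[int(zone)] = good[["pupil_x", "pupil_y"]].to_numpy(dtype=float)
    return out


def filter_and_mean(samples: np.ndarray, zone: int = 0,
                    threshold_px: float | None = None) -> ZoneCalibration:
    """Outlier-trimmed mean center for one zone's samples.

    Single pass: compute the raw mean MC_i, drop samples whose distance to
    it is strictly greater than T, and re-average the survivors into MC'_i.
    With T=None, T adapts to the sample spread as 3x the median distance to
    the raw mean, so no absolute pixel scale must be tuned.  If the
    threshold would reject everything, the single closest sample is kept.
    """
    samples = np.asarray(samples, dtype=float).reshape(-1, 2)
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    raw_mean = samples.mean(axis=0)
    dist = np.linalg.norm(samples - raw_mean, axis=1)
    if threshold_px is None:
        t = 3.0 * float(np.median(dist))
    else:
        if threshold_px <= 0:
            raise ValueError("threshold_px must be > 0")
        t = float(threshold_px)
    keep = dist <= t
    if not keep.any():
        keep = dist == dist.min()
        keep = np.asarray(keep)
        # keep exactly one on ties
        first = np.flatnonzero(keep)[0]
        keep = np.zeros(len(samples), dtype=bool)
        keep[first] = True
    filtered_mean = samples[keep].mean(axis=0)
    return ZoneCalibration(zone=zone, samples=samples, raw_mean=raw_mean,
                           filtered_mean=filtered_mean, threshold_px=t,
                           kept=int(keep.sum()),
                           rejected=int(len(samples) - keep.sum()))


def build_calibration(observations: pd.DataFrame, manifest: pd.DataFrame,
                      threshold_px: float | None = None,
                      source_checksum: str = "",
                      required_zones: range = range(1, 10)) -> CalibrationSet:
    """Collect, filter, and average calibration observations for all zones."""
    grouped = collect_samples(observations, manifest)
    missing = sorted(set(required_zones) - set(grouped))
    if missing:
        raise ValueError(f"calibration session missing zones {missing}")
    zones = {z: filter_and_mean(s, zone=z, threshold_px=threshold_px)
             for z, s in grouped.items()}
    spec = "adaptive" if threshold_px is None else f"{threshold_px:g}"
    return CalibrationSet(zones=zones, threshold_spec=spec,
                          source_checksum=source_checksum)
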