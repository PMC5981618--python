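"""Outlier-trimmed mean calibration: the threshold filter and sample collection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial import Delaunay

from neargaze.calibration import (CalibrationSet, build_calibration,
                                  collect_samples, filter_and_mean)


class TestFilterAndMean:
    def test_worked_example(self):
        # {(0,0), (2,0), (100,0)}, T = 40: raw mean (34,0), distances
        # {34, 32, 66}, the far point is dropped, MC' = (1, 0)
        zc = filter_and_mean(np.array([[0, 0], [2, 0], [100, 0]], float),
                             threshold_px=40.0)
        assert zc.raw_mean == pytest.approx([34.0, 0.0])
        assert zc.filtered_mean == pytest.approx([1.0, 0.0])
        assert (zc.kept, zc.rejected) == (2, 1)

    def test_identical_samples(self):
        zc = filter_and_mean(np.full((10, 2), 5.0))
        assert zc.filtered_mean == pytest.approx([5.0, 5.0])
        assert zc.rejected == 0

    def test_infinite_threshold_gives_raw_mean(self, rng):
        samples = rng.normal(100, 20, size=(50, 2))
        zc = filter_and_mean(samples, threshold_px=1e12)
        assert zc.filtered_mean == pytest.approx(zc.raw_mean)
        assert zc.rejected == 0

    def test_rejection_is_strict_inequality(self):
        # a sample exactly at distance T from the raw mean is kept
        samples = np.array([[0.0, 0.0], [2.0, 0.0]])  # mean (1,0), dists 1,1
        zc = filter_and_mean(samples, threshold_px=1.0)
        assert zc.rejected == 0

    def test_degenerate_guard_keeps_closest_sample(self):
        zc = filter_and_mean(np.array([[0.0, 0.0], [10.0, 0.0]]),
                             threshold_px=1e-9)
        assert zc.kept == 1
        # closest to the raw mean (5,0) is either; first wins on ties
        assert zc.filtered_mean == pytest.approx([0.0, 0.0])

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            filter_and_mean(np.empty((0, 2)))

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_and_mean(np.zeros((3, 2)), threshold_px=0.0)

    @given(samples=arrays(float, st.tuples(st.integers(3, 30), st.just(2)),
                          elements=st.floats(-100, 100)))
    @settings(deadline=None, max_examples=50)
    def test_filtered_mean_in_convex_hull_of_kept(self, samples):
        zc = filter_and_mean(samples)
        kept = zc.samples[np.linalg.norm(zc.samples - zc.raw_mean, axis=1)
                          <= zc.threshold_px]
        if len(kept) == 0:
            return
        try:
            hull = Delaunay(kept)
            assert hull.find_simplex(zc.filtered_mean) >= 0
        except Exception:  # degenerate (collinear) hull: box containment
            assert np.all(zc.filtered_mean >= kept.min(axis=0) - 1e-9)
            assert np.all(zc.filtered_mean <= kept.max(axis=0) + 1e-9)

    def test_single_pass_not_idempotent_in_general(self):
        # documented behavior: one rejection round only.  Re-filtering the
        # survivors with the same fixed T can reject further points, because
        # removing a far outlier moves the mean.  Ten samples at 0, one at
        # 60, one at 140, T = 50: the first pass drops only the 140 point
        # (distance 123.3 from the raw mean 16.7); the survivors' mean is
        # 5.45, putting the 60 point at distance 54.5 > T.
        samples = np.array([[0.0, 0.0]] * 10 + [[60.0, 0.0], [140.0, 0.0]])
        first = filter_and_mean(samples, threshold_px=50.0)
        assert first.rejected == 1
        survivors = samples[np.linalg.norm(samples - first.raw_mean, axis=1)
                            <= 50.0]
        second = filter_and_mean(survivors, threshold_px=50.0)
        assert second.rejected == 1  # the 60 point falls in the second pass

    def test_idempotent_when_spread_within_threshold(self, rng):
        samples = rng.normal(50, 2, size=(40, 2))
        zc = filter_and_mean(samples, threshold_px=50.0)
        again = filter_and_mean(samples[np.linalg.norm(
            samples - zc.raw_mean, axis=1) <= 50.0], threshold_px=50.0)
        assert again.rejected == 0
        assert again.filtered_mean == pytest.approx(zc.filtered_mean)

    def test_trimmed_mean_beats_raw_mean_under_gross_outliers(self):
        # jittered fixations plus 5% gross (>= 10 sigma) outliers: the
        # filtered mean is closer to the true center in >= 95% of trials.
        # Gross errors come from partial blinks, which displace the detected
        # center toward the eyelid: within a trial they share a direction.
        sigma, n, n_trials = 1.0, 60, 200
        wins = 0
        rng = np.random.default_rng(1234)
        for _ in range(n_trials):
            true = rng.uniform(100, 500, size=2)
            pts = rng.normal(true, sigma, size=(n, 2))
            n_out = max(1, int(0.05 * n))
            angle = rng.uniform(0, 2 * np.pi)
            direction = np.array([np.cos(angle), np.sin(angle)])
            pts[:n_out] = true + direction * rng.uniform(10 * sigma, 30 * sigma,
                                                         size=(n_out, 1))
            zc = filter_and_mean(pts)
            if (np.linalg.norm(zc.filtered_mean - true)
                    < np.linalg.norm(zc.raw_mean - true)):
                wins += 1
        assert wins / n_trials >= 0.95


class TestCollectSamples:
    @staticmethod
    def _frames(n):
        return [f"frame_{i:05d}.png" for i in range(n)]

    def _manifest(self, zones, blinks):
        n = len(zones)
        return pd.DataFrame({
            "frame_path": self._frames(n), "mark_index": zones,
            "blink": blinks})

    def _observations(self, n, blinks):
        return pd.DataFrame({
            "frame_path": self._frames(n),
            "pupil_x": np.arange(n, dtype=float),
            "pupil_y": np.zeros(n), "quality": np.ones(n),
            "blink": blinks})

    def test_groups_by_zone_and_excludes_blinks(self):
        zones = [1, 1, 1, 2, 2, 2]
        blinks = [0, 1, 0, 0, 0, 0]
        got = collect_samples(self._observations(6, blinks),
                              self._manifest(zones, blinks))
        assert len(got[1]) == 2 and len(got[2]) == 3

    def test_zone_with_only_blinks_rejected(self):
        zones = [1, 1, 2]
        blinks = [0, 0, 1]
        with pytest.raises(ValueError, match="zone 2"):
            collect_samples(self._observations(3, blinks),
                            self._manifest(zones, blinks))

    def test_full_session_counts(self, calibration_session):
        # use recorded truth as a perfect "detector": 60 per zone minus blinks
        m = calibration_session.manifest
        obs = pd.DataFrame({"frame_path": m["frame_path"],
                            "pupil_x": m["true_pupil_x"],
                            "pupil_y": m["true_pupil_y"],
                            "quality": 1.0, "blink": m["blink"]})
        got = collect_samples(obs, m)
        per_zone_blinks = m.groupby("mark_index")["blink"].sum()
        for z in range(1, 10):
            assert len(got[z]) == 60 - per_zone_blinks[z]


class TestCalibrationSet:
    def test_build_and_roundtrip(self, tmp_path, rng):
        rows = []
        obs_rows = []
        i = 0
        for z in range(1, 10):
            for _ in range(8):
                rows.append({"frame_path": f"f{i}.png", "mark_index": z,
                             "blink": 0})
                obs_rows.append({"frame_path": f"f{i}.png",
                                 "pupil_x": 100.0 * z + rng.normal(),
                                 "pupil_y": 50.0 * z + rng.normal(),
                                 "quality": 1.0, "blink": 0})
                i += 1
        cal = build_calibration(pd.DataFrame(obs_rows), pd.DataFrame(rows))
        assert cal.zone_ids() == list(range(1, 10))
        assert cal.mean_centers().shape == (9, 2)
        p = tmp_path / "cal.yaml"
        cal.save(p)
        loaded = CalibrationSet.load(p)
        assert np.allclose(loaded.mean_centers(), cal.mean_centers())
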