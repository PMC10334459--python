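"""Mouth-shape features, cheek illumination, and deformation events."""

import numpy as np
import pytest

from mgcekit.errors import GeometryError, ParameterError
from mgcekit.facial import (cheek_illumination_series,
                            detect_deformation_events,
                            mouth_feature_series, side_switch_detector)
from mgcekit.landmarks import LandmarkFrame, LandmarkStream
from mgcekit.synth import FaceScenario, face68_template, gen_face_stream


@pytest.fixture
def rest_stream():
    return gen_face_stream(FaceScenario(duration_s=10, fps=10))[0]


class TestMouthFeatures:
    def test_static_face_normalizes_to_one(self, rest_stream):
        f = mouth_feature_series(rest_stream)
        np.testing.assert_allclose(f.upper_lip_nose_distance, 1.0,
                                   atol=1e-9)
        assert np.ptp(f.mouth_angle) == pytest.approx(0.0, abs=1e-9)

    def test_mouth_angle_plane_geometry(self):
        """Corners 49=(60,100) and 55=(100,110): atan2(10,40) = 14.04 deg."""
        pts = face68_template()
        pts[48] = (60.0, 100.0)
        pts[54] = (100.0, 110.0)
        frames = [LandmarkFrame(t=t, schema="face68", points=pts)
                  for t in np.arange(0, 3, 0.5)]
        f = mouth_feature_series(LandmarkStream("face68", frames, 2.0))
        assert f.mouth_angle[0] == pytest.approx(
            np.degrees(np.arctan2(10, 40)))

    def test_lip_raise_steps_normalized_distance(self):
        stream, _ = gen_face_stream(
            FaceScenario(duration_s=10, fps=10, lip_raise=(2.0, 8.0, 5.0)))
        f = mouth_feature_series(stream, baseline_window_s=1.5)
        before = f.upper_lip_nose_distance[f.t < 2.0]
        during = f.upper_lip_nose_distance[(f.t > 2.1) & (f.t < 7.9)]
        assert np.allclose(before, 1.0, atol=1e-9)
        assert during.mean() < 0.9  # lip moved toward the nose

    def test_zoom_invariance(self, rest_stream):
        """Global scaling of the face leaves the normalized distance
        unchanged within 1%."""
        f0 = mouth_feature_series(rest_stream)
        scaled = LandmarkStream("face68", [
            LandmarkFrame(t=fr.t, schema="face68", points=fr.points * 2.5)
            for fr in rest_stream.frames], rest_stream.fps)
        f1 = mouth_feature_series(scaled)
        np.testing.assert_allclose(f1.upper_lip_nose_distance,
                                   f0.upper_lip_nose_distance, rtol=0.01)

    def test_mirror_negates_baseline_subtracted_angle(self):
        """An anatomically mirrored face (geometry reflected and the
        left/right mouth indices swapped) negates the mouth angle."""
        # 0-based left<->right swaps within the mouth ring
        swaps = [(48, 54), (49, 53), (50, 52), (55, 59), (56, 58),
                 (60, 64), (61, 63), (65, 67)]
        stream, _ = gen_face_stream(
            FaceScenario(duration_s=6, fps=10, angle_push=(3.0, 5.0)))
        f = mouth_feature_series(stream)
        mirrored_frames = []
        for fr in stream.frames:
            pts = fr.points * [-1, 1] + [200, 0]
            for i, j in swaps:
                pts[[i, j]] = pts[[j, i]]
            mirrored_frames.append(
                LandmarkFrame(t=fr.t, schema="face68", points=pts))
        fm = mouth_feature_series(
            LandmarkStream("face68", mirrored_frames, stream.fps))
        np.testing.assert_allclose(fm.mouth_angle, -f.mouth_angle,
                                   atol=1e-6)

    def test_empty_baseline_window_rejected(self, rest_stream):
        with pytest.raises(ParameterError):
            mouth_feature_series(rest_stream, baseline_window_s=-1.0)


class TestCheekIllumination:
    def _frames(self, stream, color=(100, 100, 100)):
        return [np.full((200, 200, 3), color, dtype=float)
                for _ in stream.frames]

    def test_uniform_frames_constant_series(self, rest_stream):
        sig = cheek_illumination_series(self._frames(rest_stream),
                                        rest_stream)
        np.testing.assert_allclose(sig.mean_blue_left, 100.0)
        np.testing.assert_allclose(sig.mean_blue_right, 100.0)

    def test_blue_step_inside_left_roi(self, rest_stream):
        from mgcekit.landmarks import cheek_roi
        frames = self._frames(rest_stream)
        for i, fr in enumerate(rest_stream.frames):
            if fr.t >= 3.0:
                roi = cheek_roi(fr, "left")
                x0, y0, x1, y1 = [int(round(v)) for v in roi.bounds]
                frames[i][y0 - 2:y1 + 2, x0 - 2:x1 + 2, 2] += 20.0
        sig = cheek_illumination_series(frames, rest_stream)
        assert sig.mean_blue_left[-1] - sig.mean_blue_left[0] == \
            pytest.approx(20.0, abs=0.5)

    def test_grayscale_equals_gray_mean(self, rest_stream):
        frames = [np.full((200, 200), 77.0) for _ in rest_stream.frames]
        sig = cheek_illumination_series(frames, rest_stream)
        np.testing.assert_allclose(sig.mean_blue_left, 77.0)

    def test_roi_outside_frame_is_geometry_error(self, rest_stream):
        frames = [np.zeros((60, 60, 3)) for _ in rest_stream.frames]
        with pytest.raises(GeometryError):
            cheek_illumination_series(frames, rest_stream)


class TestDeformationEvents:
    def test_clean_step_event(self):
        """Step 1.0 -> 1.2 on [5, 12] s: one event with amplitude 0.2."""
        t = np.arange(0, 15, 0.1)
        f = np.where((t >= 5) & (t <= 12), 1.2, 1.0)
        events = detect_deformation_events(t, f)
        assert len(events) == 1
        ev = events[0]
        assert ev.start == pytest.approx(5.0, abs=0.11)
        assert ev.end == pytest.approx(12.0, abs=0.11)
        assert ev.amplitude == pytest.approx(0.2)

    def test_pure_noise_no_events(self):
        rng = np.random.default_rng(11)
        t = np.arange(0, 15, 0.1)
        f = 1.0 + rng.normal(0, 0.01, len(t))
        assert detect_deformation_events(t, f, z_threshold=4.0,
                                         min_duration_s=0.5) == []

    def test_close_events_merged(self):
        t = np.arange(0, 15, 0.05)
        f = np.where(((t >= 5) & (t < 7)) | ((t >= 7.2) & (t < 9)),
                     1.3, 1.0)
        events = detect_deformation_events(t, f)
        assert len(events) == 1
        assert events[0].end > 8.5

    def test_flat_zero_deviation_no_events(self):
        t = np.arange(0, 15, 0.1)
        assert detect_deformation_events(t, np.ones(len(t))) == []

    def test_event_recovery_under_noise(self):
        """Steps of >= 5 baseline sigma, >= 1 s duration, recovered with
        boundaries within 2 frames in >= 95% of seeded runs."""
        rng = np.random.default_rng(2024)
        fps = 10.0
        hits = total = 0
        for _ in range(100):
            t = np.arange(0, 20, 1 / fps)
            sigma = 0.01
            t0 = float(rng.uniform(4, 10))
            t1 = t0 + float(rng.uniform(1.5, 6))
            amp = float(rng.uniform(5, 12)) * sigma
            f = 1.0 + rng.normal(0, sigma, len(t))
            f[(t >= t0) & (t <= t1)] += amp
            events = detect_deformation_events(t, f, z_threshold=4.0,
                                               min_duration_s=0.5)
            total += 1
            if len(events) == 1:
                ok = (abs(events[0].start - t0) <= 2.0 / fps + 1e-9
                      and abs(events[0].end - t1) <= 2.0 / fps + 1e-9)
                hits += ok
        assert hits / total >= 0.95


class TestSideSwitch:
    def test_plus_minus_switch(self):
        """+5 deg for 5 s then -5 deg for 5 s: switch at 5 s."""
        t = np.arange(0, 10, 0.1)
        a = np.where(t < 5, 5.0, -5.0)
        assert side_switch_detector(t, a) == pytest.approx(5.0, abs=0.15)

    def test_constant_angle_no_switch(self):
        t = np.arange(0, 10, 0.1)
        assert side_switch_detector(t, np.full(len(t), 3.0)) is None

    def test_noise_only_no_switch(self):
        rng = np.random.default_rng(8)
        t = np.arange(0, 10, 0.1)
        assert side_switch_detector(t, rng.normal(0, 0.3, len(t))) is None

    def test_generated_tongue_scenario(self):
        stream, _ = gen_face_stream(
            FaceScenario(duration_s=12, fps=10, angle_push=(5.6, 6.0),
                         jitter_sigma=0.3, seed=3))
        f = mouth_feature_series(stream)
        sw = side_switch_detector(f.t, f.mouth_angle)
        assert sw == pytest.approx(5.6, abs=0.3)
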