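"""Cheek-puff and tongue-to-cheek quantification from mouth geometry.

Direct reconstruction of cheek bulge needs depth sensing; at video-call
quality the workable signals are (a) the mouth's own deformation — corner
distance, the angle of the corner-to-corner segment against the image
horizontal, vertical lip opening, upper-lip-to-nose distance — and (b) the
average blue-channel intensity inside a cheek ROI, which steps when the
cheek inflates but is sensitive to lighting and skin tone (it is exposed
with that caveat attached).

The upper-lip-to-nose distance is normalized twice: by the inter-ocular
landmark distance (zoom invariance) and by its own baseline-window mean,
so a resting face reads ~1 and a cheek puff shows as a near-step away
from 1. Event detection is a robust z-score threshold against the
pre-exercise baseline; the tongue-side switch is read from the mouth-angle
sign flip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.draw import polygon as draw_polygon

from .errors import GeometryError, ParameterError
from .landmarks import (FACE68, DEFAULT_CONFIDENCE_FLOOR, LandmarkStream,
                        MOUTH_CORNER_LEFT, MOUTH_CORNER_RIGHT, cheek_roi,
                        face_point, face_slice)

#: default 1-based face68 indices (configurable — the anatomical choice of
#: "upper lip center" and "nose base" is not standardized)
UPPER_LIP_CENTER = 52
NOSE_BASE = 34
INNER_UPPER_LIP = 63
INNER_LOWER_LIP = 67
UPPER_LIP_OUTER = (50, 51, 52, 53, 54)
LOWER_LIP_OUTER = (56, 57, 58, 59, 60)


@dataclass
class MouthFeatureSeries:
    """Per-frame mouth-shape features for the cheek exercises."""

    t: np.ndarray
    corner_distance: np.ndarray          # px
    mouth_angle: np.ndarray              # deg, segment 49->55 vs horizontal
    vertical_opening: np.ndarray         # px, inner-lip gap
    upper_lip_nose_distance: np.ndarray  # unitless, baseline ~ 1
    lip_curvature_up: np.ndarray         # 1/px
    lip_curvature_low: np.ndarray
    seal: np.ndarray                     # bool
    mask: np.ndarray                     # True = usable frame


def _interocular(points: np.ndarray) -> float:
    le = face_slice(points, FACE68["left_eye"]).mean(axis=0)
    re = face_slice(points, FACE68["right_eye"]).mean(axis=0)
    d = float(np.hypot(*(le - re)))
    if d < 1e-6:
        raise GeometryError("inter-ocular distance is zero")
    return d


def _circle_curvature(pts: np.ndarray) -> float:
    """1/R of the algebraic (Kasa) least-squares circle through pts."""
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones(len(x))])
    b = x ** 2 + y ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    r2 = sol[2] + sol[0] ** 2 / 4 + sol[1] ** 2 / 4
    if r2 <= 0 or not np.isfinite(r2):
        return 0.0
    return float(1.0 / np.sqrt(r2))


def mouth_feature_series(stream: LandmarkStream,
                         baseline_window_s: float = 2.0,
                         seal_fraction: float = 0.2,
                         upper_lip_idx: int = UPPER_LIP_CENTER,
                         nose_base_idx: int = NOSE_BASE,
                         confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR
                         ) -> MouthFeatureSeries:
    """Mouth-shape features per frame, baseline-normalized.

    The seal flag marks frames whose inner-lip gap is below
    ``seal_fraction`` of the baseline gap (plus a 0.5 px floor so a closed
    resting mouth still counts as sealed).
    """
    if stream.schema != "face68":
        raise ParameterError("mouth features need a face68 stream")
    t = stream.times
    base_sel = t <= t[0] + baseline_window_s
    if not base_sel.any():
        raise ParameterError("baseline window contains no frames")
    n = len(t)
    cd = np.full(n, np.nan)
    ang = np.full(n, np.nan)
    vo = np.full(n, np.nan)
    und = np.full(n, np.nan)
    cu = np.full(n, np.nan)
    cl = np.full(n, np.nan)
    mask = stream.quality_mask(confidence_floor)
    for i, f in enumerate(stream.frames):
        p = f.points
        c49 = face_point(p, MOUTH_CORNER_RIGHT)
        c55 = face_point(p, MOUTH_CORNER_LEFT)
        d = np.hypot(*(c55 - c49))
        if d <= 0:
            mask[i] = False
            continue
        cd[i] = d
        ang[i] = np.degrees(np.arctan2(c55[1] - c49[1], c55[0] - c49[0]))
        vo[i] = abs(face_point(p, INNER_LOWER_LIP)[1]
                    - face_point(p, INNER_UPPER_LIP)[1])
        und[i] = (abs(face_point(p, upper_lip_idx)[1]
                      - face_point(p, nose_base_idx)[1])
                  / _interocular(p))
        cu[i] = _circle_curvature(
            np.array([face_point(p, j) for j in UPPER_LIP_OUTER]))
        cl[i] = _circle_curvature(
            np.array([face_point(p, j) for j in LOWER_LIP_OUTER]))
    usable_base = base_sel & mask & np.isfinite(und)
    if not usable_base.any():
        raise ParameterError("baseline window has no usable frames")
    base_und = float(np.nanmean(und[usable_base]))
    if base_und == 0:
        raise GeometryError("zero baseline lip-to-nose distance")
    und = und / base_und
    base_gap = float(np.nanmean(vo[usable_base]))
    seal = vo < max(seal_fraction * base_gap, 0.5)
    return MouthFeatureSeries(
        t=t, corner_distance=cd, mouth_angle=ang, vertical_opening=vo,
        upper_lip_nose_distance=und, lip_curvature_up=cu,
        lip_curvature_low=cl, seal=seal, mask=mask,
    )


# ---------------------------------------------------------------------------
# cheek illumination
# ---------------------------------------------------------------------------


@dataclass
class CheekSignal:
    """Mean blue-channel intensity inside each cheek half over time.

    Illumination-sensitive by construction: a lighting change inside the
    ROI is indistinguishable from a deformation. Treat as corroborating
    evidence, not a primary metric.
    """

    t: np.ndarray
    mean_blue_left: np.ndarray
    mean_blue_right: np.ndarray


def _roi_mean_blue(frame: np.ndarray, roi) -> float:
    h, w = frame.shape[:2]
    x0, y0, x1, y1 = roi.bounds
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise GeometryError("cheek ROI extends outside the frame")
    rr, cc = draw_polygon(roi.polygon[:, 1], roi.polygon[:, 0],
                          shape=(h, w))
    if len(rr) == 0:
        raise GeometryError("cheek ROI rasterizes to zero pixels")
    chan = frame[..., 2] if frame.ndim == 3 else frame
    return float(np.mean(chan[rr, cc]))


def cheek_illumination_series(frames: Sequence[np.ndarray],
                              stream: LandmarkStream) -> CheekSignal:
    """Per-side mean blue intensity inside the cheek ROI, frame by frame.

    ``frames`` must align 1:1 with ``stream.frames``; grayscale frames are
    treated as B = G = R.
    """
    if len(frames) != len(stream):
        raise ParameterError("frame count does not match landmark stream")
    t = stream.times
    left = np.empty(len(t))
    right = np.empty(len(t))
    for i, (img, lf) in enumerate(zip(frames, stream.frames)):
        left[i] = _roi_mean_blue(img, cheek_roi(lf, "left"))
        right[i] = _roi_mean_blue(img, cheek_roi(lf, "right"))
    return CheekSignal(t=t, mean_blue_left=left, mean_blue_right=right)


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeformationEvent:
    start: float
    end: float
    amplitude: float            # median in-event deviation from baseline
    side: Literal["left", "right", "both"] = "both"

    def __post_init__(self):
        if not self.start < self.end:
            raise ParameterError("event start must precede end")


def detect_deformation_events(t: np.ndarray, feature: np.ndarray,
                              z_threshold: float = 4.0,
                              min_duration_s: float = 0.3,
                              baseline_window_s: float = 2.0,
                              merge_gap_s: float = 0.3,
                              side: str = "both",
                              mask: np.ndarray | None = None
                              ) -> list[DeformationEvent]:
    """Step-like excursions of a feature from its pre-exercise baseline.

    The baseline is the first ``baseline_window_s`` of the series; its
    robust spread (1.4826*MAD) scales the threshold. A zero-variance
    baseline detects any nonzero deviation (clean synthetic steps) and
    returns no events when the signal never moves. Events on masked spans
    (detector dropouts) are suppressed.
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(feature, dtype=float)
    base_sel = t <= t[0] + baseline_window_s
    if mask is not None:
        base_sel &= mask
    if not base_sel.any():
        raise ParameterError("no baseline samples before the exercise")
    base = f[base_sel]
    mu = float(np.median(base))
    sigma = 1.4826 * float(np.median(np.abs(base - mu)))
    thr = z_threshold * max(sigma, 1e-12)
    dev = f - mu
    above = np.abs(dev) > thr
    if mask is not None:
        above &= mask
    events: list[tuple[int, int]] = []
    start = None
    for i, b in enumerate(above):
        if b and start is None:
            start = i
        elif not b and start is not None:
            events.append((start, i - 1))
            start = None
    if start is not None:
        events.append((start, len(f) - 1))
    # merge events separated by short gaps
    merged: list[list[int]] = []
    for s, e in events:
        if merged and t[s] - t[merged[-1][1]] < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if t[e] - t[s] < min_duration_s:
            continue
        out.append(DeformationEvent(
            start=float(t[s]), end=float(t[e]),
            amplitude=float(np.median(dev[s:e + 1])), side=side))
    return out


def side_switch_detector(t: np.ndarray, angle: np.ndarray,
                         baseline_deg: float = 0.0,
                         min_segment_s: float = 1.0,
                         min_amplitude_deg: float = 1.0,
                         z_threshold: float = 3.0) -> float | None:
    """Time the tongue switches cheeks, from the mouth-angle sign flip.

    The angle relative to the resting mouth orientation
    (``baseline_deg``; 0 for a level mouth) is positive while one cheek
    is pushed and negative for the other; the switch is the transition
    between the longest pair of sustained, suprathreshold opposite-sign
    runs. The amplitude threshold scales with the frame-to-frame noise
    (robustly estimated from first differences) so jitter alone never
    produces a switch. Returns None for single-signed or sub-threshold
    series.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(angle, dtype=float)
    a0 = a - baseline_deg
    d = np.diff(a)
    sigma = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2)
    thr = max(min_amplitude_deg, z_threshold * sigma)

    def _runs(cond):
        runs, start = [], None
        for i, b in enumerate(cond):
            if b and start is None:
                start = i
            elif not b and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(cond) - 1))
        return [(s, e) for s, e in runs if t[e] - t[s] >= min_segment_s]

    pos = _runs(a0 > thr)
    neg = _runs(a0 < -thr)
    if not pos or not neg:
        return None
    # best opposite-sign pair: longest combined duration, in time order
    best, best_dur = None, -1.0
    for ps, pe in pos:
        for ns, ne in neg:
            if pe < ns:
                pair = (pe, ns)
            elif ne < ps:
                pair = (ne, ps)
            else:
                continue
            dur = (t[pe] - t[ps]) + (t[ne] - t[ns])
            if dur > best_dur:
                best_dur, best = dur, pair
    if best is None:
        return None
    return float(0.5 * (t[best[0]] + t[best[1]]))
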