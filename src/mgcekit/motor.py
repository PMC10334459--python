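"""Arm-hold and sit-to-stand kinematics from body-pose landmarks.

The arm-strength exercise asks the patient to hold both arms extended
horizontally for up to 120 s. Per frame, each arm's elevation angle is the
angle of the shoulder-to-elbow segment against the *image* horizontal
(0 deg = horizontal, negative = arm fallen below horizontal; the reference
is the image x-axis, not the shoulder line, so torso tilt does not alias
into arm drift). Drift onset is the first time the smoothed angle stays
below a threshold continuously for a hold period — Table-style grading
then needs only that onset time.

The sit-to-stand maneuver is tracked through hip height: the rise interval
is detected between the seated and standing plateaus, and peak vertical
speed/acceleration plus lateral sway (RMS of hip x about its mean during
the rise) summarize how the patient stands. A pixel calibration from a
known object (e.g. the seat) converts px/s to cm/s.

Series are denoised with a Savitzky-Golay filter (polynomial order 4,
1 s window by default), which passes polynomials up to the filter order
through unchanged — trends survive, jitter does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import (DetectionError, GeometryError, InsufficientDataError,
                     ParameterError)
from .landmarks import BODY33, DEFAULT_CONFIDENCE_FLOOR, LandmarkStream


def smooth_series(x: np.ndarray, fs: float, order: int = 4,
                  window_s: float = 1.0) -> np.ndarray:
    """Savitzky-Golay smoothing; exact on polynomials of degree <= order."""
    x = np.asarray(x, dtype=float)
    win = int(round(window_s * fs))
    win += 1 - win % 2                      # force odd
    win = max(win, order + 1 + (order % 2))
    if win > len(x):
        raise ParameterError(
            f"smoothing window ({win} samples) longer than series ({len(x)})")
    return savgol_filter(x, win, order)


@dataclass
class ArmAngleSeries:
    """Per-arm elevation angle (deg, 0 = horizontal, y-down sign fixed)."""

    t: np.ndarray
    theta_left: np.ndarray
    theta_right: np.ndarray
    theta_left_smooth: np.ndarray
    theta_right_smooth: np.ndarray
    mask: np.ndarray
    drift_onset_left: float | None = None
    drift_onset_right: float | None = None


def _segment_angle(shoulder: np.ndarray, elbow: np.ndarray) -> float:
    dx = elbow[0] - shoulder[0]
    dy = elbow[1] - shoulder[1]
    if np.hypot(dx, dy) < 10.0:
        raise GeometryError("arm segment shorter than 10 px")
    # y grows downward, so a fallen arm (elbow below shoulder) has dy > 0
    # and must read negative
    return float(np.degrees(-np.arctan2(dy, abs(dx))))


def arm_angle_series(stream: LandmarkStream,
                     confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
                     smooth_order: int = 4,
                     smooth_window_s: float = 1.0) -> ArmAngleSeries:
    """Elevation angles of both arms over an arm-hold exercise."""
    if stream.schema != "body33":
        raise InsufficientDataError("arm angles need a body33 stream")
    if len(stream) == 0:
        raise InsufficientDataError("empty landmark stream")
    t = stream.times
    mask = stream.quality_mask(confidence_floor)
    needed = [BODY33["left_shoulder"], BODY33["right_shoulder"],
              BODY33["left_elbow"], BODY33["right_elbow"]]
    for i, f in enumerate(stream.frames):
        if not np.all(np.isfinite(f.points[needed])):
            mask[i] = False
    if mask.mean() < 0.8:
        raise InsufficientDataError(
            "shoulders/elbows usable on < 80% of frames")
    th_l = np.full(len(t), np.nan)
    th_r = np.full(len(t), np.nan)
    for i, f in enumerate(stream.frames):
        if not mask[i]:
            continue
        th_l[i] = _segment_angle(f.points[BODY33["left_shoulder"]],
                                 f.points[BODY33["left_elbow"]])
        th_r[i] = _segment_angle(f.points[BODY33["right_shoulder"]],
                                 f.points[BODY33["right_elbow"]])
    fs = stream.fps or 1.0 / np.median(np.diff(t))
    # interpolate masked gaps before smoothing, keep the mask for reporting
    def _smooth(v):
        vv = v.copy()
        if (~mask).any() and mask.any():
            vv[~mask] = np.interp(t[~mask], t[mask], v[mask])
        return smooth_series(vv, fs, smooth_order, smooth_window_s)
    series = ArmAngleSeries(
        t=t, theta_left=th_l, theta_right=th_r,
        theta_left_smooth=_smooth(th_l), theta_right_smooth=_smooth(th_r),
        mask=mask,
    )
    series.drift_onset_left = detect_arm_drift_single(
        t, series.theta_left_smooth)
    series.drift_onset_right = detect_arm_drift_single(
        t, series.theta_right_smooth)
    return series


def detect_arm_drift_single(t: np.ndarray, theta_smooth: np.ndarray,
                            threshold_deg: float = 5.0,
                            hold_s: float = 1.0) -> float | None:
    """First time the smoothed angle stays below -threshold for >= hold_s.

    Table-style "drift" has no numeric definition; the default (-5 deg
    sustained 1 s) is small enough to catch early drift yet robust to
    landmark jitter. Returns None when the arm never drifts.
    """
    below = theta_smooth < -threshold_deg
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b and start is not None:
            if t[i - 1] - t[start] >= hold_s:
                return float(t[start])
            start = None
    if start is not None and t[-1] - t[start] >= hold_s:
        return float(t[start])
    return None


def detect_arm_drift(series: ArmAngleSeries, threshold_deg: float = 5.0,
                     hold_s: float = 1.0
                     ) -> tuple[float | None, float | None]:
    """(left onset, right onset) in seconds, or None per arm."""
    return (
        detect_arm_drift_single(series.t, series.theta_left_smooth,
                                threshold_deg, hold_s),
        detect_arm_drift_single(series.t, series.theta_right_smooth,
                                threshold_deg, hold_s),
    )


# ---------------------------------------------------------------------------
# sit-to-stand
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PixelCalibration:
    """cm-per-pixel scale derived from an object of known size."""

    scale: float                # cm/px
    source: str = "seat"

    def __post_init__(self):
        if not self.scale > 0:
            raise ParameterError("calibration scale must be positive")


def calibrate_pixels(known_length_cm: float, measured_px: float,
                     source: str = "seat") -> PixelCalibration:
    if known_length_cm <= 0 or measured_px <= 0:
        raise ParameterError("calibration inputs must be positive")
    return PixelCalibration(scale=known_length_cm / measured_px,
                            source=source)


@dataclass
class StandKinematics:
    """Summary of one sit-to-stand maneuver."""

    t: np.ndarray
    y_hip_left: np.ndarray
    y_hip_right: np.ndarray
    rise_start: float
    rise_end: float
    peak_speed: float           # px/s, upward
    peak_acceleration: float    # px/s^2
    lateral_sway: float         # px RMS about the mean, during the rise
    peak_speed_cm_s: float | None = None
    peak_acceleration_cm_s2: float | None = None


def stand_kinematics(stream: LandmarkStream,
                     calib: PixelCalibration | None = None,
                     plateau_frac: float = 0.1,
                     plateau_window_s: float = 1.0,
                     min_rise_px: float = 20.0,
                     smooth_order: int = 4,
                     smooth_window_s: float = 0.3) -> StandKinematics:
    """Hip-height kinematics of a sit-to-stand maneuver.

    The rise interval runs from the sample where smoothed hip height leaves
    the band within ``plateau_frac`` of the seated plateau to the sample
    where it enters the same-width band around the standing plateau.
    Plateaus are medians over the first/last ``plateau_window_s``.
    """
    if stream.schema != "body33":
        raise InsufficientDataError("stand kinematics needs a body33 stream")
    t = stream.times
    if len(t) < 8:
        raise InsufficientDataError("too few frames for sit-to-stand")
    pts = np.stack([f.points for f in stream.frames])
    yl = pts[:, BODY33["left_hip"], 1]
    yr = pts[:, BODY33["right_hip"], 1]
    xh = (pts[:, BODY33["left_hip"], 0] + pts[:, BODY33["right_hip"], 0]) / 2
    y = (yl + yr) / 2.0
    fs = stream.fps or 1.0 / np.median(np.diff(t))
    ys = smooth_series(y, fs, smooth_order, smooth_window_s)

    seated = float(np.median(ys[t <= t[0] + plateau_window_s]))
    standing = float(np.median(ys[t >= t[-1] - plateau_window_s]))
    rise_px = seated - standing          # y down: standing is smaller y
    if rise_px < min_rise_px:
        raise DetectionError(
            f"no rise detected (hip elevation {rise_px:.1f}px "
            f"< {min_rise_px}px)")
    band = plateau_frac * rise_px
    left_seat = np.nonzero(ys < seated - band)[0]
    if len(left_seat) == 0:
        raise DetectionError("hip never leaves the seated plateau")
    i0 = int(left_seat[0])
    reach_stand = np.nonzero(ys[i0:] < standing + band)[0]
    if len(reach_stand) == 0:
        raise DetectionError("hip never reaches the standing plateau")
    i1 = int(i0 + reach_stand[0])

    # velocity from a linear-order (moving-average) smooth: a polynomial
    # smoother of higher order rings at the plateau corners and would
    # overshoot the true peak slope
    yv = smooth_series(y, fs, 1, smooth_window_s)
    v = np.gradient(yv, t)               # px/s, negative while rising
    a = np.gradient(v, t)
    peak_speed = float(np.max(-v))       # report upward speed as positive
    peak_acc = float(np.max(np.abs(a)))
    x_rise = xh[i0:i1 + 1]
    sway = float(np.sqrt(np.mean((x_rise - x_rise.mean()) ** 2)))
    out = StandKinematics(
        t=t, y_hip_left=yl, y_hip_right=yr,
        rise_start=float(t[i0]), rise_end=float(t[i1]),
        peak_speed=peak_speed, peak_acceleration=peak_acc,
        lateral_sway=sway,
    )
    if calib is not None:
        out.peak_speed_cm_s = peak_speed * calib.scale
        out.peak_acceleration_cm_s2 = peak_acc * calib.scale
    return out
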