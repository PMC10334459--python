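"""Ptosis and ocular-alignment exercise metrics.

The ptosis exercise (60 s sustained upgaze) is quantified by three
per-frame distances — upper-lid-to-pupil, lid-to-lid, and opening area —
assembled into a time series and summarized by an ordinary least-squares
linear fit: the fitted percent decay over the exercise window and the
two-sided t-test on the slope ("is the droop statistically significant?").

The diplopia exercise (60 s sustained lateral gaze) is quantified by the
barycentric coordinate of each eye's innermost iris border between the eye
corners, b in [0, 1]; the difference between the two eyes, referenced to
its early-exercise baseline, is the misalignment signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError, GeometryError, InsufficientDataError
from .eye import EyeGeometry, MeasurementUnavailable, eye_measures

MEASURES = ("d_lid_pupil", "d_lid_lid", "area")


@dataclass
class PtosisSeries:
    """Per-frame eye openness measures with a usability mask."""

    t: np.ndarray
    d_lid_pupil: np.ndarray
    d_lid_lid: np.ndarray
    area: np.ndarray
    mask: np.ndarray            # True = usable
    normalized: bool = False

    def values(self, measure: str) -> np.ndarray:
        if measure not in MEASURES:
            raise KeyError(f"measure must be one of {MEASURES}")
        return getattr(self, measure)


@dataclass
class DecayFit:
    """OLS summary of a ptosis measure over the exercise window."""

    slope: float                # px/s (or 1/s when normalized)
    intercept: float
    percent_decay: float        # 100*(fit(t0)-fit(t1))/fit(t0)
    p_value: float              # two-sided slope t-test
    window: tuple[float, float]

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def ptosis_series(geoms: Sequence[EyeGeometry], times: Sequence[float],
                  normalize: bool = False, min_frames: int = 10,
                  min_span_s: float = 30.0) -> PtosisSeries:
    """Assemble the three openness measures per frame.

    Frames whose geometry is not ``quality='ok'`` are masked, not dropped.
    ``normalize=True`` divides each measure by the mean of its first five
    usable frames (so the series starts near 1).
    """
    t = np.asarray(times, dtype=float)
    n = len(t)
    if len(geoms) != n:
        raise InsufficientDataError("geometries and times differ in length")
    cols = {m: np.full(n, np.nan) for m in MEASURES}
    mask = np.zeros(n, dtype=bool)
    for i, g in enumerate(geoms):
        try:
            dll, area, dlp = eye_measures(g)
        except MeasurementUnavailable:
            continue
        cols["d_lid_lid"][i] = dll
        cols["area"][i] = area
        cols["d_lid_pupil"][i] = dlp
        mask[i] = True
    usable = mask.sum()
    if usable < min_frames:
        raise InsufficientDataError(
            f"only {usable} usable frames (need >= {min_frames})")
    tu = t[mask]
    if tu[-1] - tu[0] < min_span_s:
        raise InsufficientDataError(
            f"usable span {tu[-1] - tu[0]:.1f}s < {min_span_s}s")
    if normalize:
        for m in MEASURES:
            base = np.nanmean(cols[m][mask][:5])
            if base == 0:
                raise FitError(f"zero baseline for {m}")
            cols[m] = cols[m] / base
    return PtosisSeries(t=t, mask=mask, normalized=normalize, **cols)


def fit_linear_decay(series: PtosisSeries,
                     measure: str = "d_lid_pupil") -> DecayFit:
    """OLS line through the unmasked points of one measure.

    percent_decay evaluates the fitted line at the window endpoints:
    100*(fit(t0) - fit(t1))/fit(t0). The p-value is the standard two-sided
    t-test of slope != 0.
    """
    y = series.values(measure)[series.mask]
    t = series.t[series.mask]
    if np.ptp(t) == 0:
        raise FitError("zero variance in time")
    res = stats.linregress(t, y)
    t0, t1 = float(t[0]), float(t[-1])
    f0 = res.intercept + res.slope * t0
    f1 = res.intercept + res.slope * t1
    if f0 == 0:
        raise FitError("fitted baseline is zero")
    return DecayFit(
        slope=float(res.slope), intercept=float(res.intercept),
        percent_decay=float(100.0 * (f0 - f1) / f0),
        p_value=float(res.pvalue), window=(t0, t1),
    )


@dataclass
class RelaxationFit:
    """Exploratory exponential summary: approach of the lid to equilibrium.

    This quantity is not part of the standardized core exam; it is exposed
    because the underlying time series supports it.
    """

    tau_s: float                # time to cover 1 - 1/e of the gap
    asymptote: float
    amplitude: float


def fit_relaxation(series: PtosisSeries,
                   measure: str = "d_lid_pupil") -> RelaxationFit:
    """Fit y(t) = asymptote + amplitude * exp(-t/tau) to unmasked points."""
    y = series.values(measure)[series.mask]
    t = series.t[series.mask] - series.t[series.mask][0]
    if len(t) < 4:
        raise InsufficientDataError("need >= 4 usable frames")
    a0 = y[-1]
    b0 = y[0] - a0 or 1.0
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, b, tau: a + b * np.exp(-tt / tau),
            t, y, p0=(a0, b0, max(t[-1] / 3.0, 1e-3)), maxfev=5000)
    except RuntimeError as e:
        raise FitError(f"relaxation fit failed: {e}")
    return RelaxationFit(tau_s=float(abs(popt[2])), asymptote=float(popt[0]),
                         amplitude=float(popt[1]))


# ---------------------------------------------------------------------------
# alignment (diplopia exercise)
# ---------------------------------------------------------------------------


@dataclass
class AlignmentSeries:
    """Barycentric iris coordinates per eye and the misalignment signal."""

    t: np.ndarray
    b_left: np.ndarray
    b_right: np.ndarray
    misalignment: np.ndarray
    baseline: float             # median of (b_left - b_right), first 2 s


def _barycentric(x_iris_inner: float, corners: tuple[float, float]) -> float:
    """Position of the inner iris border between (inner, outer) corner x."""
    x_in, x_out = corners
    span = x_out - x_in
    if abs(span) < 4.0:
        raise GeometryError(f"eye corner span {span:.1f}px < 4px")
    return float(np.clip((x_iris_inner - x_in) / span, 0.0, 1.0))


def alignment_series(left_geoms: Sequence[EyeGeometry],
                     right_geoms: Sequence[EyeGeometry],
                     times: Sequence[float],
                     corners_left: tuple[float, float],
                     corners_right: tuple[float, float],
                     inner_is_left_border: tuple[bool, bool] = (True, False),
                     baseline_window_s: float = 2.0) -> AlignmentSeries:
    """Barycentric coordinate of the innermost iris border of each eye.

    ``corners_*`` are the (inner, outer) eye-corner x positions in the same
    coordinate frame as the geometries. ``inner_is_left_border`` states,
    per (left eye, right eye), whether the anatomically inner iris border
    is the smaller-x (``iris_x_left``) border; the default matches a
    frontal un-mirrored image where the subject's left eye has its inner
    corner at smaller x. Frames where either eye is not ``ok`` are dropped
    from the series.
    """
    t_all = np.asarray(times, dtype=float)
    ts, bl, br = [], [], []
    for t, gl, gr in zip(t_all, left_geoms, right_geoms):
        if gl.quality != "ok" or gr.quality != "ok":
            continue
        xl = gl.iris_x_left if inner_is_left_border[0] else gl.iris_x_right
        xr = gr.iris_x_left if inner_is_left_border[1] else gr.iris_x_right
        ts.append(t)
        bl.append(_barycentric(xl, corners_left))
        br.append(_barycentric(xr, corners_right))
    if not ts:
        raise InsufficientDataError("no frames with both eyes segmented")
    ts = np.asarray(ts)
    bl = np.asarray(bl)
    br = np.asarray(br)
    delta = bl - br
    early = ts <= ts[0] + baseline_window_s
    baseline = float(np.median(delta[early]))
    return AlignmentSeries(t=ts, b_left=bl, b_right=br,
                           misalignment=np.abs(delta - baseline),
                           baseline=baseline)


@dataclass
class AlignmentSummary:
    max_misalignment: float
    drift_slope: float          # 1/s
    steady: bool


def alignment_summary(series: AlignmentSeries,
                      steady_threshold: float = 0.1,
                      min_span_s: float = 10.0) -> AlignmentSummary:
    """Max misalignment, OLS drift slope, and a steadiness verdict."""
    if series.t[-1] - series.t[0] < min_span_s:
        raise InsufficientDataError(
            f"need >= {min_span_s}s of data for an alignment summary")
    res = stats.linregress(series.t, series.misalignment)
    mx = float(series.misalignment.max())
    return AlignmentSummary(max_misalignment=mx,
                            drift_slope=float(res.slope),
                            steady=mx < steady_threshold)
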