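"""Hybrid eye segmentation at telehealth resolution.

A video-call eye region is tiny — on the order of 40x20 px — which defeats
the classical iris detectors (circular Hough transform, Daugman operator)
that assume tens of pixels of iris radius and controlled illumination.
This module instead refines a detector-supplied eye ROI with a local,
resolution-tolerant combination of intensity clustering and a per-column
vertical-gradient search:

1. grayscale + percentile contrast stretch;
2. 2-class intensity clustering (Otsu threshold by default, 1-D k-means as
   a config switch) isolates the dark iris/pupil blob;
3. the largest dark connected component gives the pupil center
   (darkness-weighted centroid) and the vertical iris borders (its extreme
   columns);
4. the upper/lower lids are located per column as the strongest vertical
   intensity transitions above/below the pupil row, refined to sub-pixel by
   parabolic interpolation, and robust-fitted by a quadratic.

At this resolution the pupil proper is rarely separable from the iris, so
the "pupil center" reported here is the centroid of the combined dark blob.
Failures (closed eye, low contrast) are reported through a quality flag
rather than guessed through.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import InputError, MeasurementUnavailable

MIN_PATCH_W = 16
MIN_PATCH_H = 8

#: standard luma weights for RGB -> gray
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the hybrid segmentation."""

    clustering: Literal["otsu", "kmeans"] = "otsu"
    min_component_area: float = 6.0   # px^2; smaller dark blobs => closed
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    subpixel: bool = True             # parabolic refinement of gradient peaks
    mad_rejection_rounds: int = 1     # robust quadratic lid fit
    min_contrast: float = 0.15        # post-stretch dynamic range floor
    lid_edge_min_gradient: float = 0.05  # post-stretch units/px; weaker
    # skin->sclera peaks are treated as absent (lid resting on the iris)
    column_smooth_sigma: float = 0.7  # Gaussian smoothing before d/dy


@dataclass
class EyeImagePatch:
    """Eye ROI pixels cut from a full frame."""

    pixels: np.ndarray                 # (H, W) gray or (H, W, 3) RGB
    offset: tuple[float, float] = (0.0, 0.0)  # patch origin in frame coords
    side: Literal["left", "right"] = "left"

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        h, w = px.shape[:2]
        if w < MIN_PATCH_W or h < MIN_PATCH_H:
            raise InputError(
                f"eye patch {w}x{h} below minimum {MIN_PATCH_W}x{MIN_PATCH_H}"
            )
        if not np.all(np.isfinite(px)):
            raise InputError("eye patch contains non-finite intensities")
        self.pixels = px

    @property
    def gray(self) -> np.ndarray:
        if self.pixels.ndim == 3:
            return self.pixels[..., :3] @ _LUMA
        return self.pixels


@dataclass
class EyeGeometry:
    """Anatomic markers for one eye in one frame (patch coordinates)."""

    pupil_center: tuple[float, float] | None = None
    iris_x_left: float | None = None
    iris_x_right: float | None = None
    iris_bottom_y: float | None = None
    columns: np.ndarray | None = None     # x positions where lids are defined
    upper_lid: np.ndarray | None = None   # y per column (fitted quadratic)
    lower_lid: np.ndarray | None = None
    quality: Literal["ok", "low_contrast", "closed"] = "ok"

    def lid_y_at(self, x: float, which: Literal["upper", "lower"]) -> float:
        """Fitted lid height at an arbitrary column (quadratic evaluation)."""
        curve = self.upper_lid if which == "upper" else self.lower_lid
        if curve is None or self.columns is None:
            raise MeasurementUnavailable("lid curve not available")
        coeff = np.polyfit(self.columns, curve, 2)
        return float(np.polyval(coeff, x))


# ---------------------------------------------------------------------------
# segmentation pipeline
# ---------------------------------------------------------------------------

def _contrast_stretch(img: np.ndarray, p: tuple[float, float]) -> np.ndarray:
    lo, hi = np.percentile(img, p)
    if hi - lo <= 1e-12:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def _otsu_threshold(img: np.ndarray) -> float:
    from skimage.filters import threshold_otsu
    return float(threshold_otsu(img, nbins=128))


def _kmeans1d_threshold(img: np.ndarray, n_iter: int = 50) -> float:
    """2-means on intensities; returns the midpoint between centers."""
    v = img.ravel()
    c = np.array([v.min(), v.max()], dtype=float)
    for _ in range(n_iter):
        d = np.abs(v[:, None] - c[None, :])
        lab = d.argmin(axis=1)
        new = np.array([v[lab == k].mean() if np.any(lab == k) else c[k]
                        for k in (0, 1)])
        if np.allclose(new, c, atol=1e-9):
            break
        c = new
    return float(c.mean())


def _dark_component(mask: np.ndarray, min_area: float) -> np.ndarray | None:
    """Largest dark connected component; ties -> closest to patch center."""
    lab, n = ndimage.label(mask)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    best = sizes.max()
    if best < min_area:
        return None
    cand = [i + 1 for i, s in enumerate(sizes) if s == best]
    if len(cand) > 1:
        h, w = mask.shape
        ctr = np.array([(h - 1) / 2, (w - 1) / 2])
        cyx = ndimage.center_of_mass(mask, lab, cand)
        d = [np.hypot(*(np.array(c) - ctr)) for c in cyx]
        cand = [cand[int(np.argmin(d))]]
    return lab == cand[0]


def _parabolic_offset(y0: float, y1: float, y2: float) -> float:
    """Sub-sample offset of the extremum of 3 consecutive samples."""
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


def _fit_quadratic_robust(x: np.ndarray, y: np.ndarray, rounds: int
                          ) -> np.ndarray:
    """Quadratic LSQ with `rounds` passes of 2*MAD outlier rejection."""
    keep = np.ones(len(x), bool)
    coeff = np.polyfit(x, y, min(2, len(x) - 1))
    for _ in range(rounds):
        resid = y[keep] - np.polyval(coeff, x[keep])
        mad = np.median(np.abs(resid - np.median(resid)))
        if mad <= 1e-9:
            break
        ok = np.abs(resid - np.median(resid)) <= 2 * 1.4826 * mad
        idx = np.where(keep)[0][ok]
        if len(idx) < 3 or len(idx) == keep.sum():
            break
        keep[:] = False
        keep[idx] = True
        coeff = np.polyfit(x[keep], y[keep], 2)
    return np.polyval(coeff, x)


def _peak_location(g: np.ndarray, lo: int, hi: int, subpixel: bool
                   ) -> tuple[float, float] | None:
    """(location, strength) of the maximum of g[lo:hi], sub-sample refined."""
    if hi - lo < 1:
        return None
    k = lo + int(np.argmax(g[lo:hi]))
    y = float(k)
    if subpixel and 0 < k < len(g) - 1:
        y += _parabolic_offset(g[k - 1], g[k], g[k + 1])
    return y, float(g[k])


def _column_lids(col: np.ndarray, itop: int, ibot: int,
                 cfg: "SegmentationConfig") -> tuple[float, float] | None:
    """Upper/lower lid heights in one column, anchored to the dark blob.

    Scanning downward the upper lid edge is a dark-to-light transition
    (skin below the lid is darker than the sclera inside the opening), so
    it is the strongest positive d/dy above the iris top. When no such
    peak exists the lid rests directly on the iris and the edge is the
    light-to-dark skin/iris boundary at the blob top. Symmetric logic for
    the lower lid below the iris bottom.
    """
    from scipy.ndimage import gaussian_filter1d

    h = len(col)
    g = np.gradient(gaussian_filter1d(col, cfg.column_smooth_sigma))
    # upper lid
    peak = _peak_location(g, 0, itop, cfg.subpixel)
    if peak is not None and peak[1] >= cfg.lid_edge_min_gradient:
        yu = peak[0]
    else:  # lid on iris: strongest negative gradient around the blob top
        lo, hi = max(0, itop - 2), min(itop + 3, h)
        fall = _peak_location(-g, lo, hi, cfg.subpixel)
        if fall is None:
            return None
        yu = fall[0]
    # lower lid
    peak = _peak_location(-g, ibot + 1, h, cfg.subpixel)
    if peak is not None and peak[1] >= cfg.lid_edge_min_gradient:
        yl = peak[0]
    else:
        lo, hi = max(0, ibot - 2), min(ibot + 3, h)
        rise = _peak_location(g, lo, hi, cfg.subpixel)
        if rise is None:
            return None
        yl = rise[0]
    if yl <= yu:
        return None
    return yu, yl


def segment_eye(patch: EyeImagePatch,
                config: SegmentationConfig | None = None) -> EyeGeometry:
    """Locate pupil center, iris borders and lid curves in an eye patch.

    Never guesses: if no dark component of sufficient area exists the
    returned geometry carries ``quality='closed'``; if the patch has no
    usable dynamic range, ``quality='low_contrast'``.
    """
    cfg = config or SegmentationConfig()
    img = _contrast_stretch(patch.gray, cfg.stretch_percentiles)
    if img.max() - img.min() < cfg.min_contrast:
        return EyeGeometry(quality="low_contrast")

    thr = (_otsu_threshold(img) if cfg.clustering == "otsu"
           else _kmeans1d_threshold(img))
    comp = _dark_component(img < thr, cfg.min_component_area)
    if comp is None:
        return EyeGeometry(quality="closed")

    ys, xs = np.nonzero(comp)
    w_dark = (1.0 - img[ys, xs]) + 1e-9       # darkness-weighted centroid
    cx = float(np.sum(xs * w_dark) / np.sum(w_dark))
    cy = float(np.sum(ys * w_dark) / np.sum(w_dark))
    x_left, x_right = float(xs.min()), float(xs.max())
    iris_bottom = float(ys.max())

    # per-column lid search across the iris span
    cols = np.arange(int(x_left), int(x_right) + 1)
    up, low, used = [], [], []
    for x in cols:
        col_mask = comp[:, x]
        if not col_mask.any():
            continue
        itop = int(col_mask.argmax())
        ibot = int(len(col_mask) - 1 - col_mask[::-1].argmax())
        lids = _column_lids(img[:, x], itop, ibot, cfg)
        if lids is not None:
            up.append(lids[0])
            low.append(lids[1])
            used.append(x)
    if len(used) < 3:
        return EyeGeometry(
            pupil_center=(cx, cy), iris_x_left=x_left, iris_x_right=x_right,
            iris_bottom_y=iris_bottom, quality="closed",
        )
    used_a = np.asarray(used, float)
    upper = _fit_quadratic_robust(used_a, np.asarray(up),
                                  cfg.mad_rejection_rounds)
    lower = _fit_quadratic_robust(used_a, np.asarray(low),
                                  cfg.mad_rejection_rounds)
    quality = "ok" if x_left < x_right else "closed"
    return EyeGeometry(
        pupil_center=(cx, cy),
        iris_x_left=x_left, iris_x_right=x_right, iris_bottom_y=iris_bottom,
        columns=used_a, upper_lid=upper, lower_lid=np.maximum(lower, upper),
        quality=quality,
    )


# ---------------------------------------------------------------------------
# geometric measures (the three per-frame distances)
# ---------------------------------------------------------------------------

def eye_measures(geom: EyeGeometry) -> tuple[float, float, float]:
    """The three per-frame openness measures, in pixels.

    Returns ``(d_lid_lid, area, d_lid_pupil)``:
    vertical lid-to-lid distance at the pupil column; the opening area
    between the fitted lid curves over the iris span; and the vertical
    distance from the upper lid (at the pupil column) down to the pupil
    center. All from the fitted lid curves.
    """
    if geom.quality != "ok":
        raise MeasurementUnavailable(f"geometry quality is {geom.quality!r}")
    px, py = geom.pupil_center
    yu = geom.lid_y_at(px, "upper")
    yl = geom.lid_y_at(px, "lower")
    d_lid_lid = yl - yu
    d_lid_pupil = py - yu
    gap = np.clip(geom.lower_lid - geom.upper_lid, 0.0, None)
    area = float(np.trapezoid(gap, geom.columns))
    return float(d_lid_lid), area, float(d_lid_pupil)


@dataclass
class QualityReport:
    """Outcome of post-hoc segmentation validation."""

    passed: bool
    reasons: list[str] = field(default_factory=list)


def validate_segmentation(geom: EyeGeometry,
                          patch: EyeImagePatch | None = None,
                          config: SegmentationConfig | None = None
                          ) -> QualityReport:
    """Check invariants of a segmentation result; always returns a report."""
    cfg = config or SegmentationConfig()
    reasons: list[str] = []
    if geom.quality != "ok":
        reasons.append(f"quality flag: {geom.quality}")
    if geom.pupil_center is not None and patch is not None:
        h, w = patch.gray.shape
        px, py = geom.pupil_center
        if not (0 <= px < w and 0 <= py < h):
            reasons.append("pupil center outside patch")
    if geom.iris_x_left is not None and geom.iris_x_right is not None:
        if not geom.iris_x_left < geom.iris_x_right:
            reasons.append("iris borders out of order")
    if geom.upper_lid is not None and geom.lower_lid is not None:
        if np.any(geom.lower_lid < geom.upper_lid - 1e-9):
            reasons.append("lid-order violation (upper below lower)")
    if patch is not None:
        img = _contrast_stretch(patch.gray, cfg.stretch_percentiles)
        if img.max() - img.min() < cfg.min_contrast:
            reasons.append("low contrast")
        thr = _otsu_threshold(img) if img.max() > img.min() else 0.0
        comp = _dark_component(img < thr, cfg.min_component_area)
        if comp is not None:
            h, w = comp.shape
            touches = sum(int(edge.any()) for edge in
                          (comp[0], comp[-1], comp[:, 0], comp[:, -1]))
            if touches == 4:
                reasons.append("spill: dark component touches all borders")
    return QualityReport(passed=not reasons, reasons=reasons)
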