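"""Landmark schemas, stream I/O and geometric ROI extraction.

Two landmark schemas are supported, mirroring the pretrained detectors a
telehealth pipeline would plug in:

* ``face68`` — the classic 68-point face annotation. Indices are **1-based**
  (the convention in which the mouth corners are points 49 and 55). Index
  ranges: 1-17 jaw, 18-27 brows, 28-36 nose, 37-42 right eye, 43-48 left
  eye, 49-68 mouth.
* ``body33`` — the 33-point full-body pose schema. Indices are **0-based**
  (11/12 shoulders, 13/14 elbows, 23/24 hips, ...).

Pixel convention throughout: origin top-left, y increases downward, so
"elevation" of a body part means *decreasing* y.

Streams are read and written as long-format CSV (columns
``t, schema, idx, x, y, conf``) or JSONL (one frame per line:
``{"t": ..., "schema": "face68", "points": [[x, y], ...], "conf": ...}``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import GeometryError, InputError, ParseError, SchemaError

# ---------------------------------------------------------------------------
# Index tables (single source of truth for landmark semantics)
# ---------------------------------------------------------------------------

#: face68, 1-based inclusive ranges
FACE68 = {
    "jaw": (1, 17),
    "right_eye": (37, 42),
    "left_eye": (43, 48),
    "nose": (28, 36),
    "mouth": (49, 68),
}
FACE68_N = 68
#: mouth corners (right, left in subject terms)
MOUTH_CORNER_RIGHT = 49
MOUTH_CORNER_LEFT = 55
#: cheek quadrilateral, in drawing order
CHEEK_QUAD = (3, 15, 13, 5)
#: eye-corner pairs used for barycentric alignment (outer, inner per eye)
EYE_CORNERS_RIGHT = (37, 40)  # outer, inner
EYE_CORNERS_LEFT = (46, 43)   # outer, inner

#: body33, 0-based
BODY33 = {
    "left_shoulder": 11,
    "right_shoulder": 12,
    "left_elbow": 13,
    "right_elbow": 14,
    "left_hip": 23,
    "right_hip": 24,
}
BODY33_N = 33

DEFAULT_CONFIDENCE_FLOOR = 0.5


def face_point(points: np.ndarray, idx_1based: int) -> np.ndarray:
    """Return the (x, y) of a 1-based face68 index from a (68, 2) array."""
    if not 1 <= idx_1based <= FACE68_N:
        raise IndexError(f"face68 index {idx_1based} out of range 1..68")
    return points[idx_1based - 1]


def face_slice(points: np.ndarray, rng: tuple[int, int]) -> np.ndarray:
    """Points for an inclusive 1-based face68 range, e.g. FACE68['mouth']."""
    lo, hi = rng
    return points[lo - 1 : hi]


# ---------------------------------------------------------------------------
# Frame / stream containers
# ---------------------------------------------------------------------------

SchemaId = Literal["face68", "body33"]
_N_POINTS = {"face68": FACE68_N, "body33": BODY33_N}


@dataclass(frozen=True)
class LandmarkFrame:
    """One time-stamped landmark frame (face68 or body33)."""

    t: float
    schema: SchemaId
    points: np.ndarray  # (N, 2) float, pixel coords, y down
    confidence: float = 1.0
    frame_size: tuple[int, int] | None = None  # (width, height) px

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        n = _N_POINTS.get(self.schema)
        if n is None:
            raise SchemaError(f"unknown schema {self.schema!r}")
        if pts.shape != (n, 2):
            raise SchemaError(
                f"{self.schema} frame at t={self.t}: expected {n} points, "
                f"got shape {pts.shape}"
            )
        object.__setattr__(self, "points", pts)


# Aliases used in type hints downstream; the payload is the same container.
FaceLandmarkFrame = LandmarkFrame
BodyLandmarkFrame = LandmarkFrame


@dataclass
class LandmarkStream:
    """Ordered landmark frames with a single schema and a nominal rate."""

    schema: SchemaId
    frames: list[LandmarkFrame]
    fps: float

    def __post_init__(self):
        for f in self.frames:
            if f.schema != self.schema:
                raise SchemaError(
                    f"mixed schemas in stream: {f.schema} vs {self.schema}"
                )
        ts = self.times
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise SchemaError("timestamps must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.frames], dtype=float)

    @property
    def confidences(self) -> np.ndarray:
        return np.array([f.confidence for f in self.frames], dtype=float)

    def quality_mask(self, floor: float = DEFAULT_CONFIDENCE_FLOOR) -> np.ndarray:
        """True where the frame is usable (confidence >= floor).

        Low-confidence frames are flagged, never dropped: every series keeps
        the full frame axis and carries this mask alongside.
        """
        return self.confidences >= floor

    def window(self, t0: float, t1: float) -> "LandmarkStream":
        """Sub-stream restricted to t0 <= t <= t1."""
        kept = [f for f in self.frames if t0 <= f.t <= t1]
        return LandmarkStream(self.schema, kept, self.fps)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class RegionOfInterest:
    """Image subregion on which a metric is computed."""

    kind: Literal["eye_left", "eye_right", "cheek_left", "cheek_right",
                  "cheek_both", "mouth"]
    polygon: np.ndarray  # (K, 2) vertices, closed implicitly
    t: float = 0.0

    def __post_init__(self):
        poly = np.asarray(self.polygon, dtype=float)
        if not np.all(np.isfinite(poly)):
            raise GeometryError(f"{self.kind} ROI has non-finite vertices")
        if self.area <= 0:
            raise GeometryError(f"{self.kind} ROI has zero area")
        object.__setattr__(self, "polygon", poly)

    @property
    def area(self) -> float:
        return Polygon(np.asarray(self.polygon, dtype=float)).area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) axis-aligned bounds."""
        p = np.asarray(self.polygon, dtype=float)
        return (p[:, 0].min(), p[:, 1].min(), p[:, 0].max(), p[:, 1].max())


def _box_polygon(x0, y0, x1, y1) -> np.ndarray:
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


# ---------------------------------------------------------------------------
# Stream I/O
# ---------------------------------------------------------------------------

def _infer_fps(ts: np.ndarray) -> float:
    if len(ts) < 2:
        return 0.0
    dt = float(np.median(np.diff(ts)))
    return 1.0 / dt if dt > 0 else 0.0


def load_landmark_stream(path: str | Path, schema: SchemaId) -> LandmarkStream:
    """Load a landmark stream from CSV or JSONL (by file extension).

    Frames with confidence below the configured floor are *flagged* through
    :meth:`LandmarkStream.quality_mask`, never dropped here.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"landmark file not found: {path}")
    n_expected = _N_POINTS.get(schema)
    if n_expected is None:
        raise SchemaError(f"unknown schema {schema!r}")
    if path.suffix.lower() == ".jsonl":
        frames = list(_read_jsonl(path, schema))
    else:
        frames = list(_read_csv(path, schema))
    ts = np.array([f.t for f in frames])
    return LandmarkStream(schema, frames, fps=_infer_fps(ts))


def _read_jsonl(path: Path, schema: SchemaId) -> Iterable[LandmarkFrame]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise ParseError(f"{path}:{lineno}: invalid JSON ({e.msg})")
            if rec.get("schema", schema) != schema:
                raise SchemaError(
                    f"{path}:{lineno}: schema {rec.get('schema')!r}, "
                    f"expected {schema!r}"
                )
            pts = np.asarray(rec["points"], dtype=float)
            if pts.ndim != 2 or pts.shape != (_N_POINTS[schema], 2):
                raise SchemaError(
                    f"{path}:{lineno}: expected {_N_POINTS[schema]} points, "
                    f"got {pts.shape[0] if pts.ndim == 2 else '?'}"
                )
            yield LandmarkFrame(
                t=float(rec["t"]), schema=schema, points=pts,
                confidence=float(rec.get("conf", 1.0)),
            )


def _read_csv(path: Path, schema: SchemaId) -> Iterable[LandmarkFrame]:
    try:
        df = pd.read_csv(path)
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: could not parse CSV: {e}")
    required = {"t", "schema", "idx", "x", "y", "conf"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    bad = df[df["schema"] != schema]
    if len(bad):
        raise SchemaError(
            f"{path}: row {bad.index[0] + 2} has schema "
            f"{bad.iloc[0]['schema']!r}, expected {schema!r}"
        )
    n = _N_POINTS[schema]
    base = 1 if schema == "face68" else 0
    for t, grp in df.groupby("t", sort=True):
        if len(grp) != n:
            raise SchemaError(
                f"{path}: frame t={t} has {len(grp)} points, expected {n}"
            )
        grp = grp.sort_values("idx")
        expected_idx = np.arange(base, base + n)
        if not np.array_equal(grp["idx"].to_numpy(), expected_idx):
            raise SchemaError(f"{path}: frame t={t} has non-contiguous idx")
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(pts)):
            raise SchemaError(f"{path}: frame t={t} has non-finite coords")
        yield LandmarkFrame(
            t=float(t), schema=schema, points=pts,
            confidence=float(grp["conf"].min()),
        )


def write_landmark_stream(stream: LandmarkStream, path: str | Path) -> None:
    """Write a stream to CSV or JSONL (by extension); round-trips exactly."""
    path = Path(path)
    if path.suffix.lower() == ".jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for f in stream.frames:
                fh.write(json.dumps({
                    "t": f.t, "schema": f.schema,
                    "points": f.points.tolist(), "conf": f.confidence,
                }) + "\n")
        return
    base = 1 if stream.schema == "face68" else 0
    rows = []
    for f in stream.frames:
        for i, (x, y) in enumerate(f.points):
            rows.append((f.t, f.schema, base + i, x, y, f.confidence))
    pd.DataFrame(rows, columns=["t", "schema", "idx", "x", "y", "conf"]) \
        .to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Geometric ROI extraction
# ---------------------------------------------------------------------------

def eye_rois(face: FaceLandmarkFrame, pad: float = 4.0
             ) -> tuple[RegionOfInterest, RegionOfInterest]:
    """Axis-aligned boxes around the two eye hexagons, padded and clipped.

    Returns ``(left, right)`` in subject terms (the subject's left eye is
    face68 indices 43-48). Each box is the bounding box of the 6 eye points
    expanded by ``pad`` px on every side, clipped to the frame when
    ``face.frame_size`` is known.
    """
    out = []
    for kind, rng in (("eye_left", FACE68["left_eye"]),
                      ("eye_right", FACE68["right_eye"])):
        pts = face_slice(face.points, rng)
        if not np.all(np.isfinite(pts)):
            raise GeometryError(f"{kind}: non-finite eye landmarks")
        x0, y0 = pts.min(axis=0) - pad
        x1, y1 = pts.max(axis=0) + pad
        if face.frame_size is not None:
            w, h = face.frame_size
            x0, y0 = max(x0, 0.0), max(y0, 0.0)
            x1, y1 = min(x1, float(w)), min(y1, float(h))
        if x1 <= x0 or y1 <= y0:
            raise GeometryError(f"{kind}: degenerate box after clipping")
        out.append(RegionOfInterest(kind, _box_polygon(x0, y0, x1, y1), face.t))
    return out[0], out[1]


def cheek_roi(face: FaceLandmarkFrame,
              side: Literal["left", "right", "both"] = "both"
              ) -> RegionOfInterest:
    """Cheek quadrilateral through jaw points 3, 15, 13, 5 (1-based).

    ``side='left'`` / ``'right'`` restricts to the half of that polygon on
    the subject's left/right of the vertical line through its centroid.
    In image coordinates the subject's left is the larger-x half (frontal,
    un-mirrored view).
    """
    quad = np.array([face_point(face.points, i) for i in CHEEK_QUAD])
    if not np.all(np.isfinite(quad)):
        raise GeometryError("cheek polygon has non-finite vertices")
    poly = Polygon(quad)
    if not poly.is_valid:
        raise GeometryError("cheek polygon is self-intersecting")
    if side == "both":
        return RegionOfInterest("cheek_both", quad, face.t)
    cx = poly.centroid.x
    x0, y0, x1, y1 = poly.bounds
    m = 10.0  # margin so the clip box always covers the polygon
    if side == "right":  # subject's right = smaller x in a frontal image
        clip = Polygon(_box_polygon(x0 - m, y0 - m, cx, y1 + m))
    elif side == "left":
        clip = Polygon(_box_polygon(cx, y0 - m, x1 + m, y1 + m))
    else:
        raise InputError(f"side must be left/right/both, got {side!r}")
    half = poly.intersection(clip)
    if half.is_empty or half.area <= 0:
        raise GeometryError(f"cheek half ({side}) is empty")
    verts = np.asarray(half.exterior.coords[:-1], dtype=float)
    return RegionOfInterest(f"cheek_{side}", verts, face.t)


@dataclass(frozen=True)
class HorizontalLine:
    """Image-horizontal reference line (y = const, slope fixed at 0)."""

    y: float

    def y_at(self, x: float) -> float:
        return self.y


def torso_horizontal(body: BodyLandmarkFrame) -> HorizontalLine:
    """Horizontal reference through the shoulder midpoint.

    The direction is fixed to the image x-axis: shoulder tilt moves the
    line's height (midpoint y) but never rotates it.
    """
    ls = body.points[BODY33["left_shoulder"]]
    rs = body.points[BODY33["right_shoulder"]]
    if not (np.all(np.isfinite(ls)) and np.all(np.isfinite(rs))):
        raise InputError("shoulder landmark missing or non-finite")
    return HorizontalLine(y=float((ls[1] + rs[1]) / 2.0))
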