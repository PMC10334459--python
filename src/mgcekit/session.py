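"""Session orchestration: config in, per-exercise analysis, JSON report out.

A session config names the input files (landmark streams per exercise,
audio per voice exercise), the per-exercise time windows, manual
annotations for the visually graded items, an optional pixel calibration,
and a seed. :func:`run_session` runs every configured exercise analyzer,
isolating failures to the exercise that raised them (its status becomes
``skipped`` with the reason; the session always completes), grades what
is gradable, and returns a schema-validated report.

The exercise windows come from the config, not from auto-detection: the
examiner drives the timing of a real session.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .errors import InputError, MGCEError
from .facial import detect_deformation_events, mouth_feature_series, \
    side_switch_detector
from .grading import grade_session
from .landmarks import load_landmark_stream
from .motor import (PixelCalibration, arm_angle_series, calibrate_pixels,
                    stand_kinematics)
from .voice import compute_voice_features, read_wav

log = logging.getLogger("mgcekit")

EXERCISES = ("ptosis", "diplopia", "cheek_puff", "tongue_to_cheek",
             "count50", "arm_strength", "single_breath", "sit_to_stand")


# ---------------------------------------------------------------------------
# config schema
# ---------------------------------------------------------------------------


class WindowModel(BaseModel):
    t0: float = 0.0
    t1: float = Field(default=1e9)

    @field_validator("t1")
    @classmethod
    def _ordered(cls, v, info):
        if v <= info.data.get("t0", 0.0):
            raise ValueError("window t1 must exceed t0")
        return v


class CalibrationModel(BaseModel):
    object_id: str = "seat"
    length_cm: float = Field(gt=0)
    span_px: float = Field(gt=0)


class ExerciseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window: WindowModel = WindowModel()
    landmarks: Optional[str] = None     # path to a landmark stream
    audio: Optional[str] = None         # path to a WAV file
    annotation: Optional[dict[str, Any]] = None
    params: dict[str, Any] = Field(default_factory=dict)


class SessionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    exercises: dict[str, ExerciseConfig] = Field(default_factory=dict)
    calibration: Optional[CalibrationModel] = None
    seed: int = 0
    base_dir: Optional[str] = None      # paths resolved against this

    @field_validator("exercises")
    @classmethod
    def _known(cls, v):
        unknown = set(v) - set(EXERCISES)
        if unknown:
            raise ValueError(f"unknown exercises: {sorted(unknown)}")
        return v

    def resolve(self, path: str) -> Path:
        p = Path(path)
        if not p.is_absolute() and self.base_dir:
            p = Path(self.base_dir) / p
        return p


def load_session_config(path: str | Path) -> SessionConfig:
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    data = (yaml.safe_load(text) if path.suffix in (".yml", ".yaml")
            else json.loads(text))
    cfg = SessionConfig.model_validate(data)
    if cfg.base_dir is None:
        cfg.base_dir = str(path.parent)
    return cfg


# ---------------------------------------------------------------------------
# report schema
# ---------------------------------------------------------------------------


class ExerciseResult(BaseModel):
    model_config = ConfigDict(extra="forbid")
    status: str = Field(pattern="^(ok|partial|skipped)$")
    metrics: dict[str, Any] = Field(default_factory=dict)
    reason: Optional[str] = None


class GradeModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grade: int = Field(ge=0, le=3)
    basis: str
    note: str = ""


class SessionReport(BaseModel):
    model_config = ConfigDict(extra="forbid")
    version: str
    config_hash: str
    seed: int
    exercises: dict[str, ExerciseResult]
    grades: dict[str, GradeModel] = Field(default_factory=dict)
    ungradable: dict[str, str] = Field(default_factory=dict)

    @field_validator("exercises")
    @classmethod
    def _all_present(cls, v):
        missing = set(EXERCISES) - set(v)
        if missing:
            raise ValueError(f"report missing exercises: {sorted(missing)}")
        return v


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_report(report: SessionReport, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(report.model_dump(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8")


def read_report(path: str | Path) -> SessionReport:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return SessionReport.model_validate(data)


# ---------------------------------------------------------------------------
# per-exercise analyzers
# ---------------------------------------------------------------------------


def _analyze_voice(cfg: SessionConfig, ex: ExerciseConfig,
                   counting: bool) -> dict:
    if not ex.audio:
        raise InputError("no audio path configured")
    track = read_wav(cfg.resolve(ex.audio))
    t0, t1 = ex.window.t0, min(ex.window.t1, track.duration)
    i0, i1 = int(t0 * track.fs), int(t1 * track.fs)
    from .voice import AudioTrack
    feats = compute_voice_features(
        AudioTrack(track.samples[i0:i1], track.fs), counting=counting,
        **{k: v for k, v in ex.params.items() if k in ("noise_k",)})
    return {k: _jsonable(v) for k, v in vars(feats).items()}


def _analyze_arm(cfg: SessionConfig, ex: ExerciseConfig) -> dict:
    if not ex.landmarks:
        raise InputError("no landmark stream configured")
    stream = load_landmark_stream(cfg.resolve(ex.landmarks), "body33")
    stream = stream.window(ex.window.t0, ex.window.t1)
    series = arm_angle_series(stream)
    return {
        "drift_onset_left_s": series.drift_onset_left,
        "drift_onset_right_s": series.drift_onset_right,
        "theta_left_final_deg": float(series.theta_left_smooth[-1]),
        "theta_right_final_deg": float(series.theta_right_smooth[-1]),
    }


def _analyze_stand(cfg: SessionConfig, ex: ExerciseConfig) -> dict:
    if not ex.landmarks:
        raise InputError("no landmark stream configured")
    stream = load_landmark_stream(cfg.resolve(ex.landmarks), "body33")
    stream = stream.window(ex.window.t0, ex.window.t1)
    calib = None
    if cfg.calibration is not None:
        calib = calibrate_pixels(cfg.calibration.length_cm,
                                 cfg.calibration.span_px,
                                 cfg.calibration.object_id)
    kin = stand_kinematics(stream, calib)
    out = {
        "rise_start_s": kin.rise_start, "rise_end_s": kin.rise_end,
        "peak_speed_px_s": kin.peak_speed,
        "peak_acceleration_px_s2": kin.peak_acceleration,
        "lateral_sway_px": kin.lateral_sway,
    }
    if kin.peak_speed_cm_s is not None:
        out["peak_speed_cm_s"] = kin.peak_speed_cm_s
    return out


def _analyze_mouth(cfg: SessionConfig, ex: ExerciseConfig,
                   tongue: bool) -> dict:
    if not ex.landmarks:
        raise InputError("no landmark stream configured")
    stream = load_landmark_stream(cfg.resolve(ex.landmarks), "face68")
    stream = stream.window(ex.window.t0, ex.window.t1)
    feats = mouth_feature_series(stream)
    events = detect_deformation_events(feats.t, feats.upper_lip_nose_distance,
                                       mask=feats.mask)
    out: dict[str, Any] = {
        "n_events": len(events),
        "events": [{"start_s": e.start, "end_s": e.end,
                    "amplitude": e.amplitude} for e in events],
        "seal_fraction": float(np.mean(feats.seal)),
    }
    if tongue:
        out["switch_time_s"] = side_switch_detector(
            feats.t, feats.mouth_angle)
    return out


_ANALYZERS = {
    "count50": lambda c, e: _analyze_voice(c, e, counting=True),
    "single_breath": lambda c, e: _analyze_voice(c, e, counting=False),
    "arm_strength": _analyze_arm,
    "sit_to_stand": _analyze_stand,
    "cheek_puff": lambda c, e: _analyze_mouth(c, e, tongue=False),
    "tongue_to_cheek": lambda c, e: _analyze_mouth(c, e, tongue=True),
}


# ---------------------------------------------------------------------------
# session driver
# ---------------------------------------------------------------------------


def _config_hash(cfg: SessionConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_session(config: SessionConfig) -> SessionReport:
    """Run every configured exercise; failures isolate to their exercise."""
    if not isinstance(config, SessionConfig):
        raise InputError("run_session needs a validated SessionConfig")
    exercises: dict[str, ExerciseResult] = {}
    bundle: dict[str, dict[str, Any]] = {}
    for name in EXERCISES:
        ex = config.exercises.get(name)
        if ex is None:
            exercises[name] = ExerciseResult(status="skipped",
                                             reason="not configured")
            continue
        metrics: dict[str, Any] = {}
        status, reason = "ok", None
        analyzer = _ANALYZERS.get(name)
        has_media = bool(ex.landmarks or ex.audio)
        if has_media and analyzer is not None:
            try:
                log.info("analyzing %s", name)
                metrics = _jsonable(analyzer(config, ex))
            except Exception as e:   # crash isolation, by design
                log.warning("%s failed: %s", name, e)
                status, reason = "skipped", f"{type(e).__name__}: {e}"
        if ex.annotation is not None:
            metrics["annotation"] = ex.annotation
            bundle[name] = dict(ex.annotation)
            if status == "skipped":
                status = "partial"    # annotation salvages the grade
        elif not (has_media and analyzer is not None):
            status, reason = "skipped", "no inputs configured"
        exercises[name] = ExerciseResult(status=status, metrics=metrics,
                                         reason=reason)
        # automated metrics that grade directly
        if name == "arm_strength" and "drift_onset_left_s" in metrics:
            onsets = [metrics.get("drift_onset_left_s"),
                      metrics.get("drift_onset_right_s")]
            onsets = [o for o in onsets if o is not None]
            bundle.setdefault(name, {})["onset_s"] = (
                min(onsets) if onsets else None)
    grades = grade_session(bundle) if bundle else None
    report = SessionReport(
        version=__version__, config_hash=_config_hash(config),
        seed=config.seed, exercises=exercises,
        grades={r.item.value: GradeModel(grade=r.grade, basis=r.basis,
                                         note=r.note)
                for r in (grades.results if grades else [])},
        ungradable=(grades.ungradable if grades else {}),
    )
    return report
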