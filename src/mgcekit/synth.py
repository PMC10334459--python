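"""Seeded synthetic fixtures with analytic ground truth.

Every metric module in the toolbox is testable without patient data through
three generators that emulate the telehealth acquisition regime:

* :func:`render_eye_sequence` — tiny eye patches (default 40x20 px, the
  size of an eye in a standard video call) built from an anti-aliased iris
  disc framed by parabolic lid occluders, with optional linear lid descent
  (ptosis) and Gaussian pixel noise;
* :func:`gen_body_stream` — 33-point body landmark streams for the
  arm-hold (drift onset + angular slope) and sit-to-stand (smoothstep rise
  with lateral sway) scenarios, with Gaussian landmark jitter;
* :func:`gen_counting_audio` — counting exercises as sine bursts with
  raised-cosine on/offsets over Gaussian noise at a stated SNR;
* :func:`gen_ptosis_geometry` — eye-geometry time series with an injected
  linear decay of the lid-to-pupil distance, bypassing the renderer when
  only the downstream metric chain is under test.

Rendering is deliberately simple (discs and parabolas, not photorealism):
the point is exact, analytically known geometry at the resolution and noise
level the deployed pipeline actually faces. All randomness flows through a
caller-provided seed; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .eye import EyeGeometry
from .landmarks import BODY33, LandmarkFrame, LandmarkStream

# ---------------------------------------------------------------------------
# Eye scenes
# ---------------------------------------------------------------------------


@dataclass
class EyeSceneParams:
    """Geometry and photometry of a rendered eye patch sequence.

    Intensities are in [0, 1]; pixel coordinates have the origin at the
    patch's top-left with y downward. ``decay_fraction`` is the fraction of
    the initial lid-to-pupil distance lost (linearly) from the first to the
    last frame of a sequence.
    """

    size: tuple[int, int] = (40, 20)          # (width, height) px
    pupil_center: tuple[float, float] = (20.0, 10.0)
    iris_radius: float = 6.0
    upper_lid_apex: float = 3.0               # y of the upper lid at pupil x
    lower_lid_apex: float = 17.0
    lid_curvature: float = 0.02               # 1/px, parabola coefficient
    sclera: float = 0.92
    iris: float = 0.15
    skin: float = 0.62
    noise_sigma: float = 0.0
    decay_fraction: float = 0.0               # f in [0, 1)
    seed: int = 0

    def __post_init__(self):
        w, h = self.size
        px, py = self.pupil_center
        if self.iris_radius >= h:
            raise ParameterError("iris radius exceeds patch height")
        if not (0 < px < w and 0 < py < h):
            raise ParameterError("pupil center outside patch")
        if not 0.0 <= self.decay_fraction < 1.0:
            raise ParameterError("decay fraction must be in [0, 1)")
        if not self.upper_lid_apex < py:
            raise ParameterError("upper lid apex must sit above the pupil")


def _lid_curves(p: EyeSceneParams, upper_apex: float, xs: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    cx = p.pupil_center[0]
    yu = upper_apex + p.lid_curvature * (xs - cx) ** 2
    yl = p.lower_lid_apex - p.lid_curvature * (xs - cx) ** 2
    return yu, yl


def _render_frame(p: EyeSceneParams, upper_apex: float, ss: int = 4
                  ) -> np.ndarray:
    """Supersampled render: skin / opening(sclera) / iris disc, then box
    down-sampling gives anti-aliased edges."""
    w, h = p.size
    xs = (np.arange(w * ss) + 0.5) / ss
    ys = (np.arange(h * ss) + 0.5) / ss
    X, Y = np.meshgrid(xs, ys)
    yu, yl = _lid_curves(p, upper_apex, xs)
    opening = (Y >= yu[None, :]) & (Y <= yl[None, :])
    img = np.full((h * ss, w * ss), p.skin)
    img[opening] = p.sclera
    px, py = p.pupil_center
    disc = (X - px) ** 2 + (Y - py) ** 2 <= p.iris_radius ** 2
    img[opening & disc] = p.iris
    return img.reshape(h, ss, w, ss).mean(axis=(1, 3))


def _ground_truth(p: EyeSceneParams, upper_apex: float) -> EyeGeometry:
    px, py = p.pupil_center
    r = p.iris_radius
    cols = np.arange(int(math.ceil(px - r)), int(math.floor(px + r)) + 1,
                     dtype=float)
    yu, yl = _lid_curves(p, upper_apex, cols)
    return EyeGeometry(
        pupil_center=(px, py),
        iris_x_left=px - r, iris_x_right=px + r,
        iris_bottom_y=min(py + r, float(np.max(yl))),
        columns=cols, upper_lid=yu, lower_lid=yl, quality="ok",
    )


def render_eye_sequence(params: EyeSceneParams, n_frames: int = 1
                        ) -> tuple[list[np.ndarray], list[EyeGeometry]]:
    """Render a patch sequence plus per-frame ground-truth geometry.

    With ``decay_fraction=f`` the upper lid descends linearly so that the
    lid-to-pupil distance at the last frame is ``(1-f)`` times its initial
    value. Noise is Gaussian, seeded from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    px, py = params.pupil_center
    d0 = py - params.upper_lid_apex
    frames, truths = [], []
    for k in range(n_frames):
        frac = k / (n_frames - 1) if n_frames > 1 else 0.0
        apex = py - d0 * (1.0 - params.decay_fraction * frac)
        img = _render_frame(params, apex)
        if params.noise_sigma > 0:
            img = img + rng.normal(0.0, params.noise_sigma, img.shape)
        frames.append(np.clip(img, 0.0, 1.0))
        truths.append(_ground_truth(params, apex))
    return frames, truths


def random_eye_params(rng: np.random.Generator,
                      noise_sigma: float = 0.05) -> EyeSceneParams:
    """Randomized but always-valid telehealth-resolution eye scene."""
    w, h = 40, 20
    r = float(rng.uniform(4.5, 7.0))
    px = float(rng.uniform(w / 2 - 4, w / 2 + 4))
    py = float(rng.uniform(h / 2 - 1.5, h / 2 + 1.5))
    upper = float(rng.uniform(max(1.0, py - r - 2.0), py - 3.5))
    lower = float(rng.uniform(py + 3.5, min(h - 1.0, py + r + 2.0)))
    return EyeSceneParams(
        size=(w, h), pupil_center=(px, py), iris_radius=r,
        upper_lid_apex=upper, lower_lid_apex=lower,
        lid_curvature=float(rng.uniform(0.01, 0.03)),
        sclera=float(rng.uniform(0.85, 0.97)),
        iris=float(rng.uniform(0.05, 0.25)),
        skin=float(rng.uniform(0.5, 0.72)),
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Ptosis geometry series (metric-chain fixture, renderer bypassed)
# ---------------------------------------------------------------------------

def gen_ptosis_geometry(decay_fraction: float = 0.15,
                        duration_s: float = 60.0, fps: float = 10.0,
                        baseline_px: float = 7.0,
                        noise_sigma_frac: float = 0.02,
                        seed: int = 0
                        ) -> tuple[list[EyeGeometry], np.ndarray, dict]:
    """Eye-geometry series whose lid-to-pupil distance decays linearly.

    ``noise_sigma_frac`` is multiplicative noise relative to the baseline
    distance (2% emulates frame-to-frame segmentation jitter). Returns
    (geometries, times, ground_truth).
    """
    if not 0.0 <= decay_fraction < 1.0:
        raise ParameterError("decay fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_s, 1.0 / fps)
    pupil = (20.0, 10.0)
    r = 6.0
    cols = np.arange(14.0, 27.0)
    geoms = []
    for t in times:
        d_true = baseline_px * (1.0 - decay_fraction * t / duration_s)
        d = d_true + rng.normal(0.0, noise_sigma_frac * baseline_px)
        yu = (pupil[1] - d) + 0.02 * (cols - pupil[0]) ** 2
        yl = (pupil[1] + 6.0) - 0.02 * (cols - pupil[0]) ** 2
        geoms.append(EyeGeometry(
            pupil_center=pupil, iris_x_left=pupil[0] - r,
            iris_x_right=pupil[0] + r, iris_bottom_y=pupil[1] + r,
            columns=cols, upper_lid=yu, lower_lid=yl, quality="ok",
        ))
    truth = {
        "decay_fraction": decay_fraction,
        "percent_decay": 100.0 * decay_fraction * (times[-1] - times[0])
                         / duration_s,
        "slope_px_s": -baseline_px * decay_fraction / duration_s,
        "baseline_px": baseline_px,
    }
    return geoms, times, truth


# ---------------------------------------------------------------------------
# Body landmark scenarios
# ---------------------------------------------------------------------------

#: static template of a seated/standing adult in a 640x480 frame (px)
_BODY_TEMPLATE = {
    0: (320, 80),                      # nose
    11: (270, 160), 12: (370, 160),    # shoulders (left, right)
    13: (210, 160), 14: (430, 160),    # elbows, arms extended horizontally
    15: (150, 160), 16: (490, 160),    # wrists
    23: (290, 300), 24: (350, 300),    # hips
    25: (285, 380), 26: (355, 380),    # knees
    27: (285, 450), 28: (355, 450),    # ankles
}


def _body_points(overrides: dict[int, tuple[float, float]]) -> np.ndarray:
    pts = np.zeros((33, 2))
    for i in range(33):
        pts[i] = _BODY_TEMPLATE.get(i, (320.0, 240.0))
    for i, xy in overrides.items():
        pts[i] = xy
    return pts


@dataclass
class MotionScenario:
    """Parameters for a generated body-landmark exercise."""

    kind: str = "arm_hold"        # arm_hold | sit_to_stand
    duration_s: float = 120.0
    fps: float = 10.0
    jitter_sigma: float = 0.0     # px, Gaussian, both axes
    seed: int = 0
    # arm_hold
    drift_onset_s: float | None = None
    drift_slope_deg_s: float = -2.0
    # sit_to_stand
    rise_start_s: float = 2.0
    rise_duration_s: float = 1.0
    seated_hip_y: float = 300.0
    standing_hip_y: float = 180.0
    sway_amplitude_px: float = 0.0
    sway_freq_hz: float = 1.5

    def __post_init__(self):
        if self.fps <= 0 or self.duration_s <= 0:
            raise ParameterError("fps and duration must be positive")
        if (self.drift_onset_s is not None
                and self.drift_onset_s >= self.duration_s):
            raise ParameterError("drift onset beyond exercise duration")


def _arm_positions(theta_deg: float, shoulder, length: float, side: str):
    th = math.radians(theta_deg)
    sx, sy = shoulder
    dx = length * math.cos(th) * (1 if side == "right" else -1)
    return (sx + dx, sy - length * math.sin(th))   # y down: raised arm -> -y


def gen_body_stream(sc: MotionScenario) -> tuple[LandmarkStream, dict]:
    """Kinematically consistent body33 stream + analytic ground truth."""
    rng = np.random.default_rng(sc.seed)
    times = np.arange(0.0, sc.duration_s, 1.0 / sc.fps)
    frames = []
    if sc.kind == "arm_hold":
        arm_len = 60.0
        theta = np.zeros_like(times)
        if sc.drift_onset_s is not None:
            after = times >= sc.drift_onset_s
            theta[after] = sc.drift_slope_deg_s * (times[after]
                                                   - sc.drift_onset_s)
        theta = np.clip(theta, -85.0, 85.0)
        for t, th in zip(times, theta):
            ov = {
                13: _arm_positions(th, _BODY_TEMPLATE[11], arm_len, "left"),
                14: _arm_positions(th, _BODY_TEMPLATE[12], arm_len, "right"),
            }
            pts = _body_points(ov)
            if sc.jitter_sigma > 0:
                pts = pts + rng.normal(0, sc.jitter_sigma, pts.shape)
            frames.append(LandmarkFrame(t=float(t), schema="body33",
                                        points=pts,
                                        frame_size=(640, 480)))
        truth = {"theta_deg": theta, "onset_s": sc.drift_onset_s,
                 "slope_deg_s": sc.drift_slope_deg_s}
    elif sc.kind == "sit_to_stand":
        dy = sc.seated_hip_y - sc.standing_hip_y
        y = np.full_like(times, sc.seated_hip_y)
        u = (times - sc.rise_start_s) / sc.rise_duration_s
        mid = (u >= 0) & (u <= 1)
        y[mid] = sc.seated_hip_y - dy * (3 * u[mid] ** 2 - 2 * u[mid] ** 3)
        y[u > 1] = sc.standing_hip_y
        for t, yh in zip(times, y):
            sway = (sc.sway_amplitude_px
                    * math.sin(2 * math.pi * sc.sway_freq_hz * t))
            ov = {23: (290.0 + sway, yh), 24: (350.0 + sway, yh),
                  11: (270.0 + sway, yh - 140.0),
                  12: (370.0 + sway, yh - 140.0),
                  0: (320.0 + sway, yh - 220.0)}
            pts = _body_points(ov)
            if sc.jitter_sigma > 0:
                pts = pts + rng.normal(0, sc.jitter_sigma, pts.shape)
            frames.append(LandmarkFrame(t=float(t), schema="body33",
                                        points=pts,
                                        frame_size=(640, 480)))
        truth = {
            "rise_start_s": sc.rise_start_s,
            "rise_end_s": sc.rise_start_s + sc.rise_duration_s,
            # max d/du of smoothstep is 1.5 at u = 1/2
            "peak_speed_px_s": 1.5 * dy / sc.rise_duration_s,
            "sway_rms_px": sc.sway_amplitude_px / math.sqrt(2.0),
        }
    else:
        raise ParameterError(f"unknown scenario kind {sc.kind!r}")
    return LandmarkStream("body33", frames, sc.fps), truth


# ---------------------------------------------------------------------------
# Face landmark streams
# ---------------------------------------------------------------------------

def face68_template() -> np.ndarray:
    """A bilaterally symmetric resting face68 layout in a 200x200 frame.

    1-based semantics follow the standard annotation (jaw 1-17, eyes
    37-48, nose 28-36, mouth 49-68); returned as a (68, 2) array indexed
    0-based. Symmetric about x = 100 so mirror-image properties can be
    tested exactly.
    """
    pts = np.zeros((68, 2))
    phis = np.pi * np.arange(17) / 16.0
    pts[0:17, 0] = 100.0 - 60.0 * np.cos(phis)       # jaw
    pts[0:17, 1] = 85.0 + 85.0 * np.sin(phis)
    pts[17:22] = np.column_stack([np.linspace(55, 85, 5),
                                  np.full(5, 65.0)])  # brows
    pts[22:27] = np.column_stack([np.linspace(115, 145, 5),
                                  np.full(5, 65.0)])
    pts[27:31] = np.column_stack([np.full(4, 100.0),
                                  np.linspace(70, 100, 4)])  # nose bridge
    pts[31:36] = [(88, 108), (94, 110), (100, 112), (106, 110), (112, 108)]
    pts[36:42] = [(55, 80), (62, 76), (72, 76),
                  (79, 80), (72, 84), (62, 84)]       # right eye
    pts[42:48] = [(121, 80), (128, 76), (138, 76),
                  (145, 80), (138, 84), (128, 84)]    # left eye
    pts[48:60] = [(75, 140), (83, 134), (91, 131), (100, 130), (109, 131),
                  (117, 134), (125, 140), (117, 146), (109, 149),
                  (100, 150), (91, 149), (83, 146)]   # outer lips
    pts[60:68] = [(80, 140), (91, 137), (100, 136), (109, 137),
                  (120, 140), (109, 143), (100, 144), (91, 143)]
    return pts


@dataclass
class FaceScenario:
    """Face-landmark exercise: cheek-puff lip raise and/or tongue switch."""

    duration_s: float = 15.0
    fps: float = 10.0
    jitter_sigma: float = 0.0
    seed: int = 0
    # cheek puff: raise the upper lip (and nose-lip gap) by `px` on [t0,t1]
    lip_raise: tuple[float, float, float] | None = None   # (t0, t1, px)
    # tongue push: rotate the mouth by +deg, then -deg after switch_t
    angle_push: tuple[float, float] | None = None         # (switch_t, deg)


def gen_face_stream(sc: FaceScenario) -> tuple[LandmarkStream, dict]:
    """face68 stream for the cheek exercises, with ground truth."""
    rng = np.random.default_rng(sc.seed)
    times = np.arange(0.0, sc.duration_s, 1.0 / sc.fps)
    base = face68_template()
    mouth_idx = np.arange(48, 68)
    mouth_ctr = base[mouth_idx].mean(axis=0)
    frames = []
    for t in times:
        pts = base.copy()
        if sc.lip_raise is not None:
            t0, t1, px = sc.lip_raise
            if t0 <= t <= t1:
                # upper lip (outer 50-54, inner 62-64) moves up = -y
                for i in list(range(49, 54)) + list(range(61, 64)):
                    pts[i, 1] -= px
        if sc.angle_push is not None:
            switch_t, deg = sc.angle_push
            ang = math.radians(deg if t < switch_t else -deg)
            c, s = math.cos(ang), math.sin(ang)
            rel = pts[mouth_idx] - mouth_ctr
            pts[mouth_idx] = rel @ np.array([[c, s], [-s, c]]) + mouth_ctr
        if sc.jitter_sigma > 0:
            pts = pts + rng.normal(0, sc.jitter_sigma, pts.shape)
        frames.append(LandmarkFrame(t=float(t), schema="face68", points=pts,
                                    frame_size=(200, 200)))
    truth = {"lip_raise": sc.lip_raise, "angle_push": sc.angle_push}
    return LandmarkStream("face68", frames, sc.fps), truth


# ---------------------------------------------------------------------------
# Counting audio
# ---------------------------------------------------------------------------


@dataclass
class AudioScenario:
    """Counting-exercise audio: n tone bursts with silences over noise."""

    n_bursts: int = 50
    burst_s: float = 0.5
    pause_s: float = 0.5
    f0_hz: float = 140.0
    amplitude: float = 0.3
    snr_db: float = 20.0
    fs: int = 16000
    lead_s: float = 1.0               # silence before the first burst
    ramp_s: float = 0.02              # raised-cosine on/offset
    seed: int = 0

    def __post_init__(self):
        if self.n_bursts < 0:
            raise ParameterError("n_bursts must be >= 0")
        if self.fs < 8000:
            raise ParameterError("fs must be >= 8000 Hz")


def gen_counting_audio(sc: AudioScenario) -> tuple["AudioTrack", list]:
    """Generate counting audio; returns (track, ground-truth segments).

    Ground truth is the list of (start, end) burst intervals in seconds.
    Noise power is set from the burst power and the stated SNR; silence
    intervals contain noise only.
    """
    from .voice import AudioTrack

    rng = np.random.default_rng(sc.seed)
    total_s = sc.lead_s + sc.n_bursts * (sc.burst_s + sc.pause_s) + sc.lead_s
    n = int(round(total_s * sc.fs))
    x = np.zeros(n)
    truth = []
    nb = int(round(sc.burst_s * sc.fs))
    ramp = int(round(sc.ramp_s * sc.fs))
    win = np.ones(nb)
    if ramp > 0:
        edge = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp)))
        win[:ramp] = edge
        win[-ramp:] = edge[::-1]
    for k in range(sc.n_bursts):
        t0 = sc.lead_s + k * (sc.burst_s + sc.pause_s)
        i0 = int(round(t0 * sc.fs))
        tt = np.arange(nb) / sc.fs
        x[i0:i0 + nb] += sc.amplitude * win * np.sin(2 * np.pi * sc.f0_hz * tt)
        truth.append((t0, t0 + sc.burst_s))
    if sc.amplitude > 0 and np.isfinite(sc.snr_db):
        p_sig = sc.amplitude ** 2 / 2.0
        sigma = math.sqrt(p_sig / 10 ** (sc.snr_db / 10.0))
        x = x + rng.normal(0.0, sigma, n)
    return AudioTrack(samples=np.clip(x, -1.0, 1.0), fs=sc.fs), truth
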