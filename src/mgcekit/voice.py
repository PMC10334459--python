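"""Voice features for the counting-to-50 and single-breath exercises.

The analysis chain mirrors how a clinician-facing toolbox digests a
counting exercise recorded over a telehealth link:

1. the raw waveform (>= 8 kHz) is rectified and RMS-resampled to a
   ~1000 Hz magnitude series, then block-averaged (block 60) into a
   ~17 Hz envelope that is smooth enough for simple thresholding;
2. speech segments are runs of the envelope above a noise threshold, with
   sub-0.15 s gaps bridged so a syllable is not split into fragments; for
   a counting-to-50 exercise the 50 longest segments are retained;
3. per exercise: integrated loudness (ITU-R BS.1770-4 / EBU R128
   K-weighted, gated), fundamental frequency per segment (normalized
   autocorrelation, 50-400 Hz — spanning typical adult male 85-155 Hz and
   female 165-255 Hz voices), L2 spectral energy in the 5-25 Hz breathing
   band of the magnitude series, Teager-Kaiser energy, spectral entropy,
   and single-breath duration/energy features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .errors import InputError, ParameterError

# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class AudioTrack:
    """Mono waveform with amplitudes in [-1, 1]."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        x = np.asarray(self.samples, dtype=float)
        if x.ndim == 2:           # average channels to mono
            x = x.mean(axis=1)
        if not np.all(np.isfinite(x)):
            raise InputError("audio contains non-finite samples")
        if self.fs <= 0:
            raise InputError("sampling rate must be positive")
        self.samples = x

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def read_wav(path) -> AudioTrack:
    """Read a PCM WAV file, normalizing integer formats to [-1, 1]."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return AudioTrack(samples=data, fs=float(fs))


def write_wav(track: AudioTrack, path) -> None:
    x = np.clip(track.samples, -1.0, 1.0)
    wavfile.write(path, int(track.fs), (x * 32767).astype(np.int16))


@dataclass
class Envelope:
    """Block-averaged magnitude envelope (~17 Hz with the defaults)."""

    values: np.ndarray
    fs_env: float
    block: int
    duration: float             # of the originating track, seconds


@dataclass
class SpeechSegments:
    """Non-overlapping (start, end) speech intervals, in seconds."""

    segments: list[tuple[float, float]]
    duration: float             # total track duration

    def __post_init__(self):
        segs = sorted(self.segments)
        for (s0, e0), (s1, e1) in zip(segs, segs[1:]):
            if s1 < e0:
                raise ParameterError("speech segments overlap")
        self.segments = segs

    @property
    def voiced_fraction(self) -> float:
        if self.duration <= 0:
            return 0.0
        return sum(e - s for s, e in self.segments) / self.duration

    def sample_mask(self, n: int, fs: float) -> np.ndarray:
        m = np.zeros(n, dtype=bool)
        for s, e in self.segments:
            m[int(s * fs): int(math.ceil(e * fs))] = True
        return m

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class VoiceFeatureSet:
    """Feature summary of one voice exercise."""

    loudness_lufs: float
    pitch_median_hz: float
    pitch_iqr_hz: float
    pitch_defined: bool
    band_energy: float
    tke_mean: float
    entropy_mean: float
    entropy_peaks: int
    sb_duration_s: float
    sb_energy_integral: float
    voiced_fraction: float
    n_segments: int
    features_defined: bool = True


# ---------------------------------------------------------------------------
# envelope + segmentation
# ---------------------------------------------------------------------------

def magnitude_series(track: AudioTrack, intermediate_fs: float = 1000.0
                     ) -> tuple[np.ndarray, float]:
    """RMS magnitude of the waveform resampled to ``intermediate_fs``.

    Window boundaries are computed per output sample, so any input rate
    (44.1 kHz included) maps cleanly onto the intermediate rate.
    """
    x = track.samples
    n_out = int(len(x) * intermediate_fs / track.fs)
    if n_out < 1:
        raise ParameterError("track too short for the intermediate rate")
    edges = np.round(np.arange(n_out + 1) * track.fs / intermediate_fs
                     ).astype(int)
    sq = np.concatenate([[0.0], np.cumsum(x ** 2)])
    counts = np.diff(edges)
    counts[counts == 0] = 1
    mag = np.sqrt(np.diff(sq[edges]) / counts)
    return mag, intermediate_fs


def envelope(track: AudioTrack, intermediate_fs: float = 1000.0,
             block: int = 60) -> Envelope:
    """Rectify, RMS-resample to ``intermediate_fs``, block-average.

    ``fs_env = intermediate_fs / block`` exactly; the defaults give
    1000/60 = 16.67 Hz, i.e. about 17 envelope samples per second.
    """
    if track.duration < 1.0:
        raise ParameterError("need >= 1 s of audio for an envelope")
    mag, fs_m = magnitude_series(track, intermediate_fs)
    if block > len(mag):
        raise ParameterError(
            f"block ({block}) exceeds magnitude series length ({len(mag)})")
    n_blocks = len(mag) // block
    vals = mag[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    return Envelope(values=vals, fs_env=fs_m / block, block=block,
                    duration=track.duration)


def detect_speech_segments(env: Envelope, noise_k: float = 3.0,
                           bridge_gap_s: float = 0.15,
                           min_segment_s: float = 0.05) -> SpeechSegments:
    """Threshold the envelope into speech segments.

    The threshold is ``noise_k`` times the median envelope (for counting
    audio, roughly half the track is silence, so the median sits at the
    noise floor), capped at 90% of the envelope maximum so a continuous
    voiced track still yields a segment. Gaps shorter than
    ``bridge_gap_s`` are bridged; fragments shorter than
    ``min_segment_s`` are dropped.
    """
    v = env.values
    if len(v) == 0:
        raise ParameterError("empty envelope")
    vmax = float(v.max())
    if vmax <= 0:
        return SpeechSegments([], env.duration)
    thr = min(noise_k * float(np.median(v)), 0.9 * vmax)
    above = v > thr
    dt = 1.0 / env.fs_env
    # bridge short gaps
    runs = []
    start = None
    for i, b in enumerate(above):
        if b and start is None:
            start = i
        elif not b and start is not None:
            runs.append([start, i])
            start = None
    if start is not None:
        runs.append([start, len(v)])
    merged = []
    for s, e in runs:
        if merged and (s - merged[-1][1]) * dt < bridge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    segs = [(s * dt, e * dt) for s, e in merged
            if (e - s) * dt >= min_segment_s]
    return SpeechSegments(segs, env.duration)


def count50_segments(segments: SpeechSegments,
                     keep: int = 50) -> SpeechSegments:
    """The ``keep`` longest segments (ties -> earlier start), time-ordered."""
    ranked = sorted(segments.segments,
                    key=lambda se: (-(se[1] - se[0]), se[0]))
    return SpeechSegments(sorted(ranked[:keep]), segments.duration)


# ---------------------------------------------------------------------------
# loudness (ITU-R BS.1770-4 / EBU R128)
# ---------------------------------------------------------------------------

def _k_weighting(fs: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """The two K-weighting biquads, bilinear-transformed from the analog
    prototypes so the standard's tabulated 48 kHz coefficients are
    reproduced exactly and any other rate gets the matching response."""
    # stage 1: high-shelf (acoustic effects of the head)
    fc, q = 1681.9744509555319, 0.7071752369554196
    vh, vb, vl = 1.584864701130855, 1.2587209437531196, 1.0
    k = math.tan(math.pi * fc / fs)
    a0 = 1.0 + k / q + k * k
    shelf = (
        np.array([(vh + vb * k / q + vl * k * k) / a0,
                  2.0 * (vl * k * k - vh) / a0,
                  (vh - vb * k / q + vl * k * k) / a0]),
        np.array([1.0, 2.0 * (k * k - 1.0) / a0,
                  (1.0 - k / q + k * k) / a0]),
    )
    # stage 2: RLB high-pass
    fc, q = 38.13547087602444, 0.5003270373238773
    k = math.tan(math.pi * fc / fs)
    a0 = 1.0 + k / q + k * k
    hp = (
        np.array([1.0, -2.0, 1.0]),
        np.array([1.0, 2.0 * (k * k - 1.0) / a0,
                  (1.0 - k / q + k * k) / a0]),
    )
    return [shelf, hp]


def integrated_loudness(track: AudioTrack,
                        segments: SpeechSegments | None = None) -> float:
    """K-weighted, gated integrated loudness in LUFS.

    400 ms blocks with 75% overlap; -70 LUFS absolute gate, then a -10 LU
    gate relative to the absolute-gated mean (BS.1770-4). When
    ``segments`` is given the measurement is restricted to speech (the
    segment samples are concatenated first). Returns NaN when everything
    is gated out (digital silence).
    """
    if track.fs < 8000:
        raise ParameterError("loudness needs fs >= 8000 Hz for K-weighting")
    x = track.samples
    if segments is not None:
        m = segments.sample_mask(len(x), track.fs)
        x = x[m]
    block = int(round(0.4 * track.fs))
    if len(x) < block:
        raise InputError("track shorter than one 400 ms gating block")
    for b, a in _k_weighting(track.fs):
        x = sps.lfilter(b, a, x)
    hop = block // 4
    n_blocks = 1 + (len(x) - block) // hop
    idx = np.arange(block)
    power = np.array([
        np.mean(x[i * hop: i * hop + block] ** 2) for i in range(n_blocks)])
    with np.errstate(divide="ignore"):
        lk = -0.691 + 10.0 * np.log10(power)
    keep = lk > -70.0
    if not keep.any():
        return float("nan")
    rel_gate = (-0.691 + 10 * np.log10(power[keep].mean())) - 10.0
    keep &= lk > rel_gate
    if not keep.any():
        return float("nan")
    return float(-0.691 + 10 * np.log10(power[keep].mean()))


# ---------------------------------------------------------------------------
# pitch
# ---------------------------------------------------------------------------


@dataclass
class PitchStats:
    median_hz: float
    iqr_hz: float
    per_segment_hz: list[float]
    defined: bool


def pitch_series(track: AudioTrack, segments: SpeechSegments,
                 f_lo: float = 50.0, f_hi: float = 400.0,
                 voicing_threshold: float = 0.5) -> PitchStats:
    """Per-segment fundamental frequency by normalized autocorrelation.

    A segment counts as voiced when its best autocorrelation peak within
    the lag range [fs/f_hi, fs/f_lo] exceeds ``voicing_threshold`` after
    normalization; unvoiced-only input yields ``defined=False``.
    """
    if len(segments) == 0:
        raise InputError("no speech segments for pitch analysis")
    fs = track.fs
    lag_min = int(fs / f_hi)
    lag_max = int(fs / f_lo)
    f0s: list[float] = []
    for s, e in segments.segments:
        seg = track.samples[int(s * fs): int(e * fs)]
        seg = seg - seg.mean()
        if len(seg) < 2 * lag_max or not np.any(seg):
            continue
        ac = sps.correlate(seg, seg, mode="full")[len(seg) - 1:]
        if ac[0] <= 0:
            continue
        ac = ac / ac[0]
        window = ac[lag_min: lag_max + 1]
        k = int(np.argmax(window)) + lag_min
        if ac[k] < voicing_threshold:
            continue
        # parabolic lag refinement
        if 0 < k < len(ac) - 1:
            denom = ac[k - 1] - 2 * ac[k] + ac[k + 1]
            if abs(denom) > 1e-12:
                k = k + float(np.clip(0.5 * (ac[k - 1] - ac[k + 1]) / denom,
                                      -0.5, 0.5))
        f0s.append(fs / k)
    if not f0s:
        return PitchStats(float("nan"), float("nan"), [], defined=False)
    q1, med, q3 = np.percentile(f0s, [25, 50, 75])
    return PitchStats(float(med), float(q3 - q1), f0s, defined=True)


# ---------------------------------------------------------------------------
# spectral / nonlinear energies
# ---------------------------------------------------------------------------

def band_energy(series: np.ndarray, fs_series: float,
                f_lo: float = 5.0, f_hi: float = 25.0) -> float:
    """L2 norm of the Fourier coefficients with f_lo <= f <= f_hi.

    Intended for the ~1000 Hz magnitude series, whose low-frequency
    content tracks the breathing-rate modulation of speech; the band
    bounds default to the 5-25 Hz breathing window. Linear in the input
    amplitude.
    """
    series = np.asarray(series, dtype=float)
    if fs_series / 2.0 <= f_hi:
        raise ParameterError(
            f"Nyquist {fs_series / 2:.1f} Hz must exceed f_hi={f_hi} Hz")
    spec = np.fft.rfft(series)
    freqs = np.fft.rfftfreq(len(series), d=1.0 / fs_series)
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    return float(np.sqrt(np.sum(np.abs(spec[sel]) ** 2)))


def teager_kaiser(x: np.ndarray,
                  segments: SpeechSegments | None = None,
                  fs: float | None = None
                  ) -> tuple[float, np.ndarray]:
    """Teager-Kaiser operator psi(n) = x(n)^2 - x(n-1)x(n+1).

    Returns (mean over speech samples, full psi series). For a sinusoid
    A*sin(omega*n) the operator is the constant A^2 sin^2(omega).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ParameterError("Teager-Kaiser needs >= 3 samples")
    psi = np.empty(len(x))
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0], psi[-1] = psi[1], psi[-2]
    if segments is not None:
        if fs is None:
            raise ParameterError("fs required when segments are given")
        m = segments.sample_mask(len(x), fs)
        mean = float(psi[m].mean()) if m.any() else float("nan")
    else:
        mean = float(psi.mean())
    return mean, psi


def spectral_entropy(track: AudioTrack, frame_s: float = 0.05,
                     hop_s: float | None = None,
                     peak_prominence: float = 0.1
                     ) -> tuple[np.ndarray, float, int]:
    """Framewise normalized Shannon entropy of the power spectrum.

    Each frame's power spectrum is normalized to a probability
    distribution; its Shannon entropy divided by log(#bins) lies in
    [0, 1] — near 0 for a pure tone, near 1 for white noise. Silent
    frames are NaN and excluded from the mean. Peaks of the entropy
    series ("entropy spikes" between words) are counted with the given
    prominence. Returns (series, mean, n_peaks).
    """
    n_frame = int(round(frame_s * track.fs))
    if n_frame < 256:
        raise ParameterError("entropy frame must be >= 256 samples")
    hop = int(round((hop_s if hop_s is not None else frame_s / 2) * track.fs))
    x = track.samples
    n_frames = max(0, 1 + (len(x) - n_frame) // hop)
    if n_frames == 0:
        raise ParameterError("track shorter than one entropy frame")
    ent = np.full(n_frames, np.nan)
    nbins = n_frame // 2 + 1
    for i in range(n_frames):
        fr = x[i * hop: i * hop + n_frame]
        p = np.abs(np.fft.rfft(fr)) ** 2
        tot = p.sum()
        if tot <= 0:
            continue
        p = p / tot
        nz = p[p > 0]
        ent[i] = float(-(nz * np.log(nz)).sum() / math.log(nbins))
    valid = ent[np.isfinite(ent)]
    mean = float(valid.mean()) if len(valid) else float("nan")
    series_for_peaks = np.nan_to_num(ent, nan=0.0)
    peaks, _ = sps.find_peaks(series_for_peaks, prominence=peak_prominence)
    return ent, mean, int(len(peaks))


def single_breath_features(track: AudioTrack, segments: SpeechSegments
                           ) -> tuple[float, float, float]:
    """(duration, energy integral, voiced fraction) of a single-breath count.

    Duration runs from the first segment's start to the last segment's
    end; the energy integral is sum(x^2)*dt over speech samples — the
    uncalibrated proxy for exhaled airflow volume.
    """
    if len(segments) == 0:
        raise InputError("no speech segments: single-breath features "
                         "undefined")
    sb_duration = segments.segments[-1][1] - segments.segments[0][0]
    m = segments.sample_mask(len(track.samples), track.fs)
    energy = float(np.sum(track.samples[m] ** 2) / track.fs)
    return float(sb_duration), energy, segments.voiced_fraction


# ---------------------------------------------------------------------------
# convenience bundle
# ---------------------------------------------------------------------------

def compute_voice_features(track: AudioTrack,
                           counting: bool = False,
                           noise_k: float = 3.0) -> VoiceFeatureSet:
    """Full feature suite for one voice exercise.

    ``counting=True`` applies the keep-the-50-longest segment rule before
    feature extraction.
    """
    env = envelope(track)
    segs = detect_speech_segments(env, noise_k=noise_k)
    if counting:
        segs = count50_segments(segs)
    if len(segs) == 0:
        return VoiceFeatureSet(
            loudness_lufs=float("nan"), pitch_median_hz=float("nan"),
            pitch_iqr_hz=float("nan"), pitch_defined=False,
            band_energy=0.0, tke_mean=float("nan"),
            entropy_mean=float("nan"), entropy_peaks=0,
            sb_duration_s=0.0, sb_energy_integral=0.0,
            voiced_fraction=0.0, n_segments=0, features_defined=False)
    mag, fs_m = magnitude_series(track)
    loud = integrated_loudness(track, segs)
    pitch = pitch_series(track, segs)
    be = band_energy(mag, fs_m)
    tke_mean, _ = teager_kaiser(track.samples, segs, track.fs)
    _, ent_mean, ent_peaks = spectral_entropy(track)
    sb_dur, sb_energy, vf = single_breath_features(track, segs)
    return VoiceFeatureSet(
        loudness_lufs=loud, pitch_median_hz=pitch.median_hz,
        pitch_iqr_hz=pitch.iqr_hz, pitch_defined=pitch.defined,
        band_energy=be, tke_mean=tke_mean, entropy_mean=ent_mean,
        entropy_peaks=ent_peaks, sb_duration_s=sb_dur,
        sb_energy_integral=sb_energy, voiced_fraction=vf,
        n_segments=len(segs))
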