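"""Envelope, speech segmentation, and the voice-feature suite."""

import numpy as np
import pytest

from mgcekit.errors import InputError, ParameterError
from mgcekit.synth import AudioScenario, gen_counting_audio
from mgcekit.voice import (AudioTrack, band_energy, compute_voice_features,
                           count50_segments, detect_speech_segments,
                           envelope, integrated_loudness, magnitude_series,
                           pitch_series, read_wav, single_breath_features,
                           SpeechSegments, spectral_entropy, teager_kaiser,
                           write_wav)


def _sine(f0=220.0, amp=0.3, dur=5.0, fs=16000):
    t = np.arange(0, dur, 1 / fs)
    return AudioTrack(amp * np.sin(2 * np.pi * f0 * t), fs)


class TestEnvelope:
    def test_rate_law(self):
        """1000 Hz magnitude series, block 60 -> 16.67 Hz, rounds to 17."""
        env = envelope(_sine(dur=3.0))
        assert env.fs_env == pytest.approx(1000.0 / 60.0)
        assert round(env.fs_env) == 17

    def test_constant_magnitude_preserved(self):
        tr = AudioTrack(np.full(16000 * 2, 0.25), 16000)
        env = envelope(tr)
        np.testing.assert_allclose(env.values, 0.25, rtol=1e-9)

    def test_block_count_arithmetic(self):
        """60 s of audio -> 60000 magnitude samples -> 1000 envelope pts."""
        tr = _sine(dur=60.0)
        mag, fs_m = magnitude_series(tr)
        assert len(mag) == 60000
        env = envelope(tr)
        assert len(env.values) == 1000

    def test_too_short_track(self):
        with pytest.raises(ParameterError):
            envelope(_sine(dur=0.5))


class TestSpeechSegments:
    def test_silence_has_no_segments(self):
        tr = AudioTrack(np.zeros(16000 * 3), 16000)
        segs = detect_speech_segments(envelope(tr))
        assert len(segs) == 0
        assert segs.voiced_fraction == 0.0

    def test_continuous_tone_single_segment(self):
        segs = detect_speech_segments(envelope(_sine(dur=4.0)))
        assert len(segs) == 1
        s, e = segs.segments[0]
        assert s < 0.2 and e > 3.6

    def test_burst_boundaries_within_one_envelope_sample(self):
        sc = AudioScenario(n_bursts=10, snr_db=20.0, seed=5)
        track, truth = gen_counting_audio(sc)
        env = envelope(track)
        segs = detect_speech_segments(env)
        assert len(segs) == 10
        tol = 1.0 / env.fs_env
        for (s, e), (ts, te) in zip(segs.segments, truth):
            assert abs(s - ts) <= tol + 1e-9
            assert abs(e - te) <= tol + 1e-9

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ParameterError):
            SpeechSegments([(0.0, 2.0), (1.0, 3.0)], 5.0)


class TestCount50:
    def test_fifty_bursts_all_kept(self):
        track, truth = gen_counting_audio(AudioScenario(n_bursts=50, seed=3))
        segs = count50_segments(detect_speech_segments(envelope(track)))
        assert len(segs) == 50

    def test_fewer_bursts_all_kept(self):
        track, _ = gen_counting_audio(AudioScenario(n_bursts=47, seed=3))
        segs = count50_segments(detect_speech_segments(envelope(track)))
        assert len(segs) == 47

    def test_longest_fifty_kept(self):
        """55 segments of known durations: exactly the 50 longest survive."""
        rng = np.random.default_rng(9)
        durations = rng.uniform(0.2, 1.0, 55)
        starts = np.cumsum(durations + 0.5) - durations - 0.5
        segs = SpeechSegments(
            [(s, s + d) for s, d in zip(starts, durations)],
            float(starts[-1] + durations[-1] + 1))
        kept = count50_segments(segs)
        assert len(kept) == 50
        dropped = sorted(durations)[:5]
        kept_durs = [e - s for s, e in kept.segments]
        assert min(kept_durs) > max(dropped) - 1e-12
        assert kept.segments == sorted(kept.segments)


class TestLoudness:
    def test_reference_sine_level(self):
        """997 Hz sine, amplitude 0.1, 48 kHz -> -23.0 LUFS."""
        t = np.arange(0, 10, 1 / 48000)
        tr = AudioTrack(0.1 * np.sin(2 * np.pi * 997 * t), 48000)
        assert integrated_loudness(tr) == pytest.approx(-23.0, abs=0.2)

    def test_gain_law_six_db_per_doubling(self):
        t = np.arange(0, 5, 1 / 48000)
        x = 0.05 * np.sin(2 * np.pi * 997 * t)
        l1 = integrated_loudness(AudioTrack(x, 48000))
        l2 = integrated_loudness(AudioTrack(2 * x, 48000))
        assert l2 - l1 == pytest.approx(6.02, abs=0.05)

    def test_twenty_db_gain(self):
        t = np.arange(0, 5, 1 / 48000)
        x = 0.01 * np.sin(2 * np.pi * 997 * t)
        l1 = integrated_loudness(AudioTrack(x, 48000))
        l2 = integrated_loudness(AudioTrack(10 * x, 48000))
        assert l2 - l1 == pytest.approx(20.0, abs=0.1)

    def test_silence_is_undefined(self):
        tr = AudioTrack(np.zeros(48000 * 2), 48000)
        assert np.isnan(integrated_loudness(tr))


class TestPitch:
    @pytest.mark.parametrize("f0", [110.0, 220.0])
    def test_sine_bursts_recovered(self, f0):
        track, _ = gen_counting_audio(
            AudioScenario(n_bursts=8, f0_hz=f0, snr_db=30.0, seed=2))
        segs = detect_speech_segments(envelope(track))
        stats = pitch_series(track, segs)
        assert stats.defined
        assert stats.median_hz == pytest.approx(f0, abs=1.0)

    def test_white_noise_undefined(self):
        rng = np.random.default_rng(4)
        tr = AudioTrack(0.3 * rng.standard_normal(16000 * 4), 16000)
        segs = detect_speech_segments(envelope(tr))
        if len(segs) == 0:
            segs = SpeechSegments([(0.5, 3.5)], tr.duration)
        stats = pitch_series(tr, segs)
        assert not stats.defined

    def test_no_segments_is_input_error(self):
        with pytest.raises(InputError):
            pitch_series(_sine(), SpeechSegments([], 5.0))


class TestBandEnergy:
    def test_ten_hz_line_dominates_band(self):
        """Magnitude series 1 + 0.5 sin(2*pi*10 t): all non-DC energy sits
        in the 5-25 Hz band (Parseval)."""
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        m = 1.0 + 0.5 * np.sin(2 * np.pi * 10 * t)
        be = band_energy(m, fs)
        spec = np.abs(np.fft.rfft(m))
        total_no_dc = np.sqrt(np.sum(spec[1:] ** 2))
        assert be / total_no_dc == pytest.approx(1.0, abs=1e-6)

    def test_forty_hz_component_outside_band(self):
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        m = 0.5 * np.sin(2 * np.pi * 40 * t)
        spec_total = np.sqrt(np.sum(np.abs(np.fft.rfft(m))[1:] ** 2))
        assert band_energy(m, fs) < 1e-3 * spec_total

    def test_linearity(self):
        rng = np.random.default_rng(3)
        m = rng.random(5000)
        assert band_energy(2 * m, 1000.0) == pytest.approx(
            2 * band_energy(m, 1000.0))

    def test_nyquist_guard(self):
        with pytest.raises(ParameterError):
            band_energy(np.ones(100), 40.0)


class TestTeagerKaiser:
    def test_constant_is_zero(self):
        mean, psi = teager_kaiser(np.full(100, 3.3))
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp_is_one(self):
        mean, psi = teager_kaiser(np.arange(100, dtype=float))
        np.testing.assert_allclose(psi[1:-1], 1.0)

    def test_sinusoid_closed_form(self):
        """psi(A sin(omega n)) = A^2 sin^2(omega) to 1e-6 relative."""
        A, omega = 0.7, 0.3
        n = np.arange(2000)
        mean, psi = teager_kaiser(A * np.sin(omega * n))
        expected = A ** 2 * np.sin(omega) ** 2
        np.testing.assert_allclose(psi[1:-1], expected, rtol=1e-6)


class TestSpectralEntropy:
    def test_bin_centered_tone_near_zero(self):
        fs = 16000
        n_frame = int(0.064 * fs)  # 1024 samples
        f0 = 10 * fs / n_frame     # exactly bin 10
        t = np.arange(0, 2, 1 / fs)
        tr = AudioTrack(0.5 * np.sin(2 * np.pi * f0 * t), fs)
        ent, mean, _ = spectral_entropy(tr, frame_s=0.064)
        assert mean < 0.05

    def test_white_noise_near_one(self):
        rng = np.random.default_rng(6)
        tr = AudioTrack(0.3 * rng.standard_normal(16000 * 2), 16000)
        _, mean, _ = spectral_entropy(tr)
        assert mean >= 0.9

    def test_bounds_and_monotone_flattening(self):
        """tone < tone+noise < noise in entropy, all within [0, 1]."""
        rng = np.random.default_rng(12)
        fs = 16000
        t = np.arange(0, 2, 1 / fs)
        tone = 0.5 * np.sin(2 * np.pi * 400 * t)
        noise = 0.5 * rng.standard_normal(len(t))
        means = []
        for x in (tone, tone + 0.2 * noise, noise):
            ent, m, _ = spectral_entropy(AudioTrack(x, fs))
            valid = ent[np.isfinite(ent)]
            assert np.all((valid >= 0) & (valid <= 1))
            means.append(m)
        assert means[0] < means[1] < means[2]

    def test_two_equal_bins_closed_form(self):
        """Two equal spectral lines among N bins: H = log 2 / log N."""
        fs = 16000
        n_frame = 1024
        f1 = 8 * fs / n_frame
        f2 = 100 * fs / n_frame
        t = np.arange(0, 2, 1 / fs)
        x = 0.4 * np.sin(2 * np.pi * f1 * t) + 0.4 * np.sin(2 * np.pi * f2 * t)
        ent, mean, _ = spectral_entropy(AudioTrack(x, fs), frame_s=0.064)
        expected = np.log(2) / np.log(n_frame // 2 + 1)
        assert mean == pytest.approx(expected, abs=0.01)

    def test_short_frame_rejected(self):
        with pytest.raises(ParameterError):
            spectral_entropy(_sine(fs=8000), frame_s=0.01)


class TestSingleBreath:
    def test_fourteen_bursts_energy_integral(self):
        """14 bursts (0.5 s, amplitude A): energy integral 14*0.5*A^2/2."""
        A = 0.3
        ramp = 0.02
        sc = AudioScenario(n_bursts=14, amplitude=A, snr_db=np.inf,
                           burst_s=0.5, pause_s=0.2, ramp_s=ramp, seed=1)
        track, truth = gen_counting_audio(sc)
        segs = SpeechSegments(truth, track.duration)
        dur, energy, vf = single_breath_features(track, segs)
        span = truth[-1][1] - truth[0][0]
        assert dur == pytest.approx(span, abs=1e-6)
        # raised-cosine on/offsets: integral of win^2 = T - 2r(1 - 3/8)
        per_burst = (0.5 - 1.25 * ramp) * A ** 2 / 2
        assert energy == pytest.approx(14 * per_burst, rel=0.02)

    def test_single_burst_duration(self):
        sc = AudioScenario(n_bursts=1, burst_s=1.0, snr_db=30.0, seed=7)
        track, _ = gen_counting_audio(sc)
        segs = detect_speech_segments(envelope(track))
        dur, _, _ = single_breath_features(track, segs)
        assert dur == pytest.approx(1.0, abs=0.1)

    def test_silence_undefined(self):
        with pytest.raises(InputError):
            single_breath_features(AudioTrack(np.zeros(16000), 16000),
                                   SpeechSegments([], 1.0))


class TestWavIO:
    def test_round_trip(self, tmp_path):
        tr = _sine(dur=1.0)
        path = tmp_path / "t.wav"
        write_wav(tr, path)
        back = read_wav(path)
        assert back.fs == tr.fs
        np.testing.assert_allclose(back.samples, tr.samples, atol=1e-3)


class TestFeatureBundle:
    def test_counting_bundle(self):
        track, _ = gen_counting_audio(AudioScenario(n_bursts=20, seed=8))
        feats = compute_voice_features(track, counting=True)
        assert feats.features_defined
        assert feats.n_segments == 20
        assert feats.pitch_defined
        assert 0 < feats.voiced_fraction < 1

    def test_silence_bundle_flagged(self):
        feats = compute_voice_features(
            AudioTrack(np.zeros(16000 * 3), 16000))
        assert not feats.features_defined
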