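"""Ptosis decay fitting and ocular-alignment metrics."""

import numpy as np
import pytest

from mgcekit.errors import (FitError, GeometryError, InsufficientDataError)
from mgcekit.eye import EyeGeometry
from mgcekit.ocular import (alignment_series, alignment_summary,
                            fit_linear_decay, fit_relaxation, ptosis_series)
from mgcekit.synth import gen_ptosis_geometry


def _geom(d_lid_pupil=6.0, pupil=(20.0, 10.0), quality="ok"):
    cols = np.arange(14.0, 27.0)
    yu = pupil[1] - d_lid_pupil
    return EyeGeometry(
        pupil_center=pupil, iris_x_left=14.0, iris_x_right=26.0,
        iris_bottom_y=16.0, columns=cols,
        upper_lid=np.full(len(cols), yu),
        lower_lid=np.full(len(cols), 16.0), quality=quality)


class TestPtosisSeries:
    def test_constant_geometry_gives_constant_series(self):
        times = np.arange(0, 60, 2.0)
        s = ptosis_series([_geom()] * len(times), times)
        assert np.allclose(s.d_lid_pupil[s.mask], 6.0)
        assert s.mask.all()

    def test_linear_descent_reproduced(self):
        times = np.arange(0, 60, 2.0)
        geoms = [_geom(d_lid_pupil=6.0 - 0.05 * t) for t in times]
        s = ptosis_series(geoms, times)
        np.testing.assert_allclose(s.d_lid_pupil, 6.0 - 0.05 * times,
                                   atol=1e-9)

    def test_all_masked_is_insufficient(self):
        times = np.arange(0, 60, 2.0)
        geoms = [_geom(quality="closed") for _ in times]
        with pytest.raises(InsufficientDataError):
            ptosis_series(geoms, times)

    def test_normalization_starts_at_one(self):
        times = np.arange(0, 60, 2.0)
        geoms = [_geom(d_lid_pupil=8.0) for _ in times]
        s = ptosis_series(geoms, times, normalize=True)
        assert s.d_lid_pupil[0] == pytest.approx(1.0)


class TestFitLinearDecay:
    def test_exact_fifteen_percent_decay(self):
        """d(t) = 10 - 0.025 t on [0, 60]: slope -0.025, decay 15%."""
        times = np.arange(0, 60.5, 0.5)
        geoms = [_geom(d_lid_pupil=10 - 0.025 * t, pupil=(20.0, 12.0))
                 for t in times]
        fit = fit_linear_decay(ptosis_series(geoms, times))
        assert fit.slope == pytest.approx(-0.025, rel=1e-6)
        assert fit.percent_decay == pytest.approx(15.0, rel=1e-6)
        assert fit.significant

    def test_constant_series_not_significant(self):
        times = np.arange(0, 60, 1.0)
        rng = np.random.default_rng(0)
        # tiny seeded jitter so the slope test is well defined
        geoms = [_geom(d_lid_pupil=6.0 + 1e-6 * rng.standard_normal())
                 for _ in times]
        fit = fit_linear_decay(ptosis_series(geoms, times))
        assert abs(fit.slope) < 1e-6
        assert fit.percent_decay == pytest.approx(0.0, abs=0.01)

    def test_noisy_decay_recovered_within_two_points(self):
        """OLS recovers a 15% injected decay under sigma = 0.2 px noise."""
        rng = np.random.default_rng(123)
        times = np.arange(0, 60, 0.1)
        d = 10 - 0.025 * times + rng.normal(0, 0.2, len(times))
        geoms = [_geom(d_lid_pupil=di, pupil=(20.0, 12.0)) for di in d]
        fit = fit_linear_decay(ptosis_series(geoms, times))
        assert fit.percent_decay == pytest.approx(15.0, abs=2.0)

    def test_parameter_recovery_across_decay_fractions(self):
        """Injected decays of 5-20% with 2% noise: estimate within +/-2
        percentage points in >= 95% of replicates."""
        hits = total = 0
        for f in (0.05, 0.10, 0.15, 0.20):
            for rep in range(25):
                geoms, times, truth = gen_ptosis_geometry(
                    decay_fraction=f, noise_sigma_frac=0.02,
                    seed=1000 + rep)
                fit = fit_linear_decay(ptosis_series(geoms, times))
                hits += abs(fit.percent_decay - truth["percent_decay"]) <= 2
                total += 1
        assert hits / total >= 0.95

    def test_scale_invariance_of_percent_decay(self):
        """Scaling all distances by s > 0 leaves decay and p-value alone."""
        rng = np.random.default_rng(5)
        times = np.arange(0, 60, 0.5)
        d = 8 - 0.02 * times + rng.normal(0, 0.1, len(times))
        fits = []
        for s in (1.0, 3.7):
            geoms = [_geom(d_lid_pupil=s * di, pupil=(20.0, 12.0))
                     for di in d]
            fits.append(fit_linear_decay(ptosis_series(geoms, times)))
        assert fits[0].percent_decay == pytest.approx(fits[1].percent_decay)
        assert fits[0].p_value == pytest.approx(fits[1].p_value)

    def test_relaxation_fit_recovers_tau(self):
        times = np.arange(0, 60, 0.25)
        d = 4.0 + 3.0 * np.exp(-times / 8.0)
        geoms = [_geom(d_lid_pupil=di, pupil=(20.0, 12.0)) for di in d]
        fit = fit_relaxation(ptosis_series(geoms, times))
        assert fit.tau_s == pytest.approx(8.0, rel=0.05)


class TestAlignment:
    def test_symmetric_eyes_zero_misalignment(self):
        times = np.arange(0, 12, 0.5)
        g = _geom()
        # identical geometry in each eye's own mirrored frame: use the
        # same border convention for both
        s = alignment_series([g] * len(times), [g] * len(times), times,
                             corners_left=(10.0, 50.0),
                             corners_right=(10.0, 50.0),
                             inner_is_left_border=(True, True))
        assert np.allclose(s.b_left, s.b_right)
        assert np.allclose(s.misalignment, 0.0)

    def test_midway_border_is_half(self):
        times = np.arange(0, 12, 0.5)
        g = _geom()  # iris_x_left = 14
        s = alignment_series([g] * len(times), [g] * len(times), times,
                             corners_left=(4.0, 24.0),
                             corners_right=(4.0, 24.0))
        assert np.allclose(s.b_left, 0.5)

    def test_two_px_shift_in_forty_px_span(self):
        times = np.arange(0, 12, 0.5)
        n = len(times)
        g0 = _geom()
        shifted = _geom()
        shifted.iris_x_left = g0.iris_x_left + 2.0
        half = n // 2
        s = alignment_series([g0] * half + [shifted] * (n - half),
                             [g0] * n, times,
                             corners_left=(0.0, 40.0),
                             corners_right=(0.0, 40.0))
        db = s.b_left[-1] - s.b_left[0]
        assert db == pytest.approx(2.0 / 40.0)
        assert s.misalignment[-1] == pytest.approx(0.05)

    def test_translation_invariance(self):
        times = np.arange(0, 12, 0.5)
        g0 = _geom()
        g1 = _geom()
        g1.iris_x_left = g0.iris_x_left + 7.0
        g1.iris_x_right = g0.iris_x_right + 7.0
        s0 = alignment_series([g0] * len(times), [g0] * len(times), times,
                              (0.0, 40.0), (0.0, 40.0))
        s1 = alignment_series([g1] * len(times), [g1] * len(times), times,
                              (7.0, 47.0), (7.0, 47.0))
        np.testing.assert_allclose(s0.b_left, s1.b_left)

    def test_narrow_corner_span_is_geometry_error(self):
        times = np.arange(0, 12, 0.5)
        g = _geom()
        with pytest.raises(GeometryError):
            alignment_series([g] * len(times), [g] * len(times), times,
                             (10.0, 12.0), (10.0, 50.0))


class TestAlignmentSummary:
    def _series(self, misalignment, times):
        from mgcekit.ocular import AlignmentSeries
        return AlignmentSeries(t=times, b_left=misalignment,
                               b_right=np.zeros_like(times),
                               misalignment=misalignment, baseline=0.0)

    def test_zero_misalignment_is_steady(self):
        times = np.arange(0, 60, 0.5)
        s = self._series(np.zeros_like(times), times)
        out = alignment_summary(s)
        assert out.steady and out.drift_slope == pytest.approx(0.0)

    def test_ramp_slope(self):
        times = np.arange(0, 60, 0.5)
        s = self._series(times / 600.0, times)  # 0 -> 0.1 over 60 s
        out = alignment_summary(s)
        assert out.drift_slope == pytest.approx(1 / 600, rel=1e-6)

    def test_single_spike_breaks_steadiness(self):
        times = np.arange(0, 60, 0.5)
        m = np.zeros_like(times)
        m[60] = 0.3
        out = alignment_summary(self._series(m, times))
        assert not out.steady
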