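"""Waveform representation, smoothing, normalisation and I/O."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from echobc import (
    InvalidParameterError,
    ParseError,
    Phase,
    Site,
    VelocityWaveform,
    WaveformParams,
    gen_waveform,
    normalize_period,
    peak_of,
    read_waveform,
    resample_uniform,
    smooth_waveform,
    write_waveform,
)


def make_wave(t, v, site=Site.ASCENDING_AORTA, **kw):
    return VelocityWaveform(site=site, t=np.asarray(t), v=np.asarray(v), **kw)


class TestInvariants:
    def test_rejects_non_increasing_times(self):
        with pytest.raises(InvalidParameterError):
            make_wave([0.0, 0.2, 0.2], [1, 1, 1])

    def test_rejects_negative_velocity(self):
        with pytest.raises(InvalidParameterError):
            make_wave([0.0, 0.1, 0.2], [1, -0.1, 1])

    def test_rejects_too_few_samples(self):
        with pytest.raises(InvalidParameterError):
            make_wave([0.0, 0.1], [1, 1])


class TestSmoothing:
    def test_window_one_is_identity(self, clean_pulse):
        out = smooth_waveform(clean_pulse, window=1)
        np.testing.assert_array_equal(out.v, clean_pulse.v)

    def test_reproduces_parabola_exactly(self):
        t = np.linspace(0.0, 0.5, 21)
        v = 3.0 - 8.0 * (t - 0.25) ** 2  # positive parabola
        w = make_wave(t, v)
        out = smooth_waveform(w, window=5)
        np.testing.assert_allclose(out.v, v, atol=1e-12)

    def test_reduces_noise_residual(self, noisy_pulse_pair):
        clean, noisy = noisy_pulse_pair
        smoothed = smooth_waveform(noisy, window=7)
        raw_sd = np.std(noisy.v - clean.v)
        smooth_sd = np.std(smoothed.v - clean.v)
        assert smooth_sd < raw_sd

    @pytest.mark.parametrize("window", [0, 2, 4, 6, 999])
    def test_invalid_window_rejected(self, clean_pulse, window):
        with pytest.raises(InvalidParameterError):
            smooth_waveform(clean_pulse, window=window)

    @given(
        peak=st.floats(0.5, 4.0),
        tail=st.floats(0.0, 0.4),
        seed=st.integers(0, 50),
    )
    def test_never_increases_max_on_unimodal_envelope(self, peak, tail, seed):
        w = gen_waveform(
            WaveformParams(
                peak_velocity=peak, diastolic_tail_fraction=tail, n_samples=80
            )
        )
        out = smooth_waveform(w, window=7)
        assert np.max(out.v) <= np.max(w.v) + 1e-12

    def test_time_grid_preserved(self, clean_pulse):
        out = smooth_waveform(clean_pulse, window=7)
        np.testing.assert_array_equal(out.t, clean_pulse.t)


class TestNormalizePeriod:
    def test_identity_at_target(self, clean_pulse):
        assert clean_pulse.period == pytest.approx(0.5)
        out = normalize_period(clean_pulse, 0.5)
        np.testing.assert_allclose(out.t, clean_pulse.t, atol=1e-15)

    def test_linear_map_from_80_bpm(self):
        t = np.linspace(0.0, 0.75, 31)
        v = np.abs(np.sin(t * 4))
        w = make_wave(t, v)
        out = normalize_period(w)
        np.testing.assert_allclose(out.t, t * (2.0 / 3.0), atol=1e-15)
        assert np.max(out.v) == np.max(v)

    def test_95_bpm_pulse_becomes_120_bpm(self):
        w = gen_waveform(WaveformParams(peak_velocity=1.0, heart_rate_bpm=95.0))
        out = normalize_period(w)
        assert out.period == pytest.approx(0.5, abs=0)
        assert out.equivalent_heart_rate_bpm == pytest.approx(120.0)

    def test_idempotent_and_composes(self, clean_pulse):
        w = gen_waveform(WaveformParams(peak_velocity=1.0, heart_rate_bpm=77.0))
        once = normalize_period(w)
        twice = normalize_period(once)
        np.testing.assert_array_equal(once.t, twice.t)
        np.testing.assert_array_equal(once.v, twice.v)

    def test_peak_value_invariant_exactly(self):
        w = gen_waveform(
            WaveformParams(peak_velocity=2.4, heart_rate_bpm=101.0, noise_sd=0.03)
        )
        assert peak_of(normalize_period(w))[1] == peak_of(w)[1]

    def test_bad_target_rejected(self, clean_pulse):
        with pytest.raises(InvalidParameterError):
            normalize_period(clean_pulse, 0.0)


class TestPeakOf:
    def test_constant_waveform_ties_to_first_sample(self):
        w = make_wave([0.0, 0.25, 0.5], [1.0, 1.0, 1.0])
        assert peak_of(w) == (0.0, 1.0)

    def test_half_sine_peak_amplitude(self):
        t = np.linspace(0.0, 0.5, 201)
        w = make_wave(t, 3.49 * np.sin(np.pi * t / 0.5))
        assert peak_of(w)[1] == pytest.approx(3.49)

    def test_equal_peaks_take_earliest(self):
        w = make_wave([0.0, 0.1, 0.2, 0.3, 0.4], [0.0, 2.0, 1.0, 2.0, 0.0])
        assert peak_of(w)[0] == 0.1


class TestResample:
    def test_own_grid_identity(self, clean_pulse):
        out = resample_uniform(clean_pulse, clean_pulse.n_samples)
        np.testing.assert_allclose(out.v, clean_pulse.v, atol=1e-14)

    @pytest.mark.parametrize("n", [3, 17, 500])
    def test_linear_ramp_exact(self, n):
        t = np.linspace(0.0, 0.5, 11)
        w = make_wave(t, 2.0 * t)
        out = resample_uniform(w, n)
        np.testing.assert_allclose(out.v, 2.0 * out.t, atol=1e-14)

    def test_peak_within_slope_bound(self, clean_pulse):
        out = resample_uniform(clean_pulse, 1000)
        max_slope = np.max(np.abs(np.diff(clean_pulse.v) / np.diff(clean_pulse.t)))
        spacing = clean_pulse.period / 999
        assert peak_of(clean_pulse)[1] - peak_of(out)[1] <= max_slope * spacing

    def test_endpoints_preserved(self, clean_pulse):
        out = resample_uniform(clean_pulse, 37)
        assert out.t[0] == clean_pulse.t[0]
        assert out.t[-1] == clean_pulse.t[-1]
        assert out.v[0] == clean_pulse.v[0]
        assert out.v[-1] == clean_pulse.v[-1]

    def test_too_few_points_rejected(self, clean_pulse):
        with pytest.raises(InvalidParameterError):
            resample_uniform(clean_pulse, 2)


class TestIO:
    def test_round_trip_preserves_metadata_and_values(self, tmp_path):
        w = gen_waveform(
            WaveformParams(peak_velocity=1.11, heart_rate_bpm=104.0, noise_sd=0.02),
            site=Site.INNOMINATE,
            phase=Phase.PRE_REPAIR,
        )
        path = tmp_path / "innominate.txt"
        write_waveform(w, path)
        back = read_waveform(path)
        assert back.site is Site.INNOMINATE
        assert back.phase is Phase.PRE_REPAIR
        assert back.heart_rate_bpm == pytest.approx(104.0, rel=1e-5)
        np.testing.assert_allclose(back.v, w.v, rtol=1e-5, atol=1e-6)

    def test_comma_delimited_accepted(self):
        text = "# site: lcca\n0.0,0.1\n0.1,0.5\n0.2,0.2\n"
        w = read_waveform(io.StringIO(text))
        assert w.site is Site.LCCA
        assert w.n_samples == 3

    def test_missing_site_rejected(self):
        with pytest.raises(ParseError):
            read_waveform(io.StringIO("0.0 0.1\n0.1 0.5\n0.2 0.2\n"))

    def test_ragged_row_rejected_with_line_number(self):
        text = "# site: lcca\n0.0 0.1\n0.1 0.5 9 9\n"
        with pytest.raises(ParseError, match="line 3"):
            read_waveform(io.StringIO(text))
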