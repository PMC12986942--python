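import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandbench import (BandSpec, ExpBandpassParams, TimeSeries,
                       distance_to_band, edge_sharpness, exp_bandpass_filter,
                       exp_gain, gain_template, select_exponent)
from bandbench.errors import ConfigurationError, ResolutionError
from conftest import sinusoid

BAND = BandSpec(5.0, 10.0)


class TestDistanceToBand:
    @pytest.mark.parametrize("f,expected", [(7.0, 0.0), (4.0, 1.0), (12.0, 2.0),
                                            (5.0, 0.0), (10.0, 0.0)])
    def test_examples(self, f, expected):
        assert distance_to_band(f, BAND) == expected

    def test_vectorized(self):
        out = distance_to_band(np.array([4.0, 7.0, 12.0]), BAND)
        assert np.array_equal(out, [1.0, 0.0, 2.0])

    @given(st.floats(min_value=-100, max_value=100, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_total_and_consistent(self, f):
        d = distance_to_band(f, BAND)
        assert d >= 0.0
        assert (d == 0.0) == (BAND.f_lo <= f <= BAND.f_hi)


class TestExpGain:
    def test_in_band_gain_near_one(self, default_params):
        g = exp_gain(np.array([7.0]), BAND, default_params, 10.0, delta_f=1.0)
        assert abs(g[0] - math.exp(-0.05 ** 10)) < 1e-15
        assert abs(g[0] - 1.0) < 1e-12

    def test_one_bin_out_closed_form(self, default_params):
        # independent high-precision evaluation of the closed form
        expected = math.exp(-(1.0 + 0.05) ** 10)
        g = exp_gain(np.array([4.0]), BAND, default_params, 10.0, delta_f=1.0)
        assert g[0] == pytest.approx(expected, abs=1e-15)
        assert g[0] == pytest.approx(0.1961, abs=5e-4)

    def test_large_exponent_underflows_to_zero(self, default_params):
        # 1.05**500 > 1e10, so exp(-that) underflows cleanly
        g = exp_gain(np.array([4.0]), BAND, default_params, 500.0, delta_f=1.0)
        assert g[0] == 0.0

    def test_bounds_and_monotone_in_distance(self, default_params):
        freqs = np.linspace(0.0, 20.0, 501)
        g = exp_gain(freqs, BAND, default_params, 25.0, delta_f=0.05)
        assert np.all(g >= 0.0) and np.all(g <= 1.0)
        dist = distance_to_band(freqs, BAND)
        order = np.argsort(dist)
        assert np.all(np.diff(g[order]) <= 1e-15)

    @pytest.mark.parametrize("d_pair", [(10.0, 15.0), (15.0, 40.0), (40.0, 200.0)])
    def test_out_of_band_gain_non_increasing_in_d(self, default_params, d_pair):
        freqs = np.array([4.0, 3.0, 11.0, 12.5])  # all >= 1 bin out at df=1
        lo = exp_gain(freqs, BAND, default_params, d_pair[0], delta_f=1.0)
        hi = exp_gain(freqs, BAND, default_params, d_pair[1], delta_f=1.0)
        assert np.all(hi <= lo + 1e-15)

    def test_bins_mode_requires_delta_f(self, default_params):
        with pytest.raises(ConfigurationError):
            exp_gain(np.array([4.0]), BAND, default_params, 10.0)

    def test_hz_mode(self):
        params = ExpBandpassParams(dist_mode="hz")
        g = exp_gain(np.array([4.0]), BAND, params, 10.0)
        assert g == pytest.approx(math.exp(-(1.0 + 0.05) ** 10), abs=1e-15)


class TestEdgeSharpness:
    def test_derived_against_scalar_arithmetic(self, default_params):
        # oracle: closed-form evaluation at the four nearest bins
        fs, n, d = 40.0, 4000, 10.0
        df = fs / n
        k_lo = math.ceil(BAND.f_lo / df)
        k_hi = math.floor(BAND.f_hi / df)

        def gain_at(k):
            f = k * df
            u = distance_to_band(f, BAND) / df
            return math.exp(-((u + 0.05) ** d))

        expected = 0.5 * ((gain_at(k_lo) - gain_at(k_lo - 1))
                          + (gain_at(k_hi) - gain_at(k_hi + 1)))
        got = edge_sharpness(d, fs, n, BAND, default_params)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_brick_wall_limit_is_one(self, default_params):
        # on-bin edges: gains 1 in band and 0 one bin out for very large d
        s = edge_sharpness(2000.0, 40.0, 4000, BAND, default_params)
        assert s == pytest.approx(1.0, abs=1e-10)

    def test_flat_template_gives_zero(self):
        # c -> 0 pushes every gain to 1, so all four points coincide
        params = ExpBandpassParams(c=1e-12)
        s = edge_sharpness(10.0, 40.0, 4000, BAND, params)
        assert abs(s) < 1e-10

    def test_monotone_non_decreasing_in_d(self, default_params):
        ds = np.arange(10.0, 300.0, 5.0)
        svals = [edge_sharpness(d, 40.0, 4000, BAND, default_params) for d in ds]
        assert np.all(np.diff(svals) >= -1e-14)
        assert max(svals) <= 1.0 + 1e-12

    def test_coarse_grid_rejected(self, default_params):
        # df = 5 Hz leaves no bin inside [1, 2]
        with pytest.raises(ResolutionError):
            edge_sharpness(10.0, 40.0, 8, BandSpec(1.0, 2.0), default_params)


def _brute_force_scan(fs, n, band, params):
    s_prev = edge_sharpness(params.d0, fs, n, band, params)
    d = params.d0
    while True:
        d += params.delta_d
        s = edge_sharpness(d, fs, n, band, params)
        if abs(s - s_prev) < params.tol:
            return d
        s_prev = s


class TestSelectExponent:
    def test_contract(self, default_params):
        sel = select_exponent(40.0, 4000, BAND, default_params)
        assert sel.d >= default_params.d0
        assert sel.converged
        s = edge_sharpness(sel.d, 40.0, 4000, BAND, default_params)
        s_prev = edge_sharpness(sel.d - default_params.delta_d, 40.0, 4000,
                                BAND, default_params)
        assert abs(s - s_prev) < default_params.tol

    def test_matches_exhaustive_scan(self, default_params):
        sel = select_exponent(40.0, 4000, BAND, default_params)
        assert sel.d == _brute_force_scan(40.0, 4000, BAND, default_params)

    def test_matches_scan_on_eeg_grid(self, default_params):
        band = BandSpec(0.5, 50.0)
        sel = select_exponent(512.0, 31744, band, default_params)
        assert sel.d == _brute_force_scan(512.0, 31744, band, default_params)

    def test_fast_saturating_template_converges_no_later(self):
        fast = ExpBandpassParams(offset=0.5)
        slow = ExpBandpassParams(offset=0.05)
        d_fast = select_exponent(40.0, 4000, BAND, fast).d
        d_slow = select_exponent(40.0, 4000, BAND, slow).d
        assert d_fast == _brute_force_scan(40.0, 4000, BAND, fast)
        assert d_fast <= d_slow

    def test_cap_hit_warns_not_raises(self):
        params = ExpBandpassParams(tol=1e-300, d_max=40.0)
        with pytest.warns(RuntimeWarning):
            sel = select_exponent(40.0, 4000, BAND, params)
        assert not sel.converged
        assert sel.d <= 40.0


class TestGainTemplate:
    def test_grid_layout(self, default_params):
        tpl = gain_template(40.0, 4000, BAND, default_params)
        assert len(tpl.freqs) == 4000 // 2 + 1
        assert tpl.freqs[0] == 0.0
        assert tpl.freqs[-1] == pytest.approx(20.0)
        assert np.all(np.diff(tpl.freqs) > 0)
        assert np.all((tpl.gains >= 0) & (tpl.gains <= 1))

    def test_band_beyond_nyquist_rejected(self, default_params):
        with pytest.raises(ConfigurationError):
            gain_template(15.0, 1000, BAND, default_params)

    def test_export_round_trip(self, default_params, tmp_path):
        tpl = gain_template(40.0, 400, BAND, default_params)
        path = tmp_path / "template.csv"
        tpl.to_text(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert np.allclose(data[:, 0], tpl.freqs)
        assert np.allclose(data[:, 1], tpl.gains)


class TestFilter:
    def test_zero_in_zero_out(self, default_params):
        ts = TimeSeries(np.zeros(256), 40.0)
        out = exp_bandpass_filter(ts, BAND, default_params)
        assert np.array_equal(out.samples, np.zeros((256, 1)))

    def test_in_band_sinusoid_passes_unchanged(self):
        params = ExpBandpassParams(pad_mode="none")
        fs, n = 40.0, 400
        x = sinusoid(7.0, fs, n)  # integer number of periods
        out = exp_bandpass_filter(TimeSeries(x, fs), BAND, params).channel(0)
        assert np.max(np.abs(out - x)) < 1e-6
        c = np.correlate(out, x, "full")
        assert int(np.argmax(c)) - (n - 1) == 0

    def test_two_tone_separation_against_fft_oracle(self):
        # oracle: zero the out-of-band FFT coefficients directly
        params = ExpBandpassParams(pad_mode="none")
        fs, n = 40.0, 400
        x = sinusoid(7.0, fs, n) + sinusoid(15.0, fs, n)
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        spec[(freqs < BAND.f_lo) | (freqs > BAND.f_hi)] = 0.0
        expected = np.fft.irfft(spec, n=n)
        out = exp_bandpass_filter(TimeSeries(x, fs), BAND, params).channel(0)
        rms = np.sqrt(np.mean((out - expected) ** 2))
        assert rms < 1e-3
        ref = sinusoid(7.0, fs, n)
        assert np.sqrt(np.mean((out - ref) ** 2)) < 1e-3

    @pytest.mark.parametrize("n", [16, 33, 64])
    def test_matches_naive_dft_oracle(self, rng, n):
        fs = 32.0
        band = BandSpec(4.0, 9.0)
        params = ExpBandpassParams(pad_mode="none")
        x = rng.standard_normal(n)
        out = exp_bandpass_filter(TimeSeries(x, fs), band, params).channel(0)
        tpl = gain_template(fs, n, band, params)
        dft = np.exp(-2j * np.pi * np.outer(np.arange(n), np.arange(n)) / n)
        weights = np.array([tpl.gains[min(k, n - k)] for k in range(n)])
        oracle = np.real(np.conj(dft) @ (weights * (dft @ x)) / n)
        assert np.max(np.abs(out - oracle)) < 1e-10

    def test_linearity(self, rng):
        params = ExpBandpassParams(pad_mode="none")
        fs, n = 40.0, 256
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        a, b = 2.5, -1.25

        def run(v):
            return exp_bandpass_filter(TimeSeries(v, fs), BAND, params).channel(0)

        lhs = run(a * x + b * y)
        rhs = a * run(x) + b * run(y)
        assert np.max(np.abs(lhs - rhs)) < 1e-12

    def test_real_output(self, rng):
        out = exp_bandpass_filter(TimeSeries(rng.standard_normal(128), 40.0),
                                  BAND, ExpBandpassParams(pad_mode="none"))
        assert np.isrealobj(out.samples)

    def test_idempotent_on_band_interior(self):
        params = ExpBandpassParams(pad_mode="none")
        fs, n = 40.0, 400
        x = sinusoid(7.0, fs, n)
        once = exp_bandpass_filter(TimeSeries(x, fs), BAND, params)
        twice = exp_bandpass_filter(once, BAND, params)
        rel = (np.sqrt(np.mean((twice.samples - once.samples) ** 2))
               / np.sqrt(np.mean(once.samples ** 2)))
        assert rel < 1e-6

    def test_reflect_padding_preserves_shape(self, rng):
        x = rng.standard_normal((300, 2))
        ts = TimeSeries(x, 40.0)
        out = exp_bandpass_filter(ts, BAND, ExpBandpassParams())
        assert out.samples.shape == (300, 2)
        assert out.fs == 40.0

    def test_band_outside_nyquist_rejected(self, rng):
        ts = TimeSeries(rng.standard_normal(128), 15.0)
        with pytest.raises(ConfigurationError):
            exp_bandpass_filter(ts, BAND, ExpBandpassParams())
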