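"""Filter design, stability by pole radius, magnitude response, zero phase."""

import numpy as np
import pytest

from bandopt import (
    FIRFilter,
    IIRFilterTF,
    ValidationError,
    apply_zero_phase,
    design_butterworth_bandpass,
    design_chebyshev1_bandpass,
    design_fir_bandpass,
    magnitude_response,
    stability_report,
)

FS = 500.0


class TestFIRDesign:
    def test_unit_gain_at_band_midpoint(self):
        filt = design_fir_bandpass(213, 10.0, 33.0, FS)
        gain = magnitude_response(filt, [21.5])[0]
        assert 0.999 <= gain <= 1.001

    @pytest.mark.parametrize("order", [50, 213, 300])
    def test_coefficients_symmetric(self, order):
        filt = design_fir_bandpass(order, 10.0, 33.0, FS)
        np.testing.assert_allclose(filt.h, filt.h[::-1], atol=1e-12)

    def test_stopband_attenuation_at_dc_and_nyquist(self):
        filt = design_fir_bandpass(213, 10.0, 33.0, FS)
        gains = magnitude_response(filt, [0.0, FS / 2])
        assert np.all(gains < 0.01)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValidationError):
            design_fir_bandpass(100, 33.0, 10.0, FS)

    def test_asymmetric_coefficients_rejected(self):
        with pytest.raises(ValidationError):
            FIRFilter(h=np.array([1.0, 2.0, 3.0]), f_low=1, f_high=2, fs=FS)


class TestButterworthDesign:
    @pytest.mark.parametrize("order", [4, 5, 6])
    def test_cutoff_gain_is_minus_3db(self, order):
        filt = design_butterworth_bandpass(order, 11.0, 32.0, FS)
        gains = magnitude_response(filt, [11.0, 32.0])
        np.testing.assert_allclose(gains, 1 / np.sqrt(2), atol=1e-3)

    def test_cutoff_gain_order7_degrades_gracefully(self):
        # at order 7 the TF polynomial's round-off already shifts the
        # cutoff gain by ~2e-3; it must still be recognisably −3 dB
        filt = design_butterworth_bandpass(7, 11.0, 32.0, FS)
        gains = magnitude_response(filt, [11.0, 32.0])
        np.testing.assert_allclose(gains, 1 / np.sqrt(2), atol=1e-2)

    def test_order4_is_stable(self):
        rep = stability_report(design_butterworth_bandpass(4, 11.0, 32.0, FS))
        assert rep.stable
        assert rep.max_pole_magnitude < 1

    def test_order8_tf_polynomial_is_unstable(self):
        rep = stability_report(design_butterworth_bandpass(8, 11.0, 32.0, FS))
        assert not rep.stable
        assert rep.max_pole_magnitude >= 1

    def test_passband_flatter_inside_than_at_cutoffs(self):
        filt = design_butterworth_bandpass(4, 11.0, 32.0, FS)
        inner = magnitude_response(filt, np.linspace(14.0, 29.0, 200))
        cut = magnitude_response(filt, [11.0, 32.0])
        assert np.abs(inner - 1).max() < np.abs(cut - 1).min()

    def test_monotone_stopband_above_cutoff(self):
        filt = design_butterworth_bandpass(4, 11.0, 32.0, FS)
        gains = magnitude_response(filt, np.linspace(32.0, 125.0, 300))
        assert np.all(np.diff(gains) < 0)

    def test_coefficient_layout(self):
        filt = design_butterworth_bandpass(4, 11.0, 32.0, FS)
        assert filt.den[0] == 1.0
        assert filt.num.size == filt.den.size == 9


class TestChebyshevDesign:
    def test_cutoff_gain_equals_one_minus_delta(self):
        filt = design_chebyshev1_bandpass(4, 0.005, 12.5, 30.5, FS)
        gains = magnitude_response(filt, [12.5, 30.5])
        np.testing.assert_allclose(gains, 0.995, atol=1e-3)

    @pytest.mark.parametrize("order", [2, 3, 4, 5])
    def test_passband_ripple_confined(self, order):
        # gain oscillates in [1−δ, 1] across the passband; checked at the
        # orders where the TF polynomial is numerically faithful
        filt = design_chebyshev1_bandpass(order, 0.005, 12.5, 30.5, FS)
        gains = magnitude_response(filt, np.linspace(13.0, 30.0, 500))
        assert gains.max() <= 1 + 1e-6
        assert gains.min() >= 0.995 - 1e-6

    def test_order8_tf_polynomial_is_unstable(self):
        rep = stability_report(
            design_chebyshev1_bandpass(8, 0.005, 12.5, 30.5, FS))
        assert not rep.stable

    def test_invalid_ripple_rejected(self):
        for bad in (0.0, -0.1, 0.5):
            with pytest.raises(ValidationError):
                design_chebyshev1_bandpass(4, bad, 12.5, 30.5, FS)


class TestStabilityReport:
    def test_fir_always_stable_with_no_poles(self):
        rep = stability_report(design_fir_bandpass(300, 10.0, 33.0, FS))
        assert rep.stable
        assert rep.poles.size == 0

    def test_single_pole_closed_forms(self):
        stable = IIRFilterTF(num=np.array([1.0, 0.0, 0.0]),
                             den=np.array([1.0, -0.5, 0.0]),
                             design_order=1, family="butterworth",
                             f_low=1.0, f_high=2.0, fs=FS)
        rep = stability_report(stable)
        assert rep.stable
        assert rep.max_pole_magnitude == pytest.approx(0.5)

        unstable = IIRFilterTF(num=np.array([1.0, 0.0, 0.0]),
                               den=np.array([1.0, -2.0, 0.0]),
                               design_order=1, family="butterworth",
                               f_low=1.0, f_high=2.0, fs=FS)
        rep = stability_report(unstable)
        assert not rep.stable
        assert rep.max_pole_magnitude == pytest.approx(2.0)

    @pytest.mark.parametrize("order", [2, 3, 4, 5])
    def test_agrees_with_independent_root_finder(self, order):
        # sympy's arbitrary-precision nroots as the independent oracle
        import sympy

        filt = design_chebyshev1_bandpass(order, 0.005, 12.5, 30.5, FS)
        rep = stability_report(filt)
        z = sympy.symbols("z")
        poly = sum(sympy.Float(c, 30) * z ** (filt.den.size - 1 - i)
                   for i, c in enumerate(filt.den))
        roots = sympy.nroots(sympy.Poly(poly, z), n=30)
        oracle_max = max(abs(complex(r)) for r in roots)
        assert rep.max_pole_magnitude == pytest.approx(oracle_max, rel=1e-6)
        assert rep.stable == (oracle_max < 1)


class TestMagnitudeResponse:
    def test_identity_filter_has_unit_gain(self):
        # a pure unit delay has |H| = 1 everywhere
        filt = FIRFilter(h=np.array([0.0, 1.0, 0.0]),
                         f_low=1.0, f_high=2.0, fs=FS)
        gains = magnitude_response(filt, [0.0, 50.0, 125.0, 250.0])
        np.testing.assert_allclose(gains, 1.0, atol=1e-12)

    def test_moving_average_null_at_nyquist(self):
        filt = FIRFilter(h=np.array([0.5, 0.5]), f_low=1.0, f_high=2.0, fs=FS)
        assert magnitude_response(filt, [FS / 2])[0] == pytest.approx(0.0,
                                                                      abs=1e-12)

    def test_out_of_range_frequency_rejected(self):
        filt = design_fir_bandpass(50, 10.0, 33.0, FS)
        with pytest.raises(ValidationError):
            magnitude_response(filt, [300.0])


class TestZeroPhase:
    def test_zero_input_zero_output(self):
        filt = design_chebyshev1_bandpass(4, 0.005, 12.5, 30.5, FS)
        out = apply_zero_phase(np.zeros(5000), filt)
        np.testing.assert_array_equal(out, np.zeros(5000))

    def test_in_band_tone_has_no_lag(self):
        t = np.arange(10000) / FS
        x = np.sin(2 * np.pi * 20 * t)
        filt = design_chebyshev1_bandpass(4, 0.005, 12.5, 30.5, FS)
        y = apply_zero_phase(x, filt)
        lags = np.arange(-50, 51)
        xc = [np.dot(x[200:-200], np.roll(y, k)[200:-200]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_amplitude_ratio_is_squared_gain(self):
        t = np.arange(20000) / FS
        x = np.sin(2 * np.pi * 20 * t)
        filt = design_chebyshev1_bandpass(4, 0.005, 12.5, 30.5, FS)
        y = apply_zero_phase(x, filt)
        gain = magnitude_response(filt, [20.0])[0]
        mid = slice(2000, 18000)
        assert y[mid].std() / x[mid].std() == pytest.approx(gain ** 2,
                                                            rel=0.01)

    def test_unstable_filter_rejected(self):
        filt = design_butterworth_bandpass(8, 11.0, 32.0, FS)
        with pytest.raises(ValidationError, match="unstable"):
            apply_zero_phase(np.zeros(5000), filt)

    def test_too_short_signal_rejected(self):
        filt = design_fir_bandpass(300, 10.0, 33.0, FS)
        with pytest.raises(ValidationError, match="too short"):
            apply_zero_phase(np.zeros(100), filt)

    def test_output_length_equals_input_length(self, rng):
        filt = design_butterworth_bandpass(4, 11.0, 32.0, FS)
        x = rng.standard_normal(4321)
        assert apply_zero_phase(x, filt).size == 4321

    def test_fir_commutes_with_time_reversal(self, rng):
        x = rng.standard_normal(8000) * 1e-5
        filt = design_fir_bandpass(213, 10.0, 33.0, FS)
        y = apply_zero_phase(x, filt)
        z = apply_zero_phase(x[::-1], filt)[::-1]
        np.testing.assert_allclose(z, y, atol=1e-9 * np.abs(y).max())

    def test_iir_commutes_with_time_reversal_away_from_edges(self, rng):
        # IIR edge transients decay like max|pole|^n, so strict commutation
        # holds only beyond the edge-transient region
        x = rng.standard_normal(30000) * 1e-5
        filt = design_chebyshev1_bandpass(4, 0.005, 12.5, 30.5, FS)
        y = apply_zero_phase(x, filt)
        z = apply_zero_phase(x[::-1], filt)[::-1]
        np.testing.assert_allclose(z[2000:-2000], y[2000:-2000],
                                   atol=1e-9 * np.abs(y).max())
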