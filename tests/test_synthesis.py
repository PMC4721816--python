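"""Analog filter synthesis: notch/highpass designs, published functions,
level scaling and bank assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import adwt
from adwt.synthesis import (
    ADWTDesignParams,
    RationalTF,
    build_filter_bank,
    design_approx_filter,
    design_details_filter,
    scale_level,
    table2_filters,
)


def rel_close(a, b, tol):
    return abs(a - b) <= tol * abs(b)


class TestApproxFilterDesign:
    def test_db1_notch_matches_published(self):
        """Monic denominator s^2 + 1599 s + 1.279e6; numerator sqrt(2)(s^2 + wn^2)."""
        tf = design_approx_filter(ADWTDesignParams.for_wavelet("db1", 360))
        den = tf.den
        num = tf.num
        assert den[0] == pytest.approx(1.0)
        assert rel_close(den[1], 1599.0, 5e-3)
        assert rel_close(den[2], 1.279e6, 5e-3)
        assert rel_close(num[0], 1.414, 5e-3)
        assert abs(num[1]) < 1e-6 * abs(num[2])
        assert rel_close(num[2], 1.809e6, 5e-3)

    def test_db4_notch_matches_published(self):
        """All nine published coefficients after scaling the denominator
        leading coefficient to 21609, each within 0.5 % (printed precision)."""
        tf = design_approx_filter(ADWTDesignParams.for_wavelet("db4", 360))
        den = 21609.0 * tf.den
        num = 21609.0 * tf.num
        for got, want in zip(den, [21609, 4.441e7, 9.495e10, 5.067e13, 2.813e16]):
            assert rel_close(got, want, 5e-3)
        for got, want in zip(num[::2], [3.056e4, 6.973e10, 3.978e16]):
            assert rel_close(got, want, 5e-3)
        assert abs(num[1]) < 1e-6 * abs(num[2])
        assert abs(num[3]) < 1e-6 * abs(num[4])

    def test_exact_transmission_zeros_and_dc_gain(self):
        """|A(j wn)| = 0 to machine precision; DC gain sqrt(2) within 1e-9."""
        for wav in ("db1", "db4"):
            params = ADWTDesignParams.for_wavelet(wav, 360)
            tf = design_approx_filter(params)
            assert abs(tf.eval(1j * params.approx_wn)) < 1e-12
            assert abs(tf.dc_gain() - np.sqrt(2)) < 1e-9

    @given(
        fs=st.floats(10.0, 5000.0),
        fn_ratio=st.floats(1.5, 4.0),
        q=st.floats(0.3, 3.0),
    )
    @settings(deadline=None, max_examples=30)
    def test_dc_gain_property(self, fs, fn_ratio, q):
        params = ADWTDesignParams(
            wavelet=adwt.WaveletSpec("db4", 4), base_fs=fs, details_order=4,
            details_fc_ratio=2.34, approx_fn_ratio=fn_ratio, approx_q=q,
        )
        tf = design_approx_filter(params)
        assert abs(tf.dc_gain() - np.sqrt(2)) < 1e-9
        assert abs(abs(tf.eval(np.array(1e9j))) - np.sqrt(2)) < 1e-6


class TestDetailsFilterDesign:
    def test_db1_pole_matches_published_ratio(self):
        """Single real pole at 4524/4 = 1131 rad/s, to 4 significant figures."""
        tf = design_details_filter(ADWTDesignParams.for_wavelet("db1", 360))
        assert tf.poles.size == 1
        assert rel_close(-tf.poles[0].real, 4524.0 / 4.0, 5e-4)

    def test_db4_butterworth_denominator(self):
        """Monic 4th-order Butterworth: s^3 coefficient 2.6131 * wc."""
        params = ADWTDesignParams.for_wavelet("db4", 360)
        tf = design_details_filter(params)
        assert rel_close(tf.den[1], 2.6131 * params.details_wc, 1e-4)

    def test_highpass_normalization(self):
        """|H(0)| = 0 exactly, |H(j inf)| = 1."""
        for wav in ("db1", "db4"):
            tf = design_details_filter(ADWTDesignParams.for_wavelet(wav, 360))
            assert tf.dc_gain() == 0.0
            assert tf.hf_gain() == pytest.approx(1.0)


class TestTable2:
    def test_literal_coefficients_at_360(self):
        t2 = table2_filters(360.0)
        np.testing.assert_allclose(t2["A1"].num, [1.414, 0, 1.809e6], rtol=1e-9)
        np.testing.assert_allclose(t2["A1"].den, [1.0, 1599.0, 1.279e6], rtol=1e-9)
        # D1 = -9s/(4s+4524): monic form -2.25 s / (s + 1131)
        assert t2["D1"].hf_gain() == pytest.approx(-2.25)
        assert t2["D1"].poles[0].real == pytest.approx(-1131.0)
        assert t2["D4"].hf_gain() == pytest.approx(-3.65e-11 / 1.825e-11)
        # denominator constant-to-leading ratio of the printed D4 row
        d4 = t2["D4"].den
        assert rel_close(d4[-1] / d4[0], 1.0 / 1.825e-11, 1e-3)

    def test_frequency_scaling(self):
        """Doubling the base rate doubles the notch frequency (2262 rad/s)."""
        a1 = table2_filters(720.0)["A1"]
        notch = abs(a1.zeros[0].imag)
        assert rel_close(notch, 2262.0, 1e-3)
        assert a1.dc_gain() == pytest.approx(1.809e6 / 1.279e6, rel=1e-9)


class TestLevelScaling:
    def test_level_one_is_identity(self):
        tf = design_details_filter(ADWTDesignParams.for_wavelet("db1", 360))
        assert scale_level(tf, 1) is tf

    def test_d1_level2_pole(self):
        tf = design_details_filter(ADWTDesignParams.for_wavelet("db1", 360))
        lvl2 = scale_level(tf, 2)
        assert -lvl2.poles[0].real == pytest.approx(565.5, rel=1e-3)

    @pytest.mark.parametrize("level", [2, 3, 5])
    def test_magnitude_substitution_property(self, level):
        """|H_level(jw)| = |H_1(j w 2^(level-1))| on a sampled grid."""
        tf = design_approx_filter(ADWTDesignParams.for_wavelet("db4", 360))
        scaled = scale_level(tf, level)
        f = np.geomspace(0.5, 500.0, 64)
        np.testing.assert_allclose(
            np.abs(scaled.freq_response(f)),
            np.abs(tf.freq_response(f * 2 ** (level - 1))),
            rtol=1e-9,
        )

    def test_scaling_associativity(self):
        tf = design_details_filter(ADWTDesignParams.for_wavelet("db4", 360))
        a = scale_level(scale_level(tf, 3), 2)
        b = scale_level(tf, 4)
        np.testing.assert_allclose(np.sort_complex(a.poles), np.sort_complex(b.poles))
        assert a.gain == pytest.approx(b.gain)


class TestFilterBank:
    def test_structure_and_deep_pole(self):
        """db1 x 4 levels: 8 transfer functions; D_4 pole at 1131/8 rad/s."""
        bank = build_filter_bank(ADWTDesignParams.for_wavelet("db1", 360), 4)
        assert len(bank.approx) == len(bank.details) == 4
        assert -bank.details[3].poles[0].real == pytest.approx(141.4, rel=1e-3)

    def test_designed_mode_consistency(self):
        params = ADWTDesignParams.for_wavelet("db4", 360)
        bank = build_filter_bank(params, 1, gain="normalized")
        ref = design_approx_filter(params)
        np.testing.assert_allclose(
            np.sort_complex(bank.approx[0].poles), np.sort_complex(ref.poles)
        )

    def test_notch_frequency_halves_per_level(self):
        bank = build_filter_bank(ADWTDesignParams.for_wavelet("db4", 360), 4)
        notches = [abs(a.zeros[0].imag) for a in bank.approx]
        for i in range(3):
            assert notches[i] / notches[i + 1] == pytest.approx(2.0)

    def test_fir_matched_gains(self):
        """A branch hits sqrt(2) at DC; D branch is negative at infinity."""
        for wav in ("db1", "db4"):
            bank = build_filter_bank(
                ADWTDesignParams.for_wavelet(wav, 360), 2, gain="fir_matched"
            )
            assert bank.approx[0].dc_gain() == pytest.approx(np.sqrt(2))
            assert bank.details[0].hf_gain() < 0

    def test_literal_requires_table2(self):
        with pytest.raises(ValueError):
            build_filter_bank(
                ADWTDesignParams.for_wavelet("db1", 360), 1, gain="literal"
            )

    def test_magnitude_estimation_envelope(self):
        """Fitted first-order pair tracks the db1 FIR magnitudes within
        1.5 dB wherever the FIR response is appreciable (0.01-0.5 x fs grid)."""
        params = ADWTDesignParams.for_wavelet("db1", 360)
        bank = build_filter_bank(params, 1, gain="fir_matched")
        pair = adwt.daubechies_filters("db1", 360)
        f = np.geomspace(3.6, 180.0, 512)
        w = np.exp(-1j * 2 * np.pi * np.outer(f / 360, np.arange(2)))
        fir_lo = np.abs(w @ pair.lowpass)
        fir_hi = np.abs(w @ pair.highpass)
        in_a = f <= 0.5 * 360 / params.approx_fn_ratio
        in_d = fir_hi > 0.3 * np.sqrt(2)
        err_a = 20 * np.log10(np.abs(bank.approx[0].freq_response(f[in_a])) / fir_lo[in_a])
        err_d = 20 * np.log10(np.abs(bank.details[0].freq_response(f[in_d])) / fir_hi[in_d])
        assert np.max(np.abs(err_a)) < 1.5
        assert np.max(np.abs(err_d)) < 1.5


class TestRationalTF:
    def test_polynomial_roundtrip_preserves_response(self):
        """zpk -> ba -> zpk round trip: 1e-9 relative on an evaluation grid."""
        tf = design_approx_filter(ADWTDesignParams.for_wavelet("db4", 360))
        back = RationalTF.from_ba(tf.num, tf.den)
        f = np.geomspace(1.0, 1000.0, 128)
        np.testing.assert_allclose(
            back.freq_response(f), tf.freq_response(f), rtol=1e-9
        )

    def test_improper_rejected(self):
        with pytest.raises(ValueError):
            RationalTF(zeros=[0.0, 0.0], poles=[-1.0], gain=1.0)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            ADWTDesignParams(
                wavelet=adwt.WaveletSpec("db1", 1), base_fs=360,
                details_order=1, details_fc_ratio=-2, approx_fn_ratio=2,
                approx_q=0.7,
            )
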