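"""Analog (s-domain) filter synthesis for the continuous-time wavelet bank.

The decimated DWT is approximated by a bank of analog-prototype filters:
the details (highpass) branch of a Daubechies-N decomposition has a
maximally flat magnitude response and is matched by a Butterworth highpass;
the approximation (lowpass) branch is matched by the lower half of a
Butterworth band-stop (notch) response with sqrt(2) passband gain (the tap
sum of the FIR lowpass).  Instead of decimating between levels, every
filter's cut-off is halved per level.

Filters are carried as zeros/poles/gain internally — polynomial
coefficients at the rad/s scales involved (up to ~1e16 for the 4th-order
notch) are ill-conditioned — and rendered to descending-power polynomial
form only on demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .wavelets import WaveletSpec

__all__ = [
    "RationalTF",
    "ADWTDesignParams",
    "ADWTFilterBank",
    "design_details_filter",
    "design_approx_filter",
    "table2_filters",
    "scale_level",
    "build_filter_bank",
]


@dataclass(frozen=True)
class RationalTF:
    """Proper rational transfer function H(s) in rad/s units.

    Stored as zeros/poles/gain:  H(s) = gain * prod(s - z) / prod(s - p).
    ``num``/``den`` render descending-power polynomial coefficients.
    """

    zeros: np.ndarray
    poles: np.ndarray
    gain: float

    def __post_init__(self) -> None:
        z = np.atleast_1d(np.asarray(self.zeros, dtype=complex))
        p = np.atleast_1d(np.asarray(self.poles, dtype=complex))
        if z.size > p.size:
            raise ValueError("improper transfer function (deg num > deg den)")
        if not (np.isfinite(z).all() and np.isfinite(p).all() and np.isfinite(self.gain)):
            raise ValueError("non-finite zero/pole/gain")
        object.__setattr__(self, "zeros", z)
        object.__setattr__(self, "poles", p)

    @classmethod
    def from_ba(cls, num, den) -> "RationalTF":
        num = np.atleast_1d(np.asarray(num, dtype=float))
        den = np.atleast_1d(np.asarray(den, dtype=float))
        if den[0] == 0:
            raise ValueError("denominator leading coefficient must be nonzero")
        z, p, k = scipy.signal.tf2zpk(num, den)
        return cls(zeros=z, poles=p, gain=float(k))

    @property
    def num(self) -> np.ndarray:
        """Numerator coefficients, descending powers of s."""
        return np.real(self.gain * np.poly(self.zeros))

    @property
    def den(self) -> np.ndarray:
        """Monic denominator coefficients, descending powers of s."""
        return np.real(np.poly(self.poles))

    @property
    def order(self) -> int:
        return self.poles.size

    def eval(self, s) -> np.ndarray:
        """Evaluate H(s) at complex frequencies ``s`` (product form)."""
        s = np.asarray(s, dtype=complex)
        out = np.full(s.shape, self.gain, dtype=complex)
        for z in self.zeros:
            out = out * (s - z)
        for p in self.poles:
            out = out / (s - p)
        return out

    def freq_response(self, f_hz) -> np.ndarray:
        """H(j 2*pi*f) at frequencies in Hz."""
        return self.eval(1j * 2 * np.pi * np.asarray(f_hz, dtype=float))

    def dc_gain(self) -> float:
        return float(np.real(self.eval(np.array(0.0))))

    def hf_gain(self) -> float:
        """Gain as s -> infinity (0 unless deg num == deg den)."""
        if self.zeros.size < self.poles.size:
            return 0.0
        return float(self.gain)

    def with_gain_factor(self, c: float) -> "RationalTF":
        return RationalTF(self.zeros, self.poles, self.gain * c)

    def substitute(self, a: float) -> "RationalTF":
        """Return H(a*s): zeros/poles divided by ``a``, gain adjusted."""
        if a <= 0:
            raise ValueError("substitution factor must be positive")
        k = self.gain * a ** (self.zeros.size - self.poles.size)
        return RationalTF(self.zeros / a, self.poles / a, k)

    def cascade(self, other: "RationalTF") -> "RationalTF":
        return RationalTF(
            np.concatenate([self.zeros, other.zeros]),
            np.concatenate([self.poles, other.poles]),
            self.gain * other.gain,
        )

    def to_ss(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Controllable-canonical state-space realization (A, B, C, D)."""
        return scipy.signal.tf2ss(self.num, self.den)

    def is_stable(self) -> bool:
        return bool(np.all(np.real(self.poles) < 0))


@dataclass(frozen=True)
class ADWTDesignParams:
    """Synthesis parameters of the analog bank for one mother wavelet.

    The details branch is a Butterworth highpass of order ``details_order``
    with cut-off ``fc = base_fs / details_fc_ratio``; the approximation
    branch is a Butterworth band-stop with notch ``fn = base_fs /
    approx_fn_ratio`` and quality factor ``approx_q``.  Defaults follow the
    published fits: db1 -> order 1, fc = fs/2, fn = fs/2, Q = 1/sqrt(2);
    db4 -> order 4, fc = fs/2.34, fn = fs/2.12, Q = 0.735.
    """

    wavelet: WaveletSpec
    base_fs: float
    details_order: int
    details_fc_ratio: float
    approx_fn_ratio: float
    approx_q: float

    _DEFAULTS = {
        1: dict(details_order=1, details_fc_ratio=2.0, approx_fn_ratio=2.0,
                approx_q=1.0 / math.sqrt(2.0)),
        4: dict(details_order=4, details_fc_ratio=2.34, approx_fn_ratio=2.12,
                approx_q=0.735),
    }

    def __post_init__(self) -> None:
        if self.base_fs <= 0:
            raise ValueError("base_fs must be positive")
        if self.details_order < 1:
            raise ValueError("details_order must be >= 1")
        if min(self.details_fc_ratio, self.approx_fn_ratio, self.approx_q) <= 0:
            raise ValueError("ratios and Q must be strictly positive")

    @classmethod
    def for_wavelet(cls, wavelet: WaveletSpec | str, base_fs: float) -> "ADWTDesignParams":
        if isinstance(wavelet, str):
            wavelet = WaveletSpec.from_name(wavelet)
        try:
            d = cls._DEFAULTS[wavelet.order]
        except KeyError:
            raise ValueError(
                f"no published design parameters for {wavelet.name}; "
                "construct ADWTDesignParams explicitly"
            ) from None
        return cls(wavelet=wavelet, base_fs=float(base_fs), **d)

    @property
    def details_wc(self) -> float:
        """Details cut-off in rad/s."""
        return 2 * math.pi * self.base_fs / self.details_fc_ratio

    @property
    def approx_wn(self) -> float:
        """Approximation notch frequency in rad/s."""
        return 2 * math.pi * self.base_fs / self.approx_fn_ratio

    @property
    def approx_prototype_order(self) -> int:
        """Lowpass prototype order of the band-stop; analog order is twice this."""
        return max(1, self.details_order // 2)


def design_details_filter(params: ADWTDesignParams) -> RationalTF:
    """Butterworth highpass matching the Daubechies details magnitude.

    Order ``details_order``, -3 dB cut-off at ``2*pi*base_fs /
    details_fc_ratio`` rad/s, high-frequency (passband) gain 1 and exact
    zero transmission at DC.
    """
    z, p, k = scipy.signal.butter(
        params.details_order, params.details_wc, btype="highpass",
        analog=True, output="zpk",
    )
    return RationalTF(z, p, float(k))


def design_approx_filter(params: ADWTDesignParams) -> RationalTF:
    """Butterworth band-stop (notch) matching the approximation magnitude.

    The Butterworth lowpass prototype of order ``approx_prototype_order``
    is transformed to a band-stop via p -> ((wn/Q) s) / (s^2 + wn^2), i.e.
    notch at ``wn`` with stop bandwidth ``wn/Q``, giving exact transmission
    zeros at +/- j*wn and a numerator proportional to
    ``(s^2 + wn^2)**prototype_order``.  Overall gain is sqrt(2) at DC and at
    infinity, matching the FIR lowpass tap sum.
    """
    m = params.approx_prototype_order
    z, p, k = scipy.signal.butter(m, 1.0, btype="lowpass", analog=True, output="zpk")
    wn = params.approx_wn
    z, p, k = scipy.signal.lp2bs_zpk(z, p, k, wo=wn, bw=wn / params.approx_q)
    tf = RationalTF(z, p, float(k))
    # butter+lp2bs already give unit DC gain; scale to sqrt(2) exactly
    return tf.with_gain_factor(math.sqrt(2.0) / tf.dc_gain())


# Published level-1 transfer functions for base sampling frequency 360 Hz,
# as (num, den) in descending powers of s.  The D-branch gains (2.25, 2.0)
# and signs are the printed ones.
_TABLE2_360 = {
    "A1": ([1.414, 0.0, 1.809e6], [1.0, 1599.0, 1.279e6]),
    "D1": ([-9.0, 0.0], [4.0, 4524.0]),
    "A4": (
        [3.056e4, 0.0, 6.973e10, 0.0, 3.978e16],
        [21609.0, 4.441e7, 9.495e10, 5.067e13, 2.813e16],
    ),
    "D4": (
        [-3.65e-11, 0.0, 0.0, 0.0, 0.0],
        [1.825e-11, 2.498e-8, 1.709e-5, 0.005846, 1.0],
    ),
}


def table2_filters(base_fs: float = 360.0) -> dict[str, RationalTF]:
    """The literal published level-1 filters {A1, D1, A4, D4}.

    Printed for a 360 Hz base rate; for any other rate the 360 Hz functions
    are frequency-scaled (s -> s*360/base_fs), preserving the printed gains
    (sqrt(2) DC on the A branch, 2.25 / 2.0 high-frequency on D1 / D4).
    """
    if base_fs <= 0:
        raise ValueError("base_fs must be positive")
    out: dict[str, RationalTF] = {}
    for name, (num, den) in _TABLE2_360.items():
        tf = RationalTF.from_ba(num, den)
        if base_fs != 360.0:
            tf = tf.substitute(360.0 / base_fs)
        out[name] = tf
    return out


def scale_level(tf: RationalTF, level: int) -> RationalTF:
    """Level-i version of a level-1 filter: cut-off divided by 2**(level-1).

    Implemented as H_level(s) = H(2**(level-1) * s), so
    |H_level(jw)| = |H_1(j * w * 2**(level-1))| and deeper levels analyse
    lower bands; gains at s = 0 and s = infinity are unchanged.
    """
    if level < 1 or int(level) != level:
        raise ValueError("level must be a positive integer")
    if level == 1:
        return tf
    return tf.substitute(2.0 ** (level - 1))


def _lsq_details_gain(d1: RationalTF, params: ADWTDesignParams) -> float:
    """Least-squares amplitude match of the unit-gain analog highpass to the
    FIR details magnitude over [0.05, 0.95] x Nyquist."""
    from .wavelets import daubechies_filters

    fs = params.base_fs
    pair = daubechies_filters(params.wavelet, base_fs=fs)
    f = np.geomspace(0.05 * fs / 2, 0.95 * fs / 2, 256)
    ha = np.abs(d1.freq_response(f)) / abs(d1.hf_gain())
    w = np.exp(-1j * 2 * np.pi * np.outer(f / fs, np.arange(pair.highpass.size)))
    hf = np.abs(w @ pair.highpass)
    return float(np.dot(ha, hf) / np.dot(ha, ha))


@dataclass(frozen=True)
class ADWTFilterBank:
    """Per-level analog filter pairs: ``approx[i-1]``/``details[i-1]`` are
    the level-i filters, the level-1 designs with cut-offs divided by
    2**(i-1)."""

    levels: int
    approx: list[RationalTF]
    details: list[RationalTF]
    design: ADWTDesignParams
    mode: str = "designed"
    gain: str = "fir_matched"


def build_filter_bank(
    params: ADWTDesignParams,
    levels: int,
    mode: str = "designed",
    gain: str = "fir_matched",
) -> ADWTFilterBank:
    """Assemble the multi-resolution analog bank.

    Parameters
    ----------
    mode : {"designed", "table2"}
        ``designed`` synthesizes the level-1 pair from ``params``;
        ``table2`` starts from the literal published transfer functions
        (db1/db4 only).
    gain : {"fir_matched", "normalized", "literal"}
        ``fir_matched`` sets the approximation DC gain and the details
        high-frequency gain to sqrt(2), the FIR branch gains at DC/Nyquist,
        so analog and digital outputs are on a common amplitude scale.
        ``normalized`` sets both passband gains to 1 (0 dB).  ``literal``
        keeps the published gains and is only meaningful with
        ``mode="table2"``.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if mode == "designed":
        a1 = design_approx_filter(params)  # sqrt(2) DC by construction
        d1 = design_details_filter(params)  # unit HF gain by construction
    elif mode == "table2":
        t2 = table2_filters(params.base_fs)
        key = params.wavelet.order
        if key not in (1, 4):
            raise ValueError("table2 mode covers db1 and db4 only")
        a1, d1 = t2[f"A{key}"], t2[f"D{key}"]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    root2 = math.sqrt(2.0)
    if gain == "fir_matched":
        # A branch: both the FIR lowpass tap sum and the notch DC gain anchor
        # at sqrt(2) exactly.  D branch: the analog highpass reaches its
        # asymptotic gain only at infinity while the FIR peaks at Nyquist, so
        # a single anchor point under-weights the passband; instead the gain
        # is fitted least-squares to the FIR magnitude over the details band
        # (this reproduces the ~2.25 / ~2.0 gains of the published level-1
        # filters).  The sign is negative: the alternating-sign highpass
        # construction gives a negative Nyquist response at every order.
        a1 = a1.with_gain_factor(root2 / a1.dc_gain())
        d1 = d1.with_gain_factor(-_lsq_details_gain(d1, params) / d1.hf_gain())
    elif gain == "normalized":
        a1 = a1.with_gain_factor(1.0 / a1.dc_gain())
        d1 = RationalTF(d1.zeros, d1.poles, d1.gain / abs(d1.hf_gain()))
    elif gain == "literal":
        if mode != "table2":
            raise ValueError("gain='literal' requires mode='table2'")
    else:
        raise ValueError(f"unknown gain mode {gain!r}")

    approx = [scale_level(a1, i) for i in range(1, levels + 1)]
    details = [scale_level(d1, i) for i in range(1, levels + 1)]
    return ADWTFilterBank(
        levels=levels, approx=approx, details=details,
        design=params, mode=mode, gain=gain,
    )
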