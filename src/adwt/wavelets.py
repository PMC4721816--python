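"""Reference digital DWT: Daubechies filters and the decimated filter bank.

This is the digital side of the comparison: orthogonal Daubechies
decomposition filters built by spectral factorization of the maximally-flat
half-band polynomial, a multi-resolution filter bank with factor-2
decimation, and the band-edge bookkeeping used by the EEG feature extractor.

Conventions
-----------
* 0-based indexing; decimation keeps the odd-indexed samples (1, 3, 5, ...)
  of each filtered stream.
* Default boundary handling is causal zero-initial-condition filtering,
  which mirrors an analog filter starting at rest and makes transient
  comparisons with the continuous-time bank fair.  A periodic-extension
  mode is available; with it the transform is orthogonal and conserves
  energy exactly.
* Coefficient time stamps are the retained output-sample positions in
  seconds.  No group-delay correction is applied at this layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .signals import Signal

__all__ = [
    "WaveletSpec",
    "FIRFilterPair",
    "DWTDecomposition",
    "daubechies_filters",
    "dwt_multires",
    "band_edges",
]


@dataclass(frozen=True)
class WaveletSpec:
    """A Daubechies mother wavelet: ``order`` vanishing moments, 2*order taps."""

    name: str
    order: int

    @classmethod
    def from_name(cls, name: str) -> "WaveletSpec":
        key = name.lower()
        if not key.startswith("db"):
            raise ValueError(f"unsupported wavelet {name!r}; expected 'dbN'")
        try:
            order = int(key[2:])
        except ValueError:
            raise ValueError(f"unsupported wavelet {name!r}; expected 'dbN'") from None
        if order < 1:
            raise ValueError("wavelet order must be a positive integer")
        return cls(name=key, order=order)


@dataclass(frozen=True)
class FIRFilterPair:
    """Decomposition filter pair of an orthogonal wavelet.

    ``lowpass`` is the approximation filter, ``highpass`` the details filter;
    index 0 is the z^0 tap.  Invariants: equal length 2*order,
    sum(lowpass) = sqrt(2), sum(highpass) = 0, unit energy each.
    """

    lowpass: np.ndarray
    highpass: np.ndarray
    base_fs: float

    def __post_init__(self) -> None:
        lo = np.asarray(self.lowpass, dtype=float)
        hi = np.asarray(self.highpass, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lowpass/highpass must be 1-D of equal length")
        object.__setattr__(self, "lowpass", lo)
        object.__setattr__(self, "highpass", hi)


@dataclass(frozen=True)
class DWTDecomposition:
    """Multi-resolution DWT output.

    ``details[i]`` / ``detail_times[i]`` hold the level-(i+1) detail
    coefficients and their time stamps; ``approximation`` is the final-level
    approximation stream.  Level-i coefficients arrive at rate
    ``base_fs / 2**i``.
    """

    levels: int
    details: list[np.ndarray]
    detail_times: list[np.ndarray]
    approximation: np.ndarray
    approximation_times: np.ndarray
    base_fs: float
    wavelet: WaveletSpec


def daubechies_filters(spec: WaveletSpec | str, base_fs: float = 1.0) -> FIRFilterPair:
    """Orthogonal Daubechies decomposition filters for ``spec``.

    The scaling filter is obtained by spectral factorization: the
    maximally-flat half-band autocorrelation is factored and the
    minimum-phase (inside the unit circle) roots are retained, the result is
    convolved with the binomial factor ``((1+z^-1)/2)**order`` and the tap
    sum normalized to sqrt(2).  The decomposition lowpass is the
    time-reverse of the scaling filter; the highpass is its
    quadrature-mirror alternating-sign reversal,
    ``g[n] = (-1)**(n+1) h[L-1-n]``.

    Parameters
    ----------
    spec : WaveletSpec or str
        Wavelet, e.g. ``"db4"``.
    base_fs : float
        Sampling rate the pair is associated with (bookkeeping only).
    """
    if isinstance(spec, str):
        spec = WaveletSpec.from_name(spec)
    order = spec.order
    if order < 1 or int(order) != order:
        raise ValueError("wavelet order must be a positive integer")

    # P(y) = sum_k C(order-1+k, k) y^k : the maximally-flat residual.
    from scipy.special import comb

    k = np.arange(order)
    poly_y = comb(order - 1 + k, k)  # ascending powers of y

    h = np.array([1.0 + 0j])
    if order > 1:
        for y0 in np.roots(poly_y[::-1]):
            # y = (2 - z - 1/z)/4  =>  z + 1/z = 2 - 4 y0; keep |z| < 1.
            zr = np.roots([1.0, -(2.0 - 4.0 * y0), 1.0])
            z0 = zr[np.argmin(np.abs(zr))]
            h = np.convolve(h, [1.0, -z0])
    for _ in range(order):
        h = np.convolve(h, [0.5, 0.5])
    h = np.real(h)
    h *= np.sqrt(2.0) / h.sum()  # scaling (reconstruction lowpass) filter

    dec_lo = h[::-1].copy()
    n = np.arange(dec_lo.size)
    dec_hi = ((-1.0) ** (n + 1)) * dec_lo[::-1]
    return FIRFilterPair(lowpass=dec_lo, highpass=dec_hi, base_fs=float(base_fs))


def _analysis_step(x: np.ndarray, taps: np.ndarray, mode: str) -> np.ndarray:
    """Filter then keep odd-indexed outputs (0-based)."""
    if mode == "causal":
        y = scipy.signal.lfilter(taps, [1.0], x)
    elif mode == "periodic":
        if x.size % 2:
            raise ValueError("periodic mode requires even-length streams")
        # circular (periodic-extension) convolution
        y = np.real(np.fft.ifft(np.fft.fft(x) * np.fft.fft(taps, x.size)))
    else:
        raise ValueError(f"unknown boundary mode {mode!r}")
    return y[1::2]


def dwt_multires(
    signal: Signal,
    spec: WaveletSpec | str,
    levels: int,
    mode: str = "causal",
) -> DWTDecomposition:
    """Decimated multi-resolution DWT of a single-channel signal.

    At each level the current approximation stream is filtered by both
    decomposition filters and the odd-indexed outputs retained; the lowpass
    result feeds the next level.  ``mode`` selects the boundary handling:
    ``"causal"`` (zero initial conditions, default) or ``"periodic"``
    (circular extension; orthogonal, energy conserving).

    Raises
    ------
    ValueError
        If the signal is too short (< 2**levels * filter length samples),
        multi-channel, or contains non-finite values.
    """
    if isinstance(spec, str):
        spec = WaveletSpec.from_name(spec)
    if levels < 1 or int(levels) != levels:
        raise ValueError("levels must be a positive integer")
    if signal.n_channels != 1:
        raise ValueError("dwt_multires expects a single-channel signal")
    pair = daubechies_filters(spec, base_fs=signal.fs)
    min_len = 2**levels * pair.lowpass.size
    if signal.n_samples < min_len:
        raise ValueError(
            f"signal too short: {signal.n_samples} samples < {min_len} "
            f"required for {levels} levels"
        )

    x = signal.values
    t = signal.times
    details: list[np.ndarray] = []
    dtimes: list[np.ndarray] = []
    for _ in range(levels):
        details.append(_analysis_step(x, pair.highpass, mode))
        dtimes.append(t[1::2].copy())
        x = _analysis_step(x, pair.lowpass, mode)
        t = t[1::2]
    return DWTDecomposition(
        levels=levels,
        details=details,
        detail_times=dtimes,
        approximation=x,
        approximation_times=t.copy(),
        base_fs=signal.fs,
        wavelet=spec,
    )


def band_edges(base_fs: float, branch: str, level: int) -> tuple[float, float]:
    """Nominal frequency band of a DWT branch, in Hz.

    Details level L covers ``[base_fs/2**(L+1), base_fs/2**L]``; the
    approximation at level L covers ``[0, base_fs/2**(L+1)]``.  At 100 Hz
    the four bands used for EEG features are D2: 12.5-25, D3: 6.25-12.5,
    D4: 3.125-6.25 and A4: 0-3.125 Hz.
    """
    if level < 1 or int(level) != level:
        raise ValueError("level must be a positive integer")
    if branch in ("details", "D", "d"):
        return (base_fs / 2 ** (level + 1), base_fs / 2**level)
    if branch in ("approximation", "A", "a"):
        return (0.0, base_fs / 2 ** (level + 1))
    raise ValueError(f"unknown branch {branch!r}")
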