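"""Continuous-time LTI machinery.

Three jobs: (1) simulate an analog transfer function on a sampled input,
(2) compute group-delay curves — analytically for rational H(s), in seconds
for FIR filters — and (3) bulk-equalize an analog curve against a digital
one with a single fixed delay and report the residual error as a percentage
of a cycle at each frequency.

Simulation discretizes the controllable-canonical state-space model exactly
under first-order-hold (linear-interpolation) input reconstruction and runs
the resulting recursion as a discrete filter, which is O(n) and equivalent
to matrix-exponential stepping.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.signal
from scipy.optimize import minimize_scalar

from .signals import Signal
from .synthesis import RationalTF

__all__ = [
    "GroupDelayCurve",
    "DelayEqualization",
    "simulate",
    "analog_group_delay",
    "fir_group_delay",
    "equalize_and_error",
    "default_band",
    "log_grid",
]


@dataclass(frozen=True)
class GroupDelayCurve:
    """Group delay tau(f) in seconds over strictly increasing frequencies in Hz."""

    freqs: np.ndarray
    delay: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        d = np.asarray(self.delay, dtype=float)
        if f.ndim != 1 or f.shape != d.shape:
            raise ValueError("freqs and delay must be 1-D of equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.isfinite(d).all():
            raise ValueError("non-finite group delay values")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "delay", d)

    def shifted(self, seconds: float) -> "GroupDelayCurve":
        return GroupDelayCurve(self.freqs, self.delay + seconds)


@dataclass(frozen=True)
class DelayEqualization:
    """Result of fixed-delay bulk equalization of two group-delay curves.

    ``error_pct`` is the residual |tau_a - tau_d - fixed_delay| * f * 100 at
    each frequency: the error as a percentage of one cycle at f.
    """

    fixed_delay: float
    freqs: np.ndarray
    error_pct: np.ndarray
    peak: float


def simulate(tf: RationalTF, signal: Signal, oversample: int = 8) -> Signal:
    """Zero-state response of an analog filter to a sampled input.

    The input is linearly interpolated onto a grid ``oversample`` times
    finer, the state-space model is discretized exactly for that grid under
    first-order-hold reconstruction, and the response is returned on the
    fine grid.  An unstable filter triggers a warning but is still
    simulated.
    """
    if signal.n_channels != 1:
        raise ValueError("simulate expects a single-channel signal")
    if not tf.is_stable():
        warnings.warn("transfer function has a pole with positive real part; "
                      "simulating anyway", RuntimeWarning, stacklevel=2)
    fine = signal.resample_linear(oversample)
    dt = 1.0 / fine.fs
    if tf.order == 0:
        return Signal(tf.gain * fine.values, fine.fs, fine.t0)
    A, B, C, D = tf.to_ss()
    n = A.shape[0]
    # Exact discretization for piecewise-linear input over each step:
    # x[k+1] = Ad x[k] + Bd0 u[k] + Bd1 u[k+1], from the augmented
    # matrix exponential (the u-ramp states integrate the segment).
    M = np.zeros((n + 2, n + 2))
    M[:n, :n] = A * dt
    M[:n, n] = (B * dt).ravel()
    M[n, n + 1] = 1.0
    expM = scipy.linalg.expm(M)
    Ad = expM[:n, :n]
    Bd1 = expM[:n, n + 1]
    Bd0 = expM[:n, n] - Bd1
    # z-domain equivalent with one-sample lookahead:
    # H(z) = C (zI - Ad)^-1 (Bd0 + z Bd1) + D, realized as an lfilter
    C1 = np.atleast_2d(C)
    b0, a = scipy.signal.ss2tf(Ad, Bd0[:, None], C1, np.atleast_2d(D))
    b1, _ = scipy.signal.ss2tf(Ad, Bd1[:, None], C1, np.zeros((1, 1)))
    b0 = np.atleast_1d(np.squeeze(b0))
    b1 = np.atleast_1d(np.squeeze(b1))
    b = b0 + np.r_[b1[1:], 0.0]  # b1[0] = 0 (strictly proper), so z*b1 stays proper
    u = fine.values
    y = scipy.signal.lfilter(b, a, u)
    if u[0] != 0.0:
        # the z-domain solution implies x[0] = Bd1*u[0]; remove its free
        # response so the simulation is genuinely zero-state
        imp = np.zeros(u.size)
        imp[0] = u[0]
        y -= scipy.signal.lfilter(np.r_[b1[1:], 0.0], a, imp)
    return Signal(y, fine.fs, fine.t0)


def analog_group_delay(tf: RationalTF, freqs) -> GroupDelayCurve:
    """Analytic group delay of a rational H(s) at frequencies in Hz.

    tau(w) = -d(phase)/dw evaluated in closed form from the pole/zero
    positions: each root r contributes -Re(r)/|jw - r|^2 with opposite
    signs for zeros and poles.  Frequencies landing exactly on a
    jw-axis transmission zero (a notch) have undefined phase slope and are
    excluded with a warning.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    w = 2 * np.pi * f
    tau = np.zeros_like(w)
    singular = np.zeros(w.shape, dtype=bool)
    for roots, sign in ((tf.zeros, +1.0), (tf.poles, -1.0)):
        for r in roots:
            d2 = np.real(r) ** 2 + (w - np.imag(r)) ** 2
            bad = d2 == 0.0
            singular |= bad
            d2 = np.where(bad, np.nan, d2)
            tau += sign * np.real(r) / d2
    if singular.any():
        warnings.warn(
            f"{int(singular.sum())} frequencies coincide with jw-axis zeros; "
            "excluded from the group-delay curve", RuntimeWarning, stacklevel=2)
        keep = ~singular
        return GroupDelayCurve(f[keep], tau[keep])
    return GroupDelayCurve(f, tau)


def fir_group_delay(coeffs, base_fs: float, freqs) -> GroupDelayCurve:
    """Group delay of an FIR filter, in seconds, at frequencies in Hz."""
    b = np.atleast_1d(np.asarray(coeffs, dtype=float))
    if b.size < 2:
        raise ValueError("need at least 2 taps")
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0) or np.any(f >= base_fs / 2):
        raise ValueError("frequencies must lie in (0, base_fs/2)")
    w = 2 * np.pi * f / base_fs
    _, gd = scipy.signal.group_delay((b, [1.0]), w=w)
    return GroupDelayCurve(f, gd / base_fs)


def log_grid(f_lo: float, f_hi: float, n: int = 512) -> np.ndarray:
    """Logarithmic frequency grid in Hz, endpoints inclusive."""
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    return np.geomspace(f_lo, f_hi, n)


def default_band(branch: str, base_fs: float, params=None) -> tuple[float, float]:
    """Default evaluation band for group-delay error, in Hz.

    Details branch: [0.05, 0.95] x Nyquist intersected with the filter's
    -3 dB passband (above fc); if the intersection is empty (db1, whose fc
    sits at Nyquist) the full [0.05, 0.95] x Nyquist span is used.
    Approximation branch: [0.01 * base_fs, 0.8 * fn], which excludes DC and
    stays clear of the notch singularity.  These are config defaults, not
    published values, and every entry point accepts an explicit band.
    """
    nyq = base_fs / 2.0
    if branch in ("details", "D", "d"):
        lo, hi = 0.05 * nyq, 0.95 * nyq
        if params is not None:
            fc = base_fs / params.details_fc_ratio
            if lo < fc < hi:
                lo = fc
        return lo, hi
    if branch in ("approximation", "A", "a"):
        if params is None:
            raise ValueError("approximation band needs design params (fn)")
        fn = base_fs / params.approx_fn_ratio
        return 0.01 * base_fs, 0.8 * fn
    raise ValueError(f"unknown branch {branch!r}")


def equalize_and_error(
    analog: GroupDelayCurve,
    digital: GroupDelayCurve,
    band: tuple[float, float],
) -> DelayEqualization:
    """Minimax fixed-delay equalization of an analog vs a digital curve.

    Finds the single delay d minimizing the peak of
    ``|tau_analog(f) - tau_digital(f) - d| * f * 100`` over the band — the
    worst residual expressed as a percentage of a cycle at each frequency.
    The objective is a maximum of convex V-shapes in d, hence unimodal;
    a bounded scalar minimization locates the optimum.
    """
    lo, hi = band
    if not (lo < hi):
        raise ValueError("empty band")
    if analog.freqs.shape != digital.freqs.shape or not np.allclose(
        analog.freqs, digital.freqs
    ):
        raise ValueError("curves must share a frequency grid")
    mask = (analog.freqs >= lo) & (analog.freqs <= hi)
    if not mask.any():
        raise ValueError("band contains no grid frequencies")
    f = analog.freqs[mask]
    dtau = analog.delay[mask] - digital.delay[mask]

    def peak_at(d: float) -> float:
        return float(np.max(np.abs(dtau - d) * f * 100.0))

    span = dtau.max() - dtau.min()
    bounds = (dtau.min() - 0.5 * span - 1e-9, dtau.max() + 0.5 * span + 1e-9)
    res = minimize_scalar(peak_at, bounds=bounds, method="bounded",
                          options={"xatol": 1e-13})
    d_opt = float(res.x)
    err = np.abs(dtau - d_opt) * f * 100.0
    return DelayEqualization(fixed_delay=d_opt, freqs=f, error_pct=err,
                             peak=float(err.max()))
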