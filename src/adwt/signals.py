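"""Sampled-signal container shared by every module.

A :class:`Signal` is a uniformly sampled real series: a value array of shape
``(n,)`` (single channel) or ``(n, c)`` (``c`` channels), a sampling rate in
Hz and a start time.  Frequencies are Hz everywhere at this level; rad/s
appears only inside the analog transfer-function internals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Signal:
    """Uniformly sampled signal.

    Parameters
    ----------
    values : ndarray, shape (n,) or (n, c)
        Sample values.  Must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim not in (1, 2) or values.shape[0] == 0:
            raise ValueError("values must be a non-empty 1-D or 2-D array")
        if not np.isfinite(values).all():
            raise ValueError("signal contains non-finite samples")
        if not (self.fs > 0):
            raise ValueError("fs must be positive")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, idx: int) -> "Signal":
        """Extract one channel as a single-channel signal."""
        if self.values.ndim == 1:
            if idx != 0:
                raise IndexError("single-channel signal")
            return self
        return Signal(self.values[:, idx], self.fs, self.t0)

    def stride_sample(self, factor: int) -> "Signal":
        """Keep every ``factor``-th sample (an ideal ADC with no further
        anti-alias filtering; the front end sets the bandwidth)."""
        if factor < 1 or int(factor) != factor:
            raise ValueError("factor must be a positive integer")
        return Signal(self.values[::factor].copy(), self.fs / factor, self.t0)

    def resample_linear(self, oversample: int) -> "Signal":
        """Linearly interpolate onto a grid ``oversample`` times finer.

        Used to feed continuous-time simulations: linear interpolation is
        consistent with the first-order-hold input reconstruction the
        simulator assumes.
        """
        if oversample < 1 or int(oversample) != oversample:
            raise ValueError("oversample must be a positive integer")
        if oversample == 1:
            return self
        n_fine = (self.n_samples - 1) * oversample + 1
        t = np.arange(self.n_samples) / self.fs
        tf = np.arange(n_fine) / (self.fs * oversample)
        if self.values.ndim == 1:
            v = np.interp(tf, t, self.values)
        else:
            v = np.column_stack(
                [np.interp(tf, t, self.values[:, c]) for c in range(self.n_channels)]
            )
        return Signal(v, self.fs * oversample, self.t0)
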