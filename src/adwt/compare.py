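"""Side-by-side evaluation of the digital and analog wavelet banks.

Two evaluations: transient alignment — run both transforms on the same
signal, bulk-align each analog branch with a fixed delay and quantify how
closely the decimated coefficients sample the continuous line — and the
group-delay error report comparing each analog branch's delay curve with
its FIR counterpart after minimax fixed-delay equalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ctsim import (
    analog_group_delay,
    default_band,
    equalize_and_error,
    fir_group_delay,
    log_grid,
    simulate,
)
from .signals import Signal
from .synthesis import ADWTDesignParams, ADWTFilterBank, build_filter_bank
from .wavelets import DWTDecomposition, WaveletSpec, daubechies_filters

__all__ = [
    "MultiResResult",
    "adwt_multires",
    "align_and_compare",
    "group_delay_report",
]


@dataclass(frozen=True)
class MultiResResult:
    """Per-level outputs of the analog multi-resolution analysis.

    ``approx[i-1]`` / ``details[i-1]`` are the level-i branch outputs; all
    share one oversampled time base.  ``transform`` tags the origin
    ("ADWT" here; decimated results stay in
    :class:`~adwt.wavelets.DWTDecomposition`).
    """

    levels: int
    approx: list[Signal]
    details: list[Signal]
    bank: ADWTFilterBank
    transform: str = "ADWT"

    @property
    def fs(self) -> float:
        return self.approx[0].fs


def adwt_multires(
    signal: Signal, bank: ADWTFilterBank, oversample: int = 8
) -> MultiResResult:
    """Analog multi-resolution analysis: no decimation anywhere.

    Level-1 filters act on the input; level-i filters (i > 1) act on the
    level-(i-1) continuous approximation output.  The input is interpolated
    onto the oversampled grid once; all outputs share that time base.
    """
    fine = signal.resample_linear(oversample)
    approx: list[Signal] = []
    details: list[Signal] = []
    current = fine
    for i in range(bank.levels):
        details.append(simulate(bank.details[i], current, oversample=1))
        a = simulate(bank.approx[i], current, oversample=1)
        approx.append(a)
        current = a
    return MultiResResult(levels=bank.levels, approx=approx, details=details, bank=bank)


def _best_delay(
    dwt_vals: np.ndarray,
    dwt_times: np.ndarray,
    cont: Signal,
    max_delay: float,
) -> tuple[float, float, int]:
    """Grid-search a fixed delay (over the oversampled grid) minimizing the
    RMS deviation between the delayed continuous line sampled at the
    coefficient time stamps and the coefficients themselves.

    Returns (delay, nrmse, n_points); nrmse is normalized by the RMS of the
    DWT coefficients.
    """
    dt = 1.0 / cont.fs
    t_hi = cont.t0 + (cont.n_samples - 1) * dt
    delays = np.arange(-max_delay, max_delay + 0.5 * dt, dt)
    query = dwt_times[None, :] + delays[:, None]
    valid = (query >= cont.t0) & (query <= t_hi)
    # keep candidates for which most coefficients can be compared
    ok = valid.mean(axis=1) >= 0.5
    delays, query, valid = delays[ok], query[ok], valid[ok]
    sampled = np.interp(query.ravel(), cont.times, cont.values).reshape(query.shape)
    sq = np.where(valid, (sampled - dwt_vals[None, :]) ** 2, np.nan)
    ref = np.where(valid, dwt_vals[None, :] ** 2, np.nan)
    with np.errstate(invalid="ignore"):
        rms = np.sqrt(np.nanmean(sq, axis=1))
        rms_ref = np.sqrt(np.nanmean(ref, axis=1))
    # normalize per candidate so windows spanning different coefficient
    # subsets stay comparable
    nrmse_all = np.where(rms_ref > 0, rms / rms_ref, rms)
    best = int(np.argmin(nrmse_all))
    return float(delays[best]), float(nrmse_all[best]), int(valid[best].sum())


def align_and_compare(
    adwt: MultiResResult,
    dwt: DWTDecomposition,
    max_delay: float | None = None,
) -> pd.DataFrame:
    """Quantify how closely DWT coefficients sample the continuous line.

    For each detail level and the final approximation an independent fixed
    delay is grid-searched over the oversampled time base; the delayed
    continuous output is linearly interpolated at the coefficient time
    stamps and the RMS deviation, normalized by the coefficient RMS, is
    reported.

    Returns a DataFrame with columns level, branch, delay_s, nrmse,
    n_points.  Branches with fewer than 2 coefficients are skipped.
    """
    if adwt.levels != dwt.levels:
        raise ValueError("transforms have different level counts")
    taps = daubechies_filters(dwt.wavelet).lowpass.size
    rows = []
    branches = [("D", i + 1, dwt.details[i], dwt.detail_times[i], adwt.details[i])
                for i in range(dwt.levels)]
    branches.append(("A", dwt.levels, dwt.approximation, dwt.approximation_times,
                     adwt.approx[-1]))
    for branch, level, vals, times, cont in branches:
        if vals.size < 2:
            continue
        w = max_delay
        if w is None:
            # generous window: FIR bulk delay grows as taps * 2**level samples
            w = (4 + 2 * taps) * 2.0 ** (level - 1) / dwt.base_fs
        delay, nrmse, n = _best_delay(vals, times, cont, w)
        rows.append(dict(level=level, branch=branch, delay_s=delay,
                         nrmse=nrmse, n_points=n))
    return pd.DataFrame(rows)


def group_delay_report(
    wavelet: WaveletSpec | str,
    base_fs: float = 360.0,
    mode: str = "designed",
    n_points: int = 512,
    bands: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Group-delay error of the analog bank vs the FIR pair, per branch.

    For each branch the analytic analog group delay and the FIR group delay
    are evaluated on a shared logarithmic grid spanning the branch's
    default evaluation band (overridable via ``bands``), a single fixed
    delay is fitted minimax, and the peak residual is reported as a
    percentage of a cycle.

    Returns a DataFrame with columns branch, f_lo_hz, f_hi_hz,
    fixed_delay_s, peak_pct_cycle.
    """
    if isinstance(wavelet, str):
        wavelet = WaveletSpec.from_name(wavelet)
    params = ADWTDesignParams.for_wavelet(wavelet, base_fs)
    bank = build_filter_bank(params, levels=1, mode=mode, gain="normalized")
    pair = daubechies_filters(wavelet, base_fs=base_fs)
    rows = []
    for branch, tf, taps in (
        ("D", bank.details[0], pair.highpass),
        ("A", bank.approx[0], pair.lowpass),
    ):
        band = (bands or {}).get(branch) or default_band(branch, base_fs, params)
        grid = log_grid(band[0], band[1], n_points)
        res = equalize_and_error(
            analog_group_delay(tf, grid),
            fir_group_delay(taps, base_fs, grid),
            band,
        )
        rows.append(dict(branch=branch, f_lo_hz=band[0], f_hi_hz=band[1],
                         fixed_delay_s=res.fixed_delay, peak_pct_cycle=res.peak))
    return pd.DataFrame(rows)
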