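"""Seeded generators for ECG-like and two-state EEG-like test signals.

The generators are pure functions of their parameter sets (seed included)
and emulate the statistical structure the transform demonstrations assume:

* an ECG-like quasi-periodic train of biphasic beats buried in broadband
  noise, with ground-truth beat times — a transient test signal whose
  events sit below fs/4 so the level-1 details branch carries mostly noise;
* multi-record, two-channel EEG-like signals alternating between a "wake"
  and a "sleep" state whose per-band power profiles over the four sub-bands
  of 0-25 Hz differ, with per-epoch state labels.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import scipy.signal

from .signals import Signal



__all__ = [
    "EcgSynthParams",
    "EegSynthParams",
    "EegRecord",
    "synth_ecg",
    "synth_eeg",
]


@dataclass(frozen=True)
class EcgSynthParams:
    """Noisy ECG-like pulse train.

    The beat template is a sum of two Gaussian-derivative lobes (biphasic,
    bandwidth-controllable); intervals carry +/-5 % uniform jitter;
    broadband noise is added at ``noise_rms``.

    The signal is generated on a continuous-time stand-in grid running at
    ``rate_multiplier * fs`` — the analog front-end view.  The noise is
    muscle-artifact-like: flat to ``noise_bandwidth_hz`` (default fs/4)
    with a gentle 2nd-order roll-off beyond, so genuine content remains
    above the digital Nyquist fs/2.  A digital transform consumes
    ``signal.stride_sample(rate_multiplier)``, the base-rate acquisition;
    an analog bank consumes the continuous signal directly.  Defaults give
    a 2.5 s segment at 72 bpm and base rate 360 Hz containing three beats
    obscured by noise of RMS comparable to the beat peak.
    """

    fs: float = 360.0
    duration: float = 2.5
    heart_rate_bpm: float = 72.0
    beat_width: float = 0.08   # seconds; keeps template energy below fs/4
    beat_amplitude: float = 1.0
    noise_rms: float = 0.3
    noise_bandwidth_hz: float | None = None
    noise_rolloff_order: int = 2
    rate_multiplier: int = 8
    jitter_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_bandwidth_hz is None:
            object.__setattr__(self, "noise_bandwidth_hz", self.fs / 4.0)
        elif not (0 < self.noise_bandwidth_hz):
            raise ValueError("noise_bandwidth_hz must be positive")
        if self.rate_multiplier < 1 or int(self.rate_multiplier) != self.rate_multiplier:
            raise ValueError("rate_multiplier must be a positive integer")


def _beat_template(t: np.ndarray, width: float, amplitude: float) -> np.ndarray:
    """Biphasic beat: two opposed Gaussian-derivative lobes.

    Lobe widths are QRS-like (millisecond-scale slopes), putting most
    energy below 25 Hz with a tail reaching the 45-90 Hz band at the
    default 360 Hz rate and essentially nothing above fs/4.
    """
    s1 = width / 18.0
    s2 = width / 12.0
    g1 = -(t / s1) * np.exp(-0.5 * (t / s1) ** 2)
    g2 = -((t - 0.25 * width) / s2) * np.exp(-0.5 * ((t - 0.25 * width) / s2) ** 2)
    w = g1 - 0.4 * g2
    return amplitude * w / np.max(np.abs(w))


def synth_ecg(params: EcgSynthParams) -> tuple[Signal, np.ndarray]:
    """Generate the noisy pulse train on the continuous-time stand-in grid.

    Returns ``(signal, beat_times)`` with the signal at
    ``rate_multiplier * fs``; ``signal.stride_sample(rate_multiplier)``
    gives the base-rate acquisition a digital transform would see.
    """
    p = params
    rate = p.fs * p.rate_multiplier
    n = int(round(rate * p.duration))
    if p.duration * p.heart_rate_bpm / 60.0 < 2:
        raise ValueError("duration must cover at least 2 beats")
    rng = np.random.default_rng(p.seed)
    period = 60.0 / p.heart_rate_bpm
    beats = []
    t_beat = 0.35 * period
    while t_beat < p.duration:
        beats.append(t_beat)
        t_beat += period * (1.0 + p.jitter_frac * rng.uniform(-1.0, 1.0))
    beats = np.asarray(beats)

    t = np.arange(n) / rate
    x = np.zeros(n)
    for tb in beats:
        x += _beat_template(t - tb, p.beat_width, p.beat_amplitude)
    if p.noise_rms > 0:
        noise = rng.standard_normal(n)
        if p.noise_bandwidth_hz < rate / 2:
            b, a = scipy.signal.butter(
                p.noise_rolloff_order, p.noise_bandwidth_hz / (rate / 2))
            noise = scipy.signal.lfilter(b, a, noise)
        noise *= p.noise_rms / np.sqrt(np.mean(noise**2))
        x = x + noise
    return Signal(x, rate), beats


# per-state RMS amplitude per band, bands being the four DWT sub-bands of
# 0-25 Hz at fs=100: A4 (0-3.125), D4 (3.125-6.25), D3 (6.25-12.5),
# D2 (12.5-25 Hz).  Sleep is delta-dominated, wake dominated by the upper
# bands, with strictly distinct per-band levels so rank order is testable.
_SLEEP_PROFILE = (5.0, 2.5, 1.5, 1.0)
_WAKE_PROFILE = (1.0, 1.5, 2.5, 3.5)


@dataclass(frozen=True)
class EegSynthParams:
    """Two-state, two-channel EEG-like records.

    Each record alternates wake/sleep states with exponentially distributed
    dwell times (mean ``dwell_mean_s``, truncated below at one 30 s epoch);
    within a state each channel is a sum over the four 0-25 Hz sub-bands of
    band-limited Gaussian noise with the state's per-band RMS.  Bands are
    partitioned spectrally (exact frequency-domain masking of white
    noise), so the realized per-band powers converge to the requested
    profile without cross-band leakage.
    """

    fs: float = 100.0
    n_records: int = 4
    duration: float = 3000.0          # 100 epochs of 30 s per record
    epoch_s: float = 30.0
    dwell_mean_s: float = 300.0
    n_channels: int = 2
    band_edges_hz: tuple = ((0.0, 3.125), (3.125, 6.25), (6.25, 12.5), (12.5, 25.0))
    sleep_profile: tuple = _SLEEP_PROFILE
    wake_profile: tuple = _WAKE_PROFILE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 10 * self.epoch_s:
            raise ValueError("records must span at least 10 epochs")
        if min(min(self.sleep_profile), min(self.wake_profile)) <= 0:
            raise ValueError("band-power profiles must be strictly positive")


@dataclass(frozen=True)
class EegRecord:
    """One generated record: multi-channel signal plus per-epoch labels."""

    signal: Signal
    epoch_labels: np.ndarray  # array of "wake"/"sleep", one per full epoch
    record_id: str


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise confined to [lo, hi) Hz (spectral masking)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < lo) | (f >= hi)] = 0.0
    x = np.fft.irfft(spec, n)
    return x / np.sqrt(np.mean(x**2))


def _state_track(p: EegSynthParams, rng: np.random.Generator, n: int) -> np.ndarray:
    """0/1 state per sample (0 = wake, 1 = sleep), exponential dwell times."""
    state = int(rng.integers(0, 2))
    out = np.empty(n, dtype=np.int8)
    i = 0
    while i < n:
        dwell = max(p.epoch_s, rng.exponential(p.dwell_mean_s))
        j = min(n, i + int(round(dwell * p.fs)))
        out[i:j] = state
        state ^= 1
        i = j
    return out


def synth_eeg(params: EegSynthParams) -> list[EegRecord]:
    """Generate ``n_records`` seeded two-state records with epoch labels."""
    p = params
    n = int(round(p.fs * p.duration))
    records = []
    for r in range(p.n_records):
        rng = np.random.default_rng((p.seed, r))
        states = _state_track(p, rng, n)
        gains = np.empty((2, len(p.band_edges_hz)))
        gains[0] = p.wake_profile
        gains[1] = p.sleep_profile
        chans = []
        for _c in range(p.n_channels):
            x = np.zeros(n)
            for b, (lo, hi) in enumerate(p.band_edges_hz):
                shaped = _band_noise(rng, n, p.fs, lo, hi)
                x += gains[states, b] * shaped
            chans.append(x)
        sig = Signal(np.column_stack(chans), p.fs)
        # label per full epoch by majority occupancy
        spe = int(round(p.epoch_s * p.fs))
        n_epochs = n // spe
        occ = states[: n_epochs * spe].reshape(n_epochs, spe).mean(axis=1)
        labels = np.where(occ >= 0.5, "sleep", "wake")
        records.append(EegRecord(signal=sig, epoch_labels=labels,
                                 record_id=f"rec{r + 1}"))
    return records
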