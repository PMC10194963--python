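"""Morlet-wavelet time-frequency decomposition with dB baseline
normalization.

Power is estimated by convolving each epoch with complex Morlet wavelets
(Gaussian-windowed complex exponentials, SD = cycles / (2*pi*f)) at 13
linearly spaced frequencies from 2 to 26 Hz, with the number of cycles
log-spaced from 3 to 12 across frequencies; convolution is carried out by
frequency-domain multiplication.  Power (squared magnitude of the analytic
signal) is averaged over epochs, then converted to decibels relative to the
mean power over a baseline window spanning the whole trial (-2000..+500 ms
by default): ``dB = 10 * log10(power / baseline)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .infodyn import RoiEpochs

__all__ = ["TFRepresentation", "default_freqs", "default_cycles", "morlet_tfr", "db_normalize"]


def default_freqs() -> np.ndarray:
    """Frequency grid: 2 to 26 Hz in 13 linear steps (2 Hz per bin)."""
    return np.arange(2.0, 27.0, 2.0)


def default_cycles(n: int = 13, lo: float = 3.0, hi: float = 12.0) -> np.ndarray:
    """Wavelet cycle counts, logarithmically spaced from 3 to 12, mapped in
    frequency order."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


@dataclass
class TFRepresentation:
    """Epoch-averaged time-frequency power, frequency x time."""

    power: np.ndarray  # (n_freqs, n_times); linear power or dB
    freqs: np.ndarray
    times: np.ndarray  # ms
    cycles: np.ndarray
    rate: float
    is_db: bool = False
    baseline_window: tuple | None = None
    #: per-frequency count of edge samples (half a wavelet) flagged
    #: unreliable at each epoch boundary (not trimmed).
    n_edge: np.ndarray | None = None


def _morlet(freq: float, cycles: float, rate: float) -> np.ndarray:
    sd = cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(3.5 * sd * rate))
    t = np.arange(-half, half + 1) / rate
    wav = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sd**2))
    return wav / np.abs(wav).sum() * 2.0  # unit gain for a matched sinusoid


def morlet_tfr(
    epochs: RoiEpochs,
    freqs: np.ndarray | None = None,
    cycles: np.ndarray | None = None,
) -> TFRepresentation:
    """Time-frequency power of ROI epochs via complex Morlet convolution
    (frequency-domain multiplication), averaged over epochs."""
    freqs = default_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    cycles = default_cycles(freqs.size) if cycles is None else np.asarray(cycles, dtype=float)
    if freqs.size != cycles.size:
        raise ValueError("freqs and cycles must have the same length")
    n_t = epochs.values.shape[1]
    min_len = 3.0 * epochs.rate / freqs.min()
    if n_t < min_len:
        raise ValueError("epoch too short for the lowest frequency (need >= 3 cycles)")
    power = np.empty((freqs.size, n_t))
    n_edge = np.empty(freqs.size, dtype=int)
    for i, (f, c) in enumerate(zip(freqs, cycles)):
        wav = _morlet(f, c, epochs.rate)
        n_edge[i] = (wav.size - 1) // 2
        z = fftconvolve(epochs.values, wav[None, :], mode="same", axes=1)
        power[i] = (z.real**2 + z.imag**2).mean(axis=0)
    return TFRepresentation(
        power=power,
        freqs=freqs,
        times=epochs.times.copy(),
        cycles=cycles,
        rate=epochs.rate,
        n_edge=n_edge,
    )


def db_normalize(tfr: TFRepresentation, baseline_window: tuple | None = None) -> TFRepresentation:
    """Per frequency, decibels relative to mean power over the baseline
    window (default: the whole epoch)."""
    if tfr.is_db:
        raise ValueError("TFR already dB-normalized")
    if baseline_window is None:
        mask = np.ones(tfr.times.size, dtype=bool)
        baseline_window = (float(tfr.times[0]), float(tfr.times[-1]))
    else:
        mask = (tfr.times >= baseline_window[0]) & (tfr.times <= baseline_window[1])
        if not mask.any():
            raise ValueError("baseline window contains no samples")
    base = tfr.power[:, mask].mean(axis=1)
    if np.any(base <= 0):
        raise ValueError("nonpositive baseline power")
    db = 10.0 * np.log10(tfr.power / base[:, None])
    return TFRepresentation(
        power=db,
        freqs=tfr.freqs.copy(),
        times=tfr.times.copy(),
        cycles=tfr.cycles.copy(),
        rate=tfr.rate,
        is_db=True,
        baseline_window=baseline_window,
        n_edge=None if tfr.n_edge is None else tfr.n_edge.copy(),
    )
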