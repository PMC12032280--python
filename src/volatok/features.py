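"""Signal conditioning and feature extraction for the EEG analyses.

Implements the spectral recipe used throughout: sliding-window Fourier
power with a Hanning taper (0.4 s window, 0.005 s steps, 1 Hz frequency
grid), decibel conversion against the trial-averaged pre-trial baseline,
the motor beta lateralisation (MBL) index (left minus right hemispheric
13-30 Hz dB power), two-pass Butterworth filtering, and sample-locked
epoching (including the first-100-ms scalar used by the motor-update
analysis).

STFT windows are centred; time points whose window would run off either
edge of the epoch are emitted as NaN rather than zero-padded, which keeps
the pre-trial dB baseline unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as spsig
from scipy.fft import next_fast_len

__all__ = [
    "TFR",
    "stft_power",
    "db_baseline",
    "mbl_index",
    "butterworth",
    "epoch_samples",
    "sample_scalars",
]


@dataclass
class TFR:
    """Time-frequency power: (..., n_freqs, n_times) over the epoch grid."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    is_db: bool = False
    baseline_window: tuple[float, float] | None = None


def stft_power(data: np.ndarray, fs: float, window: float = 0.4,
               step: float = 0.005, freqs=None,
               times: np.ndarray | None = None) -> TFR:
    """Hanning-taper sliding-window Fourier power.

    ``data``: (..., n_times).  ``freqs`` defaults to the 1..35 Hz grid in
    1 Hz steps; restrict it (e.g. to the beta band) to save work.  The hop
    is ``round(step * fs)`` samples.  Power is normalised so a unit-amplitude
    sinusoid at a grid frequency yields power 1 at that bin (squared
    amplitude); only power ratios matter downstream.
    """
    data = np.asarray(data, dtype=float)
    n_t = data.shape[-1]
    n_win = round(window * fs)
    if n_win > n_t:
        raise ValueError("data shorter than the analysis window")
    hop = round(step * fs)
    if hop < 1:
        raise ValueError(f"step {step} is below the sample interval")
    if freqs is None:
        freqs = np.arange(1.0, 36.0)
    freqs = np.asarray(freqs, dtype=float)

    taper = spsig.get_window("hann", n_win, fftbins=True)
    taper_sum = taper.sum()
    nfft = next_fast_len(n_t + n_win)
    data_f = np.fft.fft(data, n=nfft, axis=-1)

    half = n_win // 2
    out_idx = np.arange(0, n_t, hop)
    power = np.empty(data.shape[:-1] + (len(freqs), len(out_idx)))
    t_rel = np.arange(n_win) / fs
    for fi, f in enumerate(freqs):
        kern = taper * np.exp(-2j * np.pi * f * t_rel)
        kern_f = np.fft.fft(kern[::-1].conj(), n=nfft)
        conv = np.fft.ifft(data_f * kern_f, axis=-1)
        # centre-aligned: window centred on sample k ends at k + n_win - half
        centred = conv[..., (n_win - 1 - half):(n_win - 1 - half) + n_t]
        power[..., fi, :] = np.abs(centred[..., out_idx] / taper_sum * 2.0) ** 2

    # mark incomplete-window edges missing
    valid = (out_idx >= half) & (out_idx <= n_t - (n_win - half))
    power[..., ~valid] = np.nan

    if times is None:
        times = np.arange(n_t) / fs
    return TFR(power=power, freqs=freqs, times=np.asarray(times)[out_idx])


def db_baseline(tfr: TFR, baseline_window: tuple[float, float] = (-0.1, 0.0)) -> TFR:
    """Decibel transform against the trial-averaged baseline power.

    Baseline = power averaged over the baseline window *and* across trials
    (axis 0), per channel and frequency; output is 10*log10(power/baseline).
    """
    if tfr.is_db:
        raise ValueError("TFR is already in dB")
    lo, hi = baseline_window
    sel = (tfr.times >= lo) & (tfr.times <= hi)
    if not sel.any():
        raise ValueError("baseline window lies outside the epoch")
    base = np.nanmean(tfr.power[..., sel], axis=(0, -1), keepdims=True)
    if np.any(base <= 0):
        raise ValueError("baseline power must be positive")
    power_db = 10.0 * np.log10(tfr.power / base)
    return TFR(power=power_db, freqs=tfr.freqs, times=tfr.times,
               is_db=True, baseline_window=baseline_window)


def mbl_index(tfr_db: TFR, left_channels, right_channels,
              band: tuple[float, float] = (13.0, 30.0)) -> np.ndarray:
    """Motor beta lateralisation: left minus right band-averaged dB power.

    ``tfr_db.power`` must be (trials, channels, freqs, times); returns
    (trials, times).  Band endpoints are inclusive on the frequency grid.
    """
    if not tfr_db.is_db:
        raise ValueError("mbl_index expects dB-transformed power")
    left = np.asarray(left_channels, dtype=int)
    right = np.asarray(right_channels, dtype=int)
    if len(left) == 0 or len(right) == 0:
        raise ValueError("channel groups must be non-empty")
    if np.intersect1d(left, right).size:
        raise ValueError("channel groups must be disjoint")
    n_ch = tfr_db.power.shape[1]
    if left.max() >= n_ch or right.max() >= n_ch:
        raise ValueError("unknown channel index")
    fsel = (tfr_db.freqs >= band[0]) & (tfr_db.freqs <= band[1])
    if not fsel.any():
        raise ValueError("band contains no grid frequencies")
    band_pow = tfr_db.power[:, :, fsel, :].mean(axis=2)
    return band_pow[:, left].mean(axis=1) - band_pow[:, right].mean(axis=1)


def butterworth(data: np.ndarray, fs: float, kind: str, cutoff: float,
                order: int = 3) -> np.ndarray:
    """Zero-phase (two-pass) Butterworth filter along the last axis."""
    if kind not in ("low", "high"):
        raise ValueError(f"kind must be 'low' or 'high', got {kind!r}")
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2), got {cutoff}")
    sos = spsig.butter(order, cutoff, btype=kind, fs=fs, output="sos")
    return spsig.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def _onset_indices(times: np.ndarray, onsets_s: np.ndarray, fs: float) -> np.ndarray:
    idx = np.round((np.asarray(onsets_s) - times[0]) * fs).astype(int)
    if idx.min() < 0 or idx.max() >= len(times):
        raise ValueError("sample onset outside the epoch")
    return idx


def epoch_samples(data: np.ndarray, times: np.ndarray, onsets_s, fs: float,
                  window: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """Sample-locked slices: (..., n_samples, n_window) from (..., n_times).

    ``onsets_s`` are onset times on the epoch clock (seconds).  The window
    is [window[0], window[1]) relative to each onset.
    """
    data = np.asarray(data)
    idx = _onset_indices(times, onsets_s, fs)
    a = round(window[0] * fs)
    b = round(window[1] * fs)
    if idx.min() + a < 0 or idx.max() + b > data.shape[-1]:
        raise ValueError("sample window extends outside the epoch")
    out = np.stack([data[..., i + a:i + b] for i in idx], axis=-2)
    return out


def sample_scalars(data: np.ndarray, times: np.ndarray, onsets_s, fs: float,
                   window: tuple[float, float] = (0.0, 0.1)) -> np.ndarray:
    """Per-sample scalar: mean over a short post-onset window.

    With the default window this is the first-100-ms mean feeding the
    motor-update (delta-MBL) analysis; returns (..., n_samples).
    """
    return np.nanmean(epoch_samples(data, times, onsets_s, fs, window), axis=-1)
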