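"""Band-pass filtering and per-trial spectral band-power features.

Each 5-s task period is summarised by the spectral power in 1-Hz bands from
0--1 Hz up to 29--30 Hz on every electrode: 30 bands x 15 electrodes = 450
features. Power in a band is the sum of squared DFT coefficients whose
frequency falls in the half-open interval [b, b+1) Hz, scaled so that the
sum of all coefficient powers equals the mean square of the signal
(Parseval). The DC coefficient is excluded, so summing every band plus the
above-30-Hz residual recovers the population variance of the trace.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

N_BANDS = 30


def bandpass(signal: np.ndarray, low: float, high: float, rate: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective
    order and cancels phase distortion, which matters because band powers
    are computed on the filtered trace.
    """
    if not (0 < low < high < rate / 2):
        raise ValueError(f"band edges must satisfy 0 < {low} < {high} < {rate / 2}")
    sos = butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)


def dft_coefficient_powers(signal: np.ndarray, rate: float):
    """Per-coefficient power spectrum of a real signal (last axis).

    Returns ``(freqs, powers)`` where ``powers[..., k]`` is the mean-square
    contribution of the k-th rfft coefficient: ``sum_k powers[..., k] ==
    mean(signal**2)`` exactly (one-sided scaling; DC and Nyquist unhalved).
    """
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    X = np.fft.rfft(x, axis=-1)
    p = (np.abs(X) ** 2) * (2.0 / n ** 2)
    p[..., 0] /= 2.0
    if n % 2 == 0:
        p[..., -1] /= 2.0
    return np.fft.rfftfreq(n, d=1.0 / rate), p


def band_powers(signal: np.ndarray, rate: float, n_bands: int = N_BANDS) -> np.ndarray:
    """Sum coefficient powers into half-open 1-Hz bands [b, b+1), b < n_bands.

    The DC coefficient is excluded from band 0. Input may be (samples,) or
    (channels, samples); output gains a trailing ``n_bands`` axis.
    """
    x = np.asarray(signal, dtype=float)
    if x.shape[-1] < rate:  # need >= 1 s for 1-Hz frequency resolution
        raise ValueError("trial shorter than 1 s: frequency resolution coarser than band width")
    if rate < 64:
        raise ValueError("sampling rate below 64 Hz not supported")
    freqs, p = dft_coefficient_powers(x, rate)
    bands = np.floor(freqs).astype(int)
    valid = (bands >= 0) & (bands < n_bands)
    valid[0] = False  # drop DC
    sel = p[..., valid]
    idx = bands[valid]
    out = np.zeros(x.shape[:-1] + (n_bands,))
    for b in range(n_bands):
        mask = idx == b
        if mask.any():
            out[..., b] = sel[..., mask].sum(axis=-1)
    return out


def extract_band_powers(signal: np.ndarray, rate: float,
                        n_bands: int = N_BANDS) -> np.ndarray:
    """Flatten a (channels, samples) trial into the electrode-major feature
    vector: index = electrode * n_bands + band."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (channels, samples) matrix")
    return band_powers(x, rate, n_bands).ravel()


def feature_names(n_channels: int, n_bands: int = N_BANDS) -> list:
    """Column names in electrode-major, band-minor order: E1_B0 ... E15_B29."""
    return [f"E{e + 1}_B{b}" for e in range(n_channels) for b in range(n_bands)]


def feature_matrix(trials: Sequence, rate: float,
                   filter_band: tuple = (2.0, 30.0)) -> pd.DataFrame:
    """Band-power feature table for a list of trials.

    Signals are band-pass filtered (default 2--30 Hz) before power
    extraction; bands 0 and 1 Hz are therefore attenuated but retained so
    the feature vector keeps its fixed 450-column layout.
    """
    if not trials:
        raise ValueError("no trials given")
    sig = np.stack([t.signal for t in trials])  # (n, channels, samples)
    if filter_band is not None:
        sig = bandpass(sig, filter_band[0], filter_band[1], rate)
    powers = band_powers(sig, rate)              # (n, channels, bands)
    n, c, b = powers.shape
    return pd.DataFrame(powers.reshape(n, c * b), columns=feature_names(c, b))
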