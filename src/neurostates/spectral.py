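"""LFP epoching, per-epoch band power, delta amplitude, high-delta rule."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InvalidInputError, InvalidParameterError

#: Band definitions in Hz; edges are half-open [lo, hi).
BANDS = {
    "delta": (0.5, 4.0),
    "gamma": (40.0, 60.0),
    "high_gamma": (60.0, 150.0),
}

DEFAULT_EPOCH_LENGTH = 0.5


@dataclass
class EpochedLfp:
    """Epochs x channels x samples, demeaned per epoch."""

    data: np.ndarray
    fs: float
    epoch_length: float

    @property
    def n_epochs(self):
        return self.data.shape[0]

    @property
    def n_channels(self):
        return self.data.shape[1]


def epoch_signal(
    lfp: np.ndarray, fs: float, epoch_length: float = DEFAULT_EPOCH_LENGTH
) -> EpochedLfp:
    """Cut a (samples x channels) signal into non-overlapping epochs.

    The trailing partial epoch is dropped and each epoch is demeaned.
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.ndim == 1:
        lfp = lfp[:, None]
    per = int(round(epoch_length * fs))
    if per < 8:
        raise InvalidParameterError("epoch must contain at least 8 samples")
    n = lfp.shape[0]
    if n < per:
        raise InvalidInputError(
            f"signal of {n} samples shorter than one epoch ({per} samples)"
        )
    n_ep = n // per
    cut = lfp[: n_ep * per].reshape(n_ep, per, lfp.shape[1])
    cut = np.transpose(cut, (0, 2, 1))  # epochs x channels x samples
    cut = cut - cut.mean(axis=2, keepdims=True)
    return EpochedLfp(data=cut, fs=fs, epoch_length=epoch_length)


def band_power(
    epoched: EpochedLfp, band, window: str = "hann"
) -> np.ndarray:
    """Mean periodogram power in ``band`` per epoch and channel (mV^2/Hz).

    Named bands from :data:`BANDS` or an explicit (f_lo, f_hi) pair; bins
    satisfy f_lo <= f < f_hi.
    """
    if isinstance(band, str):
        band = BANDS[band]
    f_lo, f_hi = band
    if f_hi > epoched.fs / 2 + 1e-9:
        raise InvalidParameterError(
            f"band edge {f_hi} Hz above Nyquist {epoched.fs / 2} Hz"
        )
    freqs, pxx = sps.periodogram(
        epoched.data, fs=epoched.fs, window=window, axis=-1, detrend=False
    )
    sel = (freqs >= f_lo) & (freqs < f_hi)
    if not sel.any():
        raise InvalidParameterError(
            f"band ({f_lo}, {f_hi}) Hz contains no FFT bin at "
            f"resolution {freqs[1] - freqs[0]:.3g} Hz"
        )
    return pxx[..., sel].mean(axis=-1)


def band_power_table(epoched: EpochedLfp, bands=None) -> dict:
    """All named bands at once: {band: (epochs x channels)}."""
    bands = BANDS if bands is None else bands
    return {name: band_power(epoched, edges) for name, edges in bands.items()}


def delta_amplitude(
    lfp: np.ndarray,
    fs: float,
    epoch_length: float = DEFAULT_EPOCH_LENGTH,
    band=BANDS["delta"],
) -> np.ndarray:
    """Mean delta-band Hilbert envelope per epoch and channel (mV).

    Filtering and the analytic signal are computed on the continuous signal
    before epoch slicing so epoch edges carry no filter transients.
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.ndim == 1:
        lfp = lfp[:, None]
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, lfp, axis=0)
    envelope = np.abs(sps.hilbert(filtered, axis=0))
    per = int(round(epoch_length * fs))
    n_ep = lfp.shape[0] // per
    env = envelope[: n_ep * per].reshape(n_ep, per, lfp.shape[1])
    return env.mean(axis=1)


def high_delta_epochs(delta_amp: np.ndarray):
    """Boolean mask of epochs above the mid-range threshold.

    threshold = min + (max - min) / 2 over the session's per-epoch
    amplitudes; the mask is strict (amplitude > threshold), so constant
    sessions select nothing.
    """
    amp = np.asarray(delta_amp, dtype=float)
    if amp.ndim != 1:
        raise InvalidInputError("high_delta_epochs expects one channel's amplitudes")
    if amp.size < 2:
        raise InvalidInputError("need at least 2 epochs")
    threshold = amp.min() + (amp.max() - amp.min()) / 2.0
    return amp > threshold, float(threshold)
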