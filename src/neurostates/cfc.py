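"""Delta-phase -> gamma-amplitude cross-frequency coupling.

Phase convention: angle 0 at the low-band wave peak, +/-pi at the trough
(cosine convention).  The coupling vector is the amplitude-weighted circular
mean of the phase series; its modulus lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InvalidInputError, InvalidParameterError
from .spectral import BANDS

EDGE_TRIM_FRACTION = 0.05  # discarded from each end after filtering
MIN_RELIABLE_SECONDS = 2.0


@dataclass
class CfcVector:
    """Coupling strength in [0, 1] and preferred angle in (-pi, pi]."""

    strength: float
    angle: float
    n_samples: int
    reliable: bool = True


def bandpass(x, band, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise InvalidParameterError(
            f"band ({lo}, {hi}) Hz invalid for fs={fs} Hz"
        )
    sos = sps.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def analytic_phase_amplitude(filtered_low, filtered_high, trim: float = EDGE_TRIM_FRACTION):
    """Hilbert phase of the low band and Hilbert envelope of the high band.

    The edge ``trim`` fraction of samples is discarded from both ends of
    both series to suppress filter/Hilbert transients.
    """
    low = np.asarray(filtered_low, dtype=float)
    high = np.asarray(filtered_high, dtype=float)
    if low.shape != high.shape:
        raise InvalidInputError("low and high band series must share shape")
    phase = np.angle(sps.hilbert(low, axis=0))
    amplitude = np.abs(sps.hilbert(high, axis=0))
    k = int(round(trim * low.shape[0]))
    if k:
        phase, amplitude = phase[k:-k], amplitude[k:-k]
    return phase, amplitude


def cfc_vector(phase, amplitude, weight: str = "amplitude") -> CfcVector:
    """Amplitude-weighted circular mean: v = sum a * e^{i phi} / sum a."""
    phase = np.asarray(phase, dtype=float).ravel()
    amplitude = np.asarray(amplitude, dtype=float).ravel()
    if phase.size != amplitude.size:
        raise InvalidInputError("phase and amplitude length mismatch")
    if weight == "power":
        amplitude = amplitude**2
    elif weight != "amplitude":
        raise InvalidParameterError(f"unknown weight {weight!r}")
    total = amplitude.sum()
    if total <= 0:
        raise InvalidInputError("all-zero amplitude; coupling vector undefined")
    v = np.sum(amplitude * np.exp(1j * phase)) / total
    return CfcVector(
        strength=float(np.abs(v)), angle=float(np.angle(v)), n_samples=phase.size
    )


def cfc_by_state(
    lfp,
    state_per_sample,
    fs: float,
    low_band=BANDS["delta"],
    high_band=BANDS["gamma"],
    weight: str = "amplitude",
    order: int = 4,
):
    """Per-state coupling vectors for one channel.

    Filtering and the analytic transform run on the continuous signal first;
    samples are pooled by state afterwards.  States with under
    ``MIN_RELIABLE_SECONDS`` of data are flagged unreliable, not errors.
    """
    x = np.asarray(lfp, dtype=float).ravel()
    states = np.asarray(state_per_sample)
    if states.size != x.size:
        raise InvalidInputError("state mask must align to samples")
    low = bandpass(x, low_band, fs, order)
    high = bandpass(x, high_band, fs, order)
    phase, amplitude = analytic_phase_amplitude(low, high)
    k = (states.size - phase.size) // 2
    states = states[k:k + phase.size]
    out = {}
    for s in np.unique(states):
        sel = states == s
        vec = cfc_vector(phase[sel], amplitude[sel], weight=weight)
        vec.reliable = sel.sum() / fs >= MIN_RELIABLE_SECONDS
        out[int(s)] = vec
    return out
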