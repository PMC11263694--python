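"""Ground-truth simulator.

Generates a latent 3-state behavioral chain, symbol streams, paired
movement-sensor series, and multichannel LFP with planted band content,
inter-channel VAR coupling and delta-phase -> gamma-amplitude coupling, so
every downstream stage can be tested against known parameters.

Seeding: every operation takes one integer seed that is expanded into
independent child streams by the fixed scheme in :mod:`neurostates._seeds`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from ._seeds import child_rng
from .errors import InvalidInputError, InvalidParameterError
from .segmentation import HMMParams, SymbolSequence, _check_stochastic

DEFAULT_CHANNELS = ("VP", "MD", "AC", "V1")


@dataclass
class LatentStateSequence:
    """Hidden behavioral states, values in {1, 2, 3}."""

    states: np.ndarray
    step_duration: float = 0.5

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.size < 1:
            raise InvalidInputError("state sequence must be non-empty")
        if self.states.min() < 1:
            raise InvalidInputError("states are 1-based")

    def __len__(self):
        return self.states.size


@dataclass
class SensorProfile:
    """Per-state location/dispersion of the two sensors on a positive scale.

    Values are drawn log-normally: ``exp(Normal(log(mean), dispersion))``,
    so ``mean`` is the per-state median and ``dispersion`` the log-scale sd.
    Zero dispersion collapses to the per-state median exactly.
    """

    acl_mean: np.ndarray
    acl_dispersion: np.ndarray
    dlc_mean: np.ndarray
    dlc_dispersion: np.ndarray

    def __post_init__(self):
        for name in ("acl_mean", "acl_dispersion", "dlc_mean", "dlc_dispersion"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.acl_mean <= 0) or np.any(self.dlc_mean <= 0):
            raise InvalidParameterError("sensor means must be positive")
        if np.any(self.acl_dispersion < 0) or np.any(self.dlc_dispersion < 0):
            raise InvalidParameterError("dispersions must be >= 0")


def default_sensor_profile() -> SensorProfile:
    """Profile whose median-split approximates the example emissions:
    state 1 low on both sensors, state 2 high ACL / low DLC, state 3 high
    on both."""
    return SensorProfile(
        acl_mean=np.array([0.05, 1.2, 1.0]),
        acl_dispersion=np.array([0.4, 0.5, 0.6]),
        dlc_mean=np.array([0.5, 2.0, 30.0]),
        dlc_dispersion=np.array([0.5, 0.8, 0.8]),
    )


@dataclass
class LfpProfile:
    """Planted oscillatory structure for the LFP generator.

    Band amplitudes are per state (mV); PAC strength is per state and PAC
    preferred angle per channel; ``var_coefficients`` (lags x ch x ch) and
    ``noise_cov`` define the coupled innovation process.
    """

    channels: tuple = DEFAULT_CHANNELS
    delta_amp: np.ndarray = field(default_factory=lambda: np.array([2.0, 0.6, 0.4]))
    gamma_amp: np.ndarray = field(default_factory=lambda: np.array([0.1, 0.8, 0.4]))
    high_gamma_amp: np.ndarray = field(default_factory=lambda: np.array([0.05, 0.4, 0.2]))
    pac_strength: np.ndarray = field(default_factory=lambda: np.array([0.1, 0.8, 0.4]))
    pac_angle: np.ndarray | None = None
    delta_freq: float = 2.0
    noise_level: float = 0.05
    var_coefficients: np.ndarray | None = None
    noise_cov: np.ndarray | None = None

    def __post_init__(self):
        n_ch = len(self.channels)
        for name in ("delta_amp", "gamma_amp", "high_gamma_amp", "pac_strength"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if np.any(getattr(self, name) < 0):
                raise InvalidParameterError(f"{name} must be >= 0")
        if np.any(self.pac_strength > 1):
            raise InvalidParameterError("pac_strength must lie in [0, 1]")
        if self.pac_angle is None:
            self.pac_angle = np.full(n_ch, -np.pi / 4)
        self.pac_angle = np.asarray(self.pac_angle, dtype=float)
        if self.var_coefficients is None:
            self.var_coefficients = np.zeros((1, n_ch, n_ch))
        self.var_coefficients = np.asarray(self.var_coefficients, dtype=float)
        if self.noise_cov is None:
            self.noise_cov = np.eye(n_ch) * 0.05**2
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise InvalidParameterError("noise_cov must be symmetric")
        if np.any(np.linalg.eigvalsh(self.noise_cov) <= 0):
            raise InvalidParameterError("noise_cov must be positive definite")
        if var_spectral_radius(self.var_coefficients) >= 1.0:
            raise InvalidParameterError(
                "var_coefficients define an unstable VAR (spectral radius >= 1)"
            )


def var_spectral_radius(coefs: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix."""
    coefs = np.asarray(coefs, dtype=float)
    p, n, _ = coefs.shape
    companion = np.zeros((n * p, n * p))
    for k in range(p):
        companion[:n, k * n:(k + 1) * n] = coefs[k]
    if p > 1:
        companion[n:, :-n] = np.eye(n * (p - 1))
    return float(np.abs(np.linalg.eigvals(companion)).max())


# ---------------------------------------------------------------------------
# latent chain and symbols
# ---------------------------------------------------------------------------

def simulate_state_sequence(
    params: HMMParams, n_steps: int, seed: int = 0
) -> LatentStateSequence:
    """Sample a Markov chain from ``params.pi`` and ``params.A``."""
    if n_steps < 1:
        raise InvalidParameterError("n_steps must be >= 1")
    _check_stochastic(params.A, "transition matrix")
    rng = child_rng(seed, "states")
    n_states = params.n_states
    # inverse-CDF sampling against one uniform per step (bit-reproducible)
    cum_pi = np.cumsum(params.pi)
    cum_A = np.cumsum(params.A, axis=1)
    u = rng.random(n_steps)
    states = np.empty(n_steps, dtype=np.int64)
    states[0] = np.searchsorted(cum_pi, u[0], side="right")
    for t in range(1, n_steps):
        states[t] = np.searchsorted(cum_A[states[t - 1]], u[t], side="right")
    states = np.minimum(states, n_states - 1)
    return LatentStateSequence(states + 1)


def simulate_symbols(
    states: LatentStateSequence, emission: np.ndarray, seed: int = 0
) -> SymbolSequence:
    """Draw one output symbol per step from the current state's emission row."""
    emission = np.asarray(emission, dtype=float)
    _check_stochastic(emission, "emission matrix")
    rng = child_rng(seed, "symbols")
    idx = states.states - 1
    cum = np.cumsum(emission, axis=1)
    u = rng.random(len(states))
    codes = np.empty(len(states), dtype=np.int64)
    for s in range(emission.shape[0]):
        sel = idx == s
        codes[sel] = np.searchsorted(cum[s], u[sel], side="right")
    codes = np.minimum(codes, emission.shape[1] - 1)
    return SymbolSequence(codes, step_duration=states.step_duration)


# ---------------------------------------------------------------------------
# sensors
# ---------------------------------------------------------------------------

def simulate_sensors(
    states: LatentStateSequence, profile: SensorProfile, seed: int = 0
):
    """Per-step positive ACL and DLC draws conditioned on the hidden state.

    Returns a pair of value arrays aligned to the state steps.  With
    per-state medians well separated around the session medians, the
    downstream median split reproduces the product-form emission structure
    implied by the profile.
    """
    rng = child_rng(seed, "sensors")
    idx = states.states - 1
    z = rng.standard_normal((len(states), 2))
    acl = np.exp(
        np.log(profile.acl_mean[idx]) + profile.acl_dispersion[idx] * z[:, 0]
    )
    dlc = np.exp(
        np.log(profile.dlc_mean[idx]) + profile.dlc_dispersion[idx] * z[:, 1]
    )
    return acl, dlc


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _pink_noise(rng, n, n_ch):
    """1/f-amplitude noise with unit variance per channel."""
    white = rng.standard_normal((n, n_ch))
    spec = np.fft.rfft(white, axis=0)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale[:, None], n=n, axis=0)
    sd = out.std(axis=0)
    sd[sd == 0] = 1.0
    return out / sd


def _var_process(rng, coefs, noise_cov, n):
    """Simulate a stable VAR with Gaussian innovations; burn-in discarded."""
    p, n_ch, _ = coefs.shape
    burn = 10 * p + 100
    chol = np.linalg.cholesky(noise_cov)
    eps = rng.standard_normal((n + burn, n_ch)) @ chol.T
    x = np.zeros((n + burn, n_ch))
    for t in range(p, n + burn):
        acc = eps[t].copy()
        for k in range(p):
            acc += coefs[k] @ x[t - k - 1]
        x[t] = acc
    return x[burn:]


def _bandlimited_carrier(rng, n, n_ch, fs, band):
    """Unit-RMS Gaussian noise band-passed to ``band``."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal((n, n_ch)), axis=0)
    rms = np.sqrt(np.mean(x**2, axis=0))
    rms[rms == 0] = 1.0
    return x / rms


def simulate_lfp(
    states: LatentStateSequence,
    profile: LfpProfile,
    fs: float = 400.0,
    seed: int = 0,
) -> np.ndarray:
    """Multichannel LFP (samples x channels, mV) with known ground truth.

    Each channel sums: the VAR-coupled innovation process, a per-state delta
    sinusoid with phase continuous across state boundaries, a band-limited
    gamma carrier whose envelope is ``(1 + s*cos(phi_delta - pac_angle)) /
    (1 + s)`` scaled by the state gamma amplitude, a high-gamma carrier, and
    1/f background noise.
    """
    if fs <= 2 * 150.0:
        raise InvalidParameterError(f"fs={fs} must exceed 300 Hz (2 x 150 Hz)")
    rng = child_rng(seed, "lfp")
    n_ch = len(profile.channels)
    spc = int(round(states.step_duration * fs))
    n = len(states) * spc
    state_per_sample = np.repeat(states.states, spc) - 1

    t = np.arange(n) / fs
    delta_phase = 2 * np.pi * profile.delta_freq * t  # continuous ramp
    delta = profile.delta_amp[state_per_sample, None] * np.cos(delta_phase)[:, None]

    gamma_carrier = _bandlimited_carrier(rng, n, n_ch, fs, (40.0, 60.0))
    s = profile.pac_strength[state_per_sample, None]
    envelope = (1.0 + s * np.cos(delta_phase[:, None] - profile.pac_angle[None, :])) / (
        1.0 + s
    )
    gamma = profile.gamma_amp[state_per_sample, None] * envelope * gamma_carrier

    hg_carrier = _bandlimited_carrier(rng, n, n_ch, fs, (60.0, 150.0))
    high_gamma = profile.high_gamma_amp[state_per_sample, None] * hg_carrier

    coupled = _var_process(rng, profile.var_coefficients, profile.noise_cov, n)
    background = profile.noise_level * _pink_noise(rng, n, n_ch)

    return delta + gamma + high_gamma + coupled + background


# ---------------------------------------------------------------------------
# on-disk formats (shared with the pipeline)
# ---------------------------------------------------------------------------

def write_sensor_csv(path, acl, dlc, states: LatentStateSequence) -> None:
    """step_index, acl, dlc, true_state CSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("step_index,acl,dlc,true_state\n")
        for i, (a, d, s) in enumerate(zip(acl, dlc, states.states)):
            fh.write(f"{i},{a:.9g},{d:.9g},{s}\n")


def write_lfp(path_prefix, lfp: np.ndarray, fs: float, channels=DEFAULT_CHANNELS) -> None:
    """Raw little-endian float32 (sample-major) plus a JSON sidecar."""
    prefix = Path(path_prefix)
    lfp.astype("<f4").tofile(prefix.with_suffix(".f32"))
    sidecar = {
        "channels": list(channels),
        "fs_hz": fs,
        "n_samples": int(lfp.shape[0]),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_lfp(path_prefix):
    """Inverse of :func:`write_lfp`; returns (lfp, fs, channels)."""
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    raw = np.fromfile(prefix.with_suffix(".f32"), dtype="<f4")
    n_ch = len(meta["channels"])
    lfp = raw.reshape(meta["n_samples"], n_ch).astype(float)
    return lfp, float(meta["fs_hz"]), tuple(meta["channels"])
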