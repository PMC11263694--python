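"""Pose-table and accelerometer ingestion.

Reads the 3-header-row pose-tracking CSV dialect (scorer / bodyparts /
coords), derives nose speed, computes high-passed accelerometer magnitude,
and reduces both to a common step timebase.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import FormatError, InvalidInputError, InvalidParameterError

_COORDS = ("x", "y", "likelihood")


@dataclass
class PoseTrack:
    """Per-frame body-part coordinates with network likelihoods."""

    data: pd.DataFrame  # columns: MultiIndex (bodypart, coord)
    fps: float = 2.0
    scorer: str = "scorer"

    @property
    def bodyparts(self):
        return tuple(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def n_frames(self) -> int:
        return len(self.data)


@dataclass
class SensorSeries:
    """Uniformly sampled non-negative movement signal."""

    values: np.ndarray
    dt: float
    origin_time: float = 0.0
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if np.any(~np.isfinite(self.values)):
            raise InvalidInputError("sensor series contains non-finite values")

    def __len__(self):
        return self.values.size

    @property
    def times(self):
        return self.origin_time + np.arange(self.values.size) * self.dt


def read_pose_table(path) -> PoseTrack:
    """Parse a pose-table CSV (scorer / bodyparts / coords header rows).

    Every body part must carry x, y and likelihood columns; the frame count
    of the file is preserved.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: not a 3-header-row pose table ({exc})") from exc
    if df.columns.nlevels != 3:
        raise FormatError(f"{path}: expected scorer/bodyparts/coords header rows")
    scorer = df.columns.get_level_values(0)[0]
    # drop the scorer level; validate per-bodypart coord triplets
    df.columns = pd.MultiIndex.from_arrays(
        [df.columns.get_level_values(1), df.columns.get_level_values(2)]
    )
    for bp in dict.fromkeys(df.columns.get_level_values(0)):
        coords = tuple(df[bp].columns)
        missing = [c for c in _COORDS if c not in coords]
        if missing:
            raise FormatError(
                f"{path}: bodypart {bp!r} missing coordinate column(s) {missing}"
            )
        lik = df[(bp, "likelihood")].to_numpy(float)
        if np.any((lik < 0) | (lik > 1)):
            raise FormatError(f"{path}: likelihood outside [0, 1] for {bp!r}")
    return PoseTrack(data=df.astype(float), scorer=str(scorer))


def write_pose_table(path, track: PoseTrack) -> None:
    """Write a PoseTrack back to the 3-header-row CSV dialect."""
    df = track.data.copy()
    df.columns = pd.MultiIndex.from_arrays(
        [
            [track.scorer] * df.shape[1],
            df.columns.get_level_values(0),
            df.columns.get_level_values(1),
        ],
        names=["scorer", "bodyparts", "coords"],
    )
    df.to_csv(path, index_label=None)


def _interpolate_low_likelihood(x, y, lik, likelihood_min):
    good = lik >= likelihood_min
    if not good.any():
        raise InvalidInputError(
            "all frames fall below the likelihood threshold; track unusable"
        )
    idx = np.arange(x.size)
    xi = np.interp(idx, idx[good], x[good])
    yi = np.interp(idx, idx[good], y[good])
    return xi, yi


def compute_speed(
    track: PoseTrack,
    bodypart: str = "nose",
    likelihood_min: float = 0.9,
    fps: float | None = None,
) -> SensorSeries:
    """Frame-to-frame speed of one body part in px/s.

    Low-likelihood frames are linearly interpolated from the nearest
    confident neighbors before differencing; the first speed value is
    duplicated so the series length matches the frame count.
    """
    if bodypart not in track.bodyparts:
        raise InvalidInputError(
            f"bodypart {bodypart!r} not in track ({track.bodyparts})"
        )
    if track.n_frames < 2:
        raise InvalidInputError("need at least 2 frames to compute speed")
    fps = track.fps if fps is None else fps
    x = track.data[(bodypart, "x")].to_numpy(float)
    y = track.data[(bodypart, "y")].to_numpy(float)
    lik = track.data[(bodypart, "likelihood")].to_numpy(float)
    x, y = _interpolate_low_likelihood(x, y, lik, likelihood_min)
    dist = np.hypot(np.diff(x), np.diff(y))
    speed = np.concatenate(([dist[0]], dist)) * fps
    return SensorSeries(values=speed, dt=1.0 / fps, units="px/s")


def accel_magnitude(
    xyz: np.ndarray, fs: float = 400.0, highpass_hz: float = 1.0
) -> SensorSeries:
    """Gravity-free movement magnitude from a 3-axis accelerometer.

    Each axis is high-passed (4th-order Butterworth, zero-phase) to remove
    the static gravity component, then the per-sample Euclidean norm across
    axes is taken.
    """
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        if xyz.ndim == 2 and xyz.shape[0] == 3:
            xyz = xyz.T
        else:
            raise InvalidInputError(
                f"expected (n, 3) axis array, got shape {xyz.shape}"
            )
    if fs <= 2 * highpass_hz:
        raise InvalidParameterError("fs must exceed twice the high-pass corner")
    sos = sps.butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, xyz, axis=0)
    mag = np.linalg.norm(filtered, axis=1)
    return SensorSeries(values=mag, dt=1.0 / fs, units="a.u.")


def resample_to_steps(
    series: SensorSeries, step: float, reducer: str = "rms"
) -> SensorSeries:
    """Reduce non-overlapping windows of length ``step`` to one value each.

    The trailing partial window is dropped.  ``reducer`` is "rms" (default;
    energy-preserving for vibration-like signals) or "mean".
    """
    if step < series.dt:
        raise InvalidParameterError(
            f"step {step} s shorter than series dt {series.dt} s"
        )
    per = int(round(step / series.dt))
    n_windows = series.values.size // per
    if n_windows == 0:
        raise InvalidInputError("series shorter than one step")
    windows = series.values[: n_windows * per].reshape(n_windows, per)
    if reducer == "rms":
        vals = np.sqrt(np.mean(windows**2, axis=1))
    elif reducer == "mean":
        vals = windows.mean(axis=1)
    else:
        raise InvalidParameterError(f"unknown reducer {reducer!r}")
    return SensorSeries(
        values=vals, dt=step, origin_time=series.origin_time, units=series.units
    )


def read_accel_csv(path):
    """t, ax, ay, az CSV -> ((n, 3) array, fs)."""
    df = pd.read_csv(path)
    for col in ("t", "ax", "ay", "az"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    t = df["t"].to_numpy(float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    fs = 1.0 / np.median(np.diff(t))
    return df[["ax", "ay", "az"]].to_numpy(float), fs


def write_series_csv(path, series: SensorSeries) -> None:
    with Path(path).open("w") as fh:
        fh.write("t,value\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.9g},{v:.9g}\n")
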