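"""Acceleration synthesis from position trajectories and motion noise.

A virtual accelerometer signal is the second time derivative of the
sensor's position trajectory (default: vertical axis), computed with a
second-order central finite difference.  No gravity term exists because
the signal is a pure kinematic derivative; real accelerometers would
additionally measure the gravity projection.

Soft-tissue artefact is modelled as additive sinusoidal motion noise
``N = A sin(2 pi f t + phi)`` with defaults A = 10 % of the signal's
maximal absolute value, f = 2 Hz, phi = 180 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["AccelSignal", "NoiseModel", "synthesize_acceleration", "apply_motion_noise"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class AccelSignal:
    """A synthesised acceleration time series for one sensor and axis."""

    time: np.ndarray
    values: np.ndarray  # m/s^2
    sensor_id: str
    fs_hz: float
    axis: str = "y"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.shape != self.values.shape:
            raise ValueError("time and values must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("acceleration values must be finite")


@dataclass(frozen=True)
class NoiseModel:
    """Additive sinusoidal motion-noise model.

    ``amplitude`` in m/s^2, or ``None`` to use ``amplitude_fraction``
    of the signal's maximal absolute value (default 10 %).
    """

    amplitude: float | None = None
    amplitude_fraction: float = 0.10
    frequency_hz: float = 2.0
    phase_rad: float = np.pi

    def __post_init__(self) -> None:
        if self.amplitude is not None and self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")


def _check_uniform(time: np.ndarray, fs: float) -> None:
    dt = np.diff(time)
    if np.any(np.abs(dt - 1.0 / fs) > 1e-9):
        raise ValueError("time vector must be uniform with step 1/fs")


def synthesize_acceleration(
    time: np.ndarray,
    positions: np.ndarray,
    fs_hz: float,
    sensor_id: str = "",
    axis: str = "y",
    method: str = "central",
) -> AccelSignal:
    """Second derivative of a position trajectory.

    Parameters
    ----------
    positions : ndarray
        Either (N, 3) Cartesian positions (``axis`` selects the
        component) or an (N,) scalar series.
    method : str
        ``"central"`` (default): a[i] = (p[i-1] - 2 p[i] + p[i+1]) fs^2
        with endpoints replicated from the nearest interior value.
        ``"spline"``: second derivative of a cubic spline through the
        samples (same contract, smoother at the cost of locality).
    """
    time = np.asarray(time, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if len(time) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    _check_uniform(time, fs_hz)
    if positions.ndim == 2:
        p = positions[:, _AXES[axis]]
    else:
        p = positions
    if method == "central":
        a = np.empty_like(p)
        a[1:-1] = (p[:-2] - 2.0 * p[1:-1] + p[2:]) * fs_hz**2
        a[0] = a[1]
        a[-1] = a[-2]
    elif method == "spline":
        a = CubicSpline(time, p).derivative(2)(time)
    else:
        raise ValueError(f"unknown differentiation method {method!r}")
    return AccelSignal(time=time, values=a, sensor_id=sensor_id, fs_hz=fs_hz, axis=axis)


def apply_motion_noise(signal: AccelSignal, model: NoiseModel | None = None) -> AccelSignal:
    """Superimpose the sinusoidal soft-tissue motion noise on a signal."""
    if model is None:
        model = NoiseModel()
    if len(signal.values) == 0:
        raise ValueError("signal is empty")
    amp = model.amplitude
    if amp is None:
        amp = model.amplitude_fraction * float(np.max(np.abs(signal.values)))
    noise = amp * np.sin(2.0 * np.pi * model.frequency_hz * signal.time + model.phase_rad)
    return AccelSignal(
        time=signal.time,
        values=signal.values + noise,
        sensor_id=signal.sensor_id,
        fs_hz=signal.fs_hz,
        axis=signal.axis,
    )
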