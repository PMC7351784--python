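"""Gait-marker extraction: stride segmentation, duration, count, cadence.

Two marker extraction algorithms operate on a synthesised acceleration
signal:

* ``smpl`` - peak detection directly on the raw signal;
* ``cmplx`` - Savitzky-Golay smoothing (polynomial order 5, 25-sample
  window, mirror-padded boundaries) followed by the identical peak
  pipeline.

The gait reference comes from the *unfiltered* vertical position of the
calcaneus: ground-contact (heel-strike) events are its local minima,
found by running the same peak detector on the negated series.

Peak detection contract: local maxima whose topographic prominence
exceeds a threshold (default one quarter of the signal range), then a
greedy minimum-distance filter in descending peak-height order (ties
broken by earlier time).  The minimum inter-peak distance defaults to a
quarter of the expected stride period (supplied, or estimated from the
dominant spectral peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_prominences, savgol_filter

from .synthesis import AccelSignal

__all__ = [
    "PeakDetectorConfig",
    "StrideSeries",
    "detect_peaks",
    "reference_heel_strikes",
    "smpl_markers",
    "cmplx_markers",
    "stride_markers",
    "stride_distance_error",
    "SAVGOL_WINDOW",
    "SAVGOL_ORDER",
]

SAVGOL_WINDOW = 25
SAVGOL_ORDER = 5


@dataclass(frozen=True)
class PeakDetectorConfig:
    """Parameters of the stride-segmentation peak detector.

    ``prominence=None`` resolves to ``prominence_fraction`` (default one
    quarter) of the signal range; ``min_distance_s=None`` resolves to
    ``0.25 x`` the expected stride period (``expected_period_s``, or
    estimated from the dominant non-DC spectral peak when not supplied).
    """

    prominence: float | None = None
    prominence_fraction: float = 0.25
    min_distance_s: float | None = None
    expected_period_s: float | None = None


@dataclass
class StrideSeries:
    """Ordered gait-event times and the per-stride durations they imply."""

    event_times_s: np.ndarray
    source: str = ""
    algorithm: str = ""

    def __post_init__(self) -> None:
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)
        if len(self.event_times_s) >= 2 and np.any(np.diff(self.event_times_s) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def durations_ms(self) -> np.ndarray:
        return np.diff(self.event_times_s) * 1000.0

    def __len__(self) -> int:
        return len(self.event_times_s)


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def _estimate_period(values: np.ndarray, fs: float) -> float | None:
    """Period (s) of the dominant non-DC spectral component, if any."""
    x = values - np.mean(values)
    if not np.any(x):
        return None
    spec = np.abs(np.fft.rfft(x))
    if len(spec) < 2:
        return None
    k = 1 + int(np.argmax(spec[1:]))
    freq = k * fs / len(values)
    return 1.0 / freq if freq > 0 else None


def detect_peaks(
    values: np.ndarray,
    fs_hz: float,
    config: PeakDetectorConfig | None = None,
) -> np.ndarray:
    """Event times (s) of prominent local maxima.

    A constant or empty-structure signal yields zero events (not an
    error); fewer than 3 samples is an error.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("signal must have at least 3 samples")
    if config is None:
        config = PeakDetectorConfig()

    rng_ = float(np.max(values) - np.min(values))
    if rng_ == 0.0:
        return np.array([])
    prominence = (config.prominence if config.prominence is not None
                  else rng_ * config.prominence_fraction)

    if config.min_distance_s is not None:
        dist_s = config.min_distance_s
    else:
        period = config.expected_period_s
        if period is None:
            period = _estimate_period(values, fs_hz)
        dist_s = 0.25 * period if period else 2.0 / fs_hz
    dist_samples = max(int(round(dist_s * fs_hz)), 2)

    candidates, _ = find_peaks(values)
    if len(candidates) == 0:
        return np.array([])
    proms = peak_prominences(values, candidates)[0]
    keep = candidates[proms >= prominence]
    if len(keep) == 0:
        return np.array([])

    # greedy min-distance filter, tallest first, ties -> earlier time
    order = sorted(range(len(keep)), key=lambda i: (-values[keep[i]], keep[i]))
    accepted: list[int] = []
    for i in order:
        idx = keep[i]
        if all(abs(idx - a) >= dist_samples for a in accepted):
            accepted.append(idx)
    return np.sort(np.asarray(accepted)) / fs_hz


# ---------------------------------------------------------------------------
# reference and algorithms
# ---------------------------------------------------------------------------

def reference_heel_strikes(
    time: np.ndarray,
    vertical_position: np.ndarray,
    fs_hz: float,
    config: PeakDetectorConfig | None = None,
) -> StrideSeries:
    """Heel-strike reference from the unfiltered calcaneus vertical series.

    Ground-contact events are the local minima of the vertical position,
    detected by applying the peak detector to the negated series.
    """
    events = detect_peaks(-np.asarray(vertical_position, dtype=float), fs_hz, config)
    if len(events) < 2:
        raise ValueError("insufficient strides: fewer than 2 heel-strike events")
    return StrideSeries(event_times_s=events + time[0], source="calcaneus", algorithm="reference")


def smpl_markers(signal: AccelSignal, config: PeakDetectorConfig | None = None) -> StrideSeries:
    """Gait events from the raw acceleration signal (no preprocessing)."""
    events = detect_peaks(signal.values, signal.fs_hz, config)
    return StrideSeries(
        event_times_s=events + signal.time[0], source=signal.sensor_id, algorithm="smpl"
    )


def cmplx_markers(signal: AccelSignal, config: PeakDetectorConfig | None = None) -> StrideSeries:
    """Gait events after Savitzky-Golay smoothing (order 5, 25 samples)."""
    if len(signal.values) < SAVGOL_WINDOW:
        raise ValueError(f"signal shorter than the {SAVGOL_WINDOW}-sample filter window")
    smoothed = savgol_filter(signal.values, SAVGOL_WINDOW, SAVGOL_ORDER, mode="mirror")
    events = detect_peaks(smoothed, signal.fs_hz, config)
    return StrideSeries(
        event_times_s=events + signal.time[0], source=signal.sensor_id, algorithm="cmplx"
    )


def stride_markers(strides: StrideSeries) -> dict[str, float]:
    """Stride count, mean stride duration (ms) and cadence (strides/min)."""
    d = strides.durations_ms
    if len(d) == 0:
        raise ValueError("need at least one stride duration")
    mean_ms = float(np.mean(d))
    return {
        "stride_count": int(len(d)),
        "mean_duration_ms": mean_ms,
        "cadence_spm": 60000.0 / mean_ms,
    }


def stride_distance_error(
    sensor: StrideSeries,
    reference: StrideSeries,
    x_time: np.ndarray,
    x_position: np.ndarray,
) -> np.ndarray:
    """Per-stride distance errors (cm) of sensor events vs the reference.

    Events are paired by the evaluation module's matcher; for each
    matched pair ``(t_s, t_c)`` the error is ``|x(t_s) - x(t_c)|`` with
    ``x`` the calcaneus anterior-posterior position, linearly
    interpolated.  Unmatched events are excluded.
    """
    from .evaluation import match_events  # local import avoids a module cycle

    matched = match_events(sensor.event_times_s, reference.event_times_s)
    xs = np.interp(matched.event_pairs[:, 0], x_time, x_position)
    xc = np.interp(matched.event_pairs[:, 1], x_time, x_position)
    return np.abs(xs - xc) * 100.0
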