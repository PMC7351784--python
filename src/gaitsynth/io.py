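"""File formats: trajectory CSV dialects, stride series, run configs.

The interchange format for trajectories is a tidy CSV with columns
``time_s, point, x_m, y_m, z_m``.  A wide dialect (one time column plus
``<point>_x/_y/_z`` columns, as produced by common mocap tabular
exports) is auto-detected on read.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .kinematics import TrajectorySet
from .markers import StrideSeries

log = logging.getLogger(__name__)

TIDY_COLUMNS = ["time_s", "point", "x_m", "y_m", "z_m"]


def write_trajectories(ts: TrajectorySet, path) -> None:
    frames = []
    for name in sorted(ts.points):
        arr = ts.points[name]
        frames.append(pd.DataFrame({
            "time_s": ts.time, "point": name,
            "x_m": arr[:, 0], "y_m": arr[:, 1], "z_m": arr[:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")


def _fs_from_time(time: np.ndarray, strict: bool) -> tuple[np.ndarray, float, bool]:
    dt = np.diff(time)
    if len(dt) == 0 or np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    step = float(np.median(dt))
    uniform = bool(np.all(np.abs(dt - step) <= 1e-9))
    if not uniform and strict:
        raise ValueError("non-uniform time vector (strict mode)")
    return time, 1.0 / step, uniform


def read_trajectories(path, strict: bool = False) -> TrajectorySet:
    """Read a trajectory CSV (tidy or wide dialect, auto-detected).

    Non-uniform time is resampled onto a uniform grid with a warning,
    or rejected in strict mode.  NaN positions and missing axis columns
    raise descriptive errors.
    """
    df = pd.read_csv(path)
    if set(TIDY_COLUMNS) <= set(df.columns):
        points: dict[str, np.ndarray] = {}
        time = None
        for name, grp in df.groupby("point", sort=True):
            grp = grp.sort_values("time_s")
            t = grp["time_s"].to_numpy(dtype=float)
            if time is None:
                time = t
            elif len(t) != len(time) or not np.allclose(t, time, atol=1e-9):
                raise ValueError(f"point {name!r} is not aligned with the common time vector")
            points[str(name)] = grp[["x_m", "y_m", "z_m"]].to_numpy(dtype=float)
    else:
        tcol = next((c for c in df.columns if c.lower() in ("time_s", "time", "t")), None)
        if tcol is None:
            raise ValueError("malformed header: no time column (expected 'time_s')")
        time = df[tcol].to_numpy(dtype=float)
        names = sorted({c[:-2] for c in df.columns if c.endswith(("_x", "_y", "_z")) and c != tcol})
        if not names:
            raise ValueError("malformed header: no '<point>_x/_y/_z' columns found")
        points = {}
        for name in names:
            cols = [f"{name}_{ax}" for ax in "xyz"]
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"missing axis column(s) {missing} for point {name!r}")
            points[name] = df[cols].to_numpy(dtype=float)

    for name, arr in points.items():
        if np.isnan(arr).any():
            raise ValueError(f"NaN positions in series {name!r}")

    time, fs, uniform = _fs_from_time(time, strict)
    if not uniform:
        log.warning("non-uniform time vector; resampling to %.6g Hz", fs)
        grid = time[0] + np.arange(int(np.floor((time[-1] - time[0]) * fs)) + 1) / fs
        points = {
            n: np.column_stack([np.interp(grid, time, a[:, k]) for k in range(3)])
            for n, a in points.items()
        }
        time = grid
    return TrajectorySet(time=time, points=points, fs_hz=fs)


def write_stride_series(ss: StrideSeries, path) -> None:
    d = np.concatenate([[np.nan], ss.durations_ms])
    pd.DataFrame({
        "source": ss.source, "algorithm": ss.algorithm,
        "event_time_s": ss.event_times_s, "duration_ms": d,
    }).to_csv(path, index=False, float_format="%.9g")


def read_stride_series(path) -> StrideSeries:
    df = pd.read_csv(path)
    return StrideSeries(
        event_times_s=df["event_time_s"].to_numpy(dtype=float),
        source=str(df["source"].iloc[0]),
        algorithm=str(df["algorithm"].iloc[0]),
    )


def write_accel_signal(signal, path) -> None:
    pd.DataFrame({
        "time_s": signal.time, "accel_mps2": signal.values, "sensor_id": signal.sensor_id,
    }).to_csv(path, index=False, float_format="%.9g")
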