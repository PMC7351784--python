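"""Synthetic gait kinematics and forward kinematics.

This module stands in for a motion-capture + musculoskeletal-simulation
pipeline.  It generates rigid articulated-body gait motion from
parametric joint-angle waveforms and computes 3-D position trajectories
for any attachment point (landmark or sensor offset) by forward
kinematics.

Model
-----
Gait is driven by a global stride phase ``Phi(t)``, piecewise linear in
time: stride ``k`` with duration ``T_k`` maps onto phase interval
``[k, k+1)``.  Per-stride durations are drawn i.i.d. from a normal
distribution (mean, SD given in ms) truncated below at 0.25 x mean.
Joint angles are truncated Fourier series of the fractional phase
``u = Phi mod 1`` (left-side limbs use ``u + 0.5``):

* hip flexion: fundamental + 2nd harmonic; the fundamental amplitude
  scales linearly with forward speed (``HIP_DEG_PER_MPS`` deg per m/s) -
  this is the generator's documented speed -> fore-aft amplitude mapping.
* knee flexion: squared raised cosine = 2-harmonic Fourier series, zero
  (extended knee) shortly after the stride boundary, so the calcaneus
  reaches its lowest point (ground contact) near the stride boundary.
* ankle, shoulder, elbow: small 2-harmonic series.
* pelvis: vertical oscillation at twice the stride frequency and a
  zero-mean periodic fore-aft sway (treadmill frame: no net forward
  displacement over an integer number of strides).

Each leg additionally carries a ground-contact impact transient: a
raised-cosine pulse in the hip and knee angles centred at the contact
phase (``U_CONTACT``), emulating the loading-response shock that makes
heel strikes detectable in real accelerometer data.  Near contact the
leg is almost vertical, so the pulse moves sensors mostly horizontally
in proportion to their fore-aft offset from the bone axis: ventral and
dorsal ring positions see a strong vertical acceleration transient once
per stride, lateral positions barely any - which is what creates the
spatial structure of the downstream error maps.

Hemiparetic asymmetry is modelled by a per-side irregularity factor
``f >= 0`` with two seeded per-stride effects on the affected leg,
using draws that are independent of ``f`` (common random numbers):

* waveform-shape modulation ``1 + f * r_k * sin^2(pi u)`` of the smooth
  joint waveforms (the envelope vanishes at stride boundaries), and
* contact-timing jitter: the impact pulse centre shifts by
  ``f * CONTACT_JITTER * q_k`` stride fractions (incoordination between
  the limb trajectory and the foot-strike shock).

Both effects scale monotonically with ``f``, so stride-to-stride
waveform deviation never decreases when ``f`` increases.

Stride durations used by the motion are snapped to the sampling grid so
that stride boundaries fall exactly on samples; this makes the noiseless
motion exactly periodic and the treadmill-frame invariant exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .body import BodyModel

__all__ = [
    "GaitParameters",
    "GaitMotion",
    "TrajectorySet",
    "sample_stride_durations",
    "simulate_gait",
    "compute_poses",
    "forward_kinematics",
    "trajectory_set",
    "stride_waveform_deviation",
    "HIP_DEG_PER_MPS",
]

#: hip fore-aft fundamental amplitude per unit forward speed (deg / (m/s))
HIP_DEG_PER_MPS = 6.0

#: default joint waveform amplitudes (deg); hip is speed-scaled instead
DEFAULT_AMPLITUDES_DEG: dict[str, float] = {
    "knee": 32.0,
    "ankle": 8.0,
    "shoulder": 12.0,
    "elbow": 18.0,
}

#: pelvis oscillation amplitudes
PELVIS_VERTICAL_AMP_M = 0.003   # at 2x stride frequency
PELVIS_FOREAFT_AMP_M_PER_MPS = 0.008  # zero-mean sway, scales with speed

#: ground-contact impact transient (loading response)
U_CONTACT = 0.28        # contact phase within the stride
PULSE_WIDTH = 0.14      # pulse width as a fraction of the stride
PULSE_HIP_RAD = 0.130   # hip pulse amplitude (rad)
PULSE_KNEE_RAD = 0.060  # knee pulse amplitude (rad)
CONTACT_JITTER = 0.35   # contact-phase jitter (stride fractions) per unit irregularity

#: per-stride amplitude scaling (T_k / mean T)^1.5, clipped to this range;
#: keeps acceleration magnitudes stationary when stride durations vary
#: (short strides are smaller movements, not faster ones)
AMP_FACTOR_CLIP = (0.5, 2.0)


@dataclass(frozen=True)
class GaitParameters:
    """Parameters of one synthetic gait trial.

    Attributes
    ----------
    speed_mps : float
        Forward (treadmill belt) speed in m/s; scales the hip fore-aft
        amplitude and the pelvis sway.
    mean_stride_ms, stride_sd_ms : float
        Mean and standard deviation of the per-stride duration (ms).
    amplitudes_deg : mapping
        Overrides for the joint waveform amplitudes (deg), keys as in
        :data:`DEFAULT_AMPLITUDES_DEG`.
    irregularity_affected, irregularity_other : float
        Dimensionless >= 0 within-stride waveform perturbation factors
        for the affected and the other body side.
    affected_side : str
        ``"left"``, ``"right"`` or ``"none"`` (both sides then use
        ``irregularity_other``).
    fs_hz : float
        Sampling rate, default 100 Hz.
    seed : int
        Seed for every random draw of the trial.
    """

    speed_mps: float = 3.0
    mean_stride_ms: float = 1000.0
    stride_sd_ms: float = 0.0
    amplitudes_deg: Mapping[str, float] = field(default_factory=dict)
    irregularity_affected: float = 0.0
    irregularity_other: float = 0.0
    affected_side: str = "none"
    fs_hz: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_stride_ms <= 0:
            raise ValueError("mean stride duration must be positive")
        if self.stride_sd_ms < 0:
            raise ValueError("stride duration SD must be non-negative")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.irregularity_affected < 0 or self.irregularity_other < 0:
            raise ValueError("irregularity factors must be >= 0")
        if self.affected_side not in ("left", "right", "none"):
            raise ValueError("affected_side must be 'left', 'right' or 'none'")

    def amplitude(self, joint: str) -> float:
        """Waveform amplitude (deg) for a joint, applying defaults."""
        if joint == "hip":
            return float(self.amplitudes_deg.get("hip", HIP_DEG_PER_MPS * self.speed_mps))
        return float(self.amplitudes_deg.get(joint, DEFAULT_AMPLITUDES_DEG[joint]))

    def irregularity(self, side: str) -> float:
        if self.affected_side == "none":
            return self.irregularity_other
        return self.irregularity_affected if side == self.affected_side else self.irregularity_other


@dataclass
class GaitMotion:
    """Joint-angle time series of one simulated trial.

    ``joint_angles`` maps segment name -> angle (rad) of that segment's
    proximal joint about the lateral (z) axis, relative to the parent.
    ``stride_starts`` are the stride boundary times (s) of the right
    leg including the final boundary; ``durations_ms`` are the grid-
    snapped per-stride durations actually used by the motion.
    """

    time: np.ndarray
    joint_angles: dict[str, np.ndarray]
    pelvis_pos: np.ndarray  # (N, 3)
    stride_starts: np.ndarray
    durations_ms: np.ndarray
    params: GaitParameters


@dataclass
class TrajectorySet:
    """Time-aligned 3-D position series for named attachment points."""

    time: np.ndarray
    points: dict[str, np.ndarray]  # name -> (N, 3)
    fs_hz: float

    def __post_init__(self) -> None:
        n = len(self.time)
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.fs_hz, rtol=0, atol=1e-9)):
            raise ValueError("time vector must be strictly increasing with constant step 1/fs")
        for name, arr in self.points.items():
            if arr.shape != (n, 3):
                raise ValueError(f"series {name!r} has shape {arr.shape}, expected ({n}, 3)")


# ---------------------------------------------------------------------------
# stride timing
# ---------------------------------------------------------------------------

def sample_stride_durations(params: GaitParameters, n_strides: int) -> np.ndarray:
    """Draw per-stride durations (ms), i.i.d. normal truncated at 0.25 x mean.

    Reproducible for a fixed ``params.seed``.
    """
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    rng = np.random.default_rng(params.seed)
    d = rng.normal(params.mean_stride_ms, params.stride_sd_ms, size=n_strides)
    return np.maximum(d, 0.25 * params.mean_stride_ms)


def _snap_to_grid(durations_ms: np.ndarray, fs: float) -> np.ndarray:
    """Round durations to whole samples (>= 4 samples per stride)."""
    samples = np.maximum(np.rint(durations_ms * fs / 1000.0), 4)
    return samples * 1000.0 / fs


# ---------------------------------------------------------------------------
# joint waveforms
# ---------------------------------------------------------------------------

def _hip(u: np.ndarray, amp_rad: float) -> np.ndarray:
    return amp_rad * (np.cos(2 * np.pi * u) + 0.06 * np.cos(4 * np.pi * u + 1.2))


def _knee(u: np.ndarray, amp_rad: float) -> np.ndarray:
    # squared raised cosine: 0.375 - 0.5 cos + 0.125 cos(2.) Fourier form;
    # extended (zero flexion) at u = 0.25 through stance, maximal at
    # u = 0.75 (mid-swing), lifting the foot so the calcaneus has a
    # single vertical minimum per stride (ground contact)
    return amp_rad * (0.5 - 0.5 * np.cos(2 * np.pi * (u - 0.25))) ** 2


def _ankle(u: np.ndarray, amp_rad: float) -> np.ndarray:
    return amp_rad * (np.sin(2 * np.pi * (u - 0.05)) + 0.3 * np.sin(4 * np.pi * (u - 0.05)))


def _shoulder(u: np.ndarray, amp_rad: float) -> np.ndarray:
    return -amp_rad * (np.cos(2 * np.pi * u) + 0.1 * np.cos(4 * np.pi * u))


def _elbow(u: np.ndarray, amp_rad: float) -> np.ndarray:
    return amp_rad * (0.6 - 0.5 * np.cos(2 * np.pi * (u - 0.55)) + 0.1 * np.cos(4 * np.pi * u))


def _perturb(wave: np.ndarray, u: np.ndarray, stride_idx: np.ndarray,
             draws: np.ndarray, factor: float) -> np.ndarray:
    """Multiplicative within-stride modulation; identity for factor 0."""
    if factor == 0.0:
        return wave
    env = np.sin(np.pi * u) ** 2
    return wave * (1.0 + factor * draws[stride_idx] * env)


def _contact_pulse(u: np.ndarray, stride_idx: np.ndarray, jitter_draws: np.ndarray,
                   factor: float) -> np.ndarray:
    """Raised-cosine impact pulse, per-stride contact-timing jitter ~ factor."""
    centers = U_CONTACT + factor * CONTACT_JITTER * jitter_draws[stride_idx]
    d = u - centers
    pulse = np.where(np.abs(d) < PULSE_WIDTH / 2.0,
                     0.5 * (1.0 + np.cos(2.0 * np.pi * d / PULSE_WIDTH)), 0.0)
    return pulse


def _amp_factor(u: np.ndarray, stride_idx: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Smoothly blended per-stride amplitude factor (C1 across boundaries)."""
    s = u * u * (3.0 - 2.0 * u)  # smoothstep
    nxt = np.minimum(stride_idx + 1, len(factors) - 1)
    return factors[stride_idx] + (factors[nxt] - factors[stride_idx]) * s


# ---------------------------------------------------------------------------
# gait simulation
# ---------------------------------------------------------------------------

def simulate_gait(body: BodyModel, params: GaitParameters, n_strides: int) -> GaitMotion:
    """Generate joint-angle and pelvis time series for ``n_strides`` strides.

    Raises
    ------
    ValueError
        If ``n_strides < 2`` (stride segmentation downstream needs at
        least two events).
    """
    if n_strides < 2:
        raise ValueError("n_strides must be >= 2 for stride segmentation")
    body.validate()
    fs = params.fs_hz
    durations = _snap_to_grid(sample_stride_durations(params, n_strides), fs)
    starts = np.concatenate([[0.0], np.cumsum(durations)]) / 1000.0  # s
    total_samples = int(round(starts[-1] * fs))
    time = np.arange(total_samples + 1) / fs

    # global phase, piecewise linear per stride
    k = np.clip(np.searchsorted(starts, time, side="right") - 1, 0, n_strides - 1)
    phi = k + (time - starts[k]) / (durations[k] / 1000.0)
    phi[-1] = float(n_strides)  # exact closure at the final boundary

    # per-stride perturbation draws, independent of the irregularity value
    rng = np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(1,)))
    draws = {side: rng.standard_normal(n_strides + 2) for side in ("right", "left")}
    # contact-timing jitter draws, clipped so jittered pulses stay inside the stride
    jitter = {side: np.clip(rng.standard_normal(n_strides + 2), -2.0, 2.0)
              for side in ("right", "left")}

    deg = np.pi / 180.0
    a_hip = params.amplitude("hip") * deg
    a_knee = params.amplitude("knee") * deg
    a_ankle = params.amplitude("ankle") * deg
    a_sh = params.amplitude("shoulder") * deg
    a_el = params.amplitude("elbow") * deg

    angles: dict[str, np.ndarray] = {}
    hip_pulse = float(params.amplitudes_deg.get("hip_pulse_deg", np.degrees(PULSE_HIP_RAD))) * deg
    knee_pulse = float(params.amplitudes_deg.get("knee_pulse_deg", np.degrees(PULSE_KNEE_RAD))) * deg

    # per-stride amplitude factors (T_k / mean T)^2, indices padded at the ends
    mean_t = float(np.mean(durations))
    f_by_stride = np.clip((durations / mean_t) ** 1.5, *AMP_FACTOR_CLIP)
    factors = np.concatenate([f_by_stride, [f_by_stride[-1], f_by_stride[-1]]])

    for side, offset in (("right", 0.0), ("left", 0.5)):
        u = np.mod(phi + offset, 1.0)
        idx = np.clip(np.floor(phi + offset).astype(int), 0, n_strides + 1)
        f = params.irregularity(side)
        amp = _amp_factor(u, idx, factors)
        pulse = _contact_pulse(u, idx, jitter[side], f)
        hip = amp * (_perturb(_hip(u, a_hip), u, idx, draws[side], f) + hip_pulse * pulse)
        knee = amp * (_perturb(_knee(u, a_knee), u, idx, draws[side], f) + knee_pulse * pulse)
        ankle = amp * _perturb(_ankle(u, a_ankle), u, idx, draws[side], f)
        s = side[0]
        angles[f"upper_leg_{s}"] = hip
        angles[f"lower_leg_{s}"] = -knee  # knee flexion folds the shank backwards
        angles[f"foot_{s}"] = ankle
        # arms swing in anti-phase with the ipsilateral leg
        ua = np.mod(phi + offset + 0.5, 1.0)
        angles[f"upper_arm_{s}"] = _shoulder(ua, a_sh)
        angles[f"lower_arm_{s}"] = _elbow(ua, a_el)

    hip_height = 0.42 + 0.43 + 0.05
    u_g = np.mod(phi, 1.0)
    idx_g = np.clip(np.floor(phi).astype(int), 0, n_strides + 1)
    amp_g = _amp_factor(u_g, idx_g, factors)
    pelvis = np.zeros((len(time), 3))
    pelvis[:, 0] = amp_g * PELVIS_FOREAFT_AMP_M_PER_MPS * params.speed_mps * np.sin(2 * np.pi * phi)
    pelvis[:, 1] = hip_height + amp_g * PELVIS_VERTICAL_AMP_M * np.cos(4 * np.pi * (phi - 0.05))

    return GaitMotion(
        time=time,
        joint_angles=angles,
        pelvis_pos=pelvis,
        stride_starts=starts,
        durations_ms=durations,
        params=params,
    )


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def _rotz(theta: np.ndarray) -> np.ndarray:
    """Batched rotation matrices about z, shape (N, 3, 3)."""
    c, s = np.cos(theta), np.sin(theta)
    R = np.zeros(theta.shape + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    R[..., 2, 2] = 1.0
    return R


def compute_poses(body: BodyModel, motion: GaitMotion) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """World pose (R (N,3,3), origin (N,3)) for every segment."""
    n = len(motion.time)
    poses: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    eye = np.broadcast_to(np.eye(3), (n, 3, 3))
    for name in body.topological_order():
        seg = body.segments[name]
        theta = motion.joint_angles.get(name)
        if name == "pelvis":
            parent_R, parent_o = eye, motion.pelvis_pos
        else:
            parent_R, parent_o = poses[seg.parent]
        origin = parent_o + np.einsum("nij,j->ni", parent_R, np.asarray(seg.attach, dtype=float))
        if theta is None:
            R = parent_R
        else:
            R = np.einsum("nij,njk->nik", parent_R, _rotz(np.asarray(theta)))
        poses[name] = (R, origin)
    return poses


def forward_kinematics(
    body: BodyModel,
    motion: GaitMotion,
    point: str | tuple[str, np.ndarray],
    poses: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> np.ndarray:
    """Position series (N, 3) of a landmark name or ``(segment, offset)``.

    Raises
    ------
    KeyError
        For an unknown landmark or segment.
    """
    if poses is None:
        poses = compute_poses(body, motion)
    if isinstance(point, str):
        if point not in body.landmarks:
            raise KeyError(f"unknown landmark {point!r}")
        segname, offset = body.landmarks[point]
    else:
        segname, offset = point
        if segname not in body.segments:
            raise KeyError(f"unknown segment {segname!r}")
    R, origin = poses[segname]
    return origin + np.einsum("nij,j->ni", R, np.asarray(offset, dtype=float))


def positions_for_offsets(
    poses: dict[str, tuple[np.ndarray, np.ndarray]],
    segment: str,
    offsets: np.ndarray,
) -> np.ndarray:
    """Positions (N, M, 3) of M offsets on one segment; batched FK."""
    R, origin = poses[segment]
    return origin[:, None, :] + np.einsum("nij,mj->nmi", R, np.asarray(offsets, dtype=float))


def trajectory_set(
    body: BodyModel,
    motion: GaitMotion,
    points: Mapping[str, str | tuple[str, np.ndarray]],
) -> TrajectorySet:
    """Forward-kinematics trajectories for a named collection of points."""
    poses = compute_poses(body, motion)
    data = {name: forward_kinematics(body, motion, pt, poses=poses) for name, pt in points.items()}
    return TrajectorySet(time=motion.time, points=data, fs_hz=motion.params.fs_hz)


# ---------------------------------------------------------------------------
# analysis helper
# ---------------------------------------------------------------------------

def stride_waveform_deviation(motion: GaitMotion, segment: str, n_grid: int = 64) -> float:
    """Stride-to-stride RMS waveform deviation of one joint-angle series.

    Each stride's angle waveform is resampled onto a common phase grid;
    the result is the RMS over the grid of the across-stride standard
    deviation.  Zero for a perfectly periodic series.
    """
    angles = motion.joint_angles[segment]
    starts = motion.stride_starts
    grid = np.linspace(0.0, 1.0, n_grid, endpoint=False)
    waves = []
    for k in range(len(starts) - 1):
        t = starts[k] + grid * (starts[k + 1] - starts[k])
        waves.append(np.interp(t, motion.time, angles))
    waves = np.asarray(waves)
    return float(np.sqrt(np.mean(np.std(waves, axis=0) ** 2)))
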