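"""Virtual sensor grids on body segments.

Ring sensors are indexed by a ring index ``Rx`` (1-based, proximal ->
distal along the bone long axis) and a circumferential index ``Sx``
(1-based, 16 positions per ring, 22.5 deg steps, ``S1`` on the ventral
midline increasing toward the lateral side).  Rings of a segment span a
fixed fraction of the bone length (15 % to 85 %), so doubling the number
of rings doubles the spatial density over the same extent.

The foot carries its own convention on a rigid (non-deforming) shoe
surface: two perimeter rows of 36 sensors each (72 total) around an
elliptical shoe outline, plus a 5 x 5 instep grid (25), i.e. 97 sensors
per foot.

Sensors are massless point markers rigidly welded to their segment; they
never influence the motion of any other point.

Standard layouts:

* ``fullbody_cs1`` - 834 sensors: per side, upper arm 4 rings x 16 = 64,
  lower arm 4 x 16 = 64, upper leg 6 x 16 = 96, lower leg 6 x 16 = 96,
  foot 97.
* ``upperleg_cs2`` - 384 sensors: 12 rings x 16 per upper leg, both
  sides (double the ring density of the full-body layout).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .body import BodyModel

__all__ = [
    "SensorSpec",
    "SensorLayout",
    "build_fullbody_layout",
    "build_upperleg_layout",
    "build_layout",
    "resolve_offsets",
    "RING_SPAN",
]

#: fractional extent of the bone long axis covered by rings (proximal, distal)
RING_SPAN = (0.15, 0.85)

#: circumferential positions per ring
SENSORS_PER_RING = 16

#: radial offset from the bone axis per segment (m)
SEGMENT_RADIUS_M = {
    "upper_arm": 0.045,
    "lower_arm": 0.035,
    "upper_leg": 0.06,
    "lower_leg": 0.05,
}

#: ring counts of the full-body layout
_FULLBODY_RINGS = {"upper_arm": 4, "lower_arm": 4, "upper_leg": 6, "lower_leg": 6}

# shoe geometry (foot frame: origin at ankle, +x forward)
_SHOE_CENTER_X = 0.10
_SHOE_HALF_LENGTH = 0.12
_SHOE_HALF_WIDTH = 0.05
_SHOE_ROW_Y = (-0.030, -0.055)
_SHOE_ROW_COUNT = 36
_INSTEP_Y = 0.020
_INSTEP_X = (0.05, 0.17)
_INSTEP_Z = (-0.03, 0.03)
_INSTEP_N = 5


@dataclass(frozen=True)
class SensorSpec:
    """One virtual sensor position.

    ``ring`` is the 1-based ring index for limb sensors; for foot
    sensors it is the perimeter row index (1 or 2), or 3 for the instep
    grid.  ``explicit_offset`` carries the precomputed segment-frame
    offset for foot sensors (limb sensors are resolved from ring
    fraction, angle and radius).
    """

    id: str
    segment: str  # base name, e.g. "upper_leg"
    side: str  # "L" | "R"
    ring: int
    sx: int
    axial_fraction: float
    angle_deg: float
    radius_m: float
    explicit_offset: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")
        if self.explicit_offset is None and not (1 <= self.sx <= SENSORS_PER_RING):
            raise ValueError(f"Sx must be in 1..{SENSORS_PER_RING} for ring sensors")

    @property
    def body_segment(self) -> str:
        return f"{self.segment}_{self.side.lower()}"


@dataclass
class SensorLayout:
    """Named collection of sensor specs with unique ids."""

    name: str
    sensors: list[SensorSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sensors]
        if len(ids) != len(set(ids)):
            raise ValueError("sensor ids must be unique within a layout")

    def __len__(self) -> int:
        return len(self.sensors)

    def __iter__(self):
        return iter(self.sensors)

    def by_id(self) -> dict[str, SensorSpec]:
        return {s.id: s for s in self.sensors}

    def subset(self, segment: str | None = None, side: str | None = None) -> list[SensorSpec]:
        out = self.sensors
        if segment is not None:
            out = [s for s in out if s.segment == segment]
        if side is not None:
            out = [s for s in out if s.side == side]
        return out

    def counts(self) -> dict[tuple[str, str], int]:
        c: dict[tuple[str, str], int] = {}
        for s in self.sensors:
            key = (s.segment, s.side)
            c[key] = c.get(key, 0) + 1
        return c

    # -- serialisation ------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sensors:
            off = s.explicit_offset
            rows.append(
                dict(
                    id=s.id, segment=s.segment, side=s.side, ring=s.ring, sx=s.sx,
                    axial_fraction=s.axial_fraction, angle_deg=s.angle_deg,
                    radius_m=s.radius_m,
                    offset_x=off[0] if off else np.nan,
                    offset_y=off[1] if off else np.nan,
                    offset_z=off[2] if off else np.nan,
                )
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, name: str = "custom") -> "SensorLayout":
        df = pd.read_csv(path)
        sensors = []
        for row in df.itertuples(index=False):
            off = None
            if not np.isnan(row.offset_x):
                off = (float(row.offset_x), float(row.offset_y), float(row.offset_z))
            sensors.append(
                SensorSpec(
                    id=row.id, segment=row.segment, side=row.side, ring=int(row.ring),
                    sx=int(row.sx), axial_fraction=float(row.axial_fraction),
                    angle_deg=float(row.angle_deg), radius_m=float(row.radius_m),
                    explicit_offset=off,
                )
            )
        return cls(name=name, sensors=sensors)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _ring_fractions(n_rings: int) -> np.ndarray:
    return np.linspace(RING_SPAN[0], RING_SPAN[1], n_rings)


def _ring_sensors(segment: str, side: str, n_rings: int) -> list[SensorSpec]:
    radius = SEGMENT_RADIUS_M[segment]
    fractions = _ring_fractions(n_rings)
    out = []
    for r, frac in enumerate(fractions, start=1):
        for sx in range(1, SENSORS_PER_RING + 1):
            out.append(
                SensorSpec(
                    id=f"{segment}_{side}_R{r}S{sx}",
                    segment=segment, side=side, ring=r, sx=sx,
                    axial_fraction=float(frac),
                    angle_deg=(sx - 1) * 360.0 / SENSORS_PER_RING,
                    radius_m=radius,
                )
            )
    return out


def _foot_sensors(side: str) -> list[SensorSpec]:
    """Two 36-sensor perimeter rows plus a 5x5 instep grid (97 total)."""
    zsign = 1.0 if side == "R" else -1.0
    out = []
    for row, y in enumerate(_SHOE_ROW_Y, start=1):
        for j in range(_SHOE_ROW_COUNT):
            t = 2 * np.pi * (j + 0.5) / _SHOE_ROW_COUNT
            off = (
                _SHOE_CENTER_X + _SHOE_HALF_LENGTH * np.cos(t),
                y,
                zsign * _SHOE_HALF_WIDTH * np.sin(t),
            )
            out.append(
                SensorSpec(
                    id=f"foot_{side}_R{row}S{j + 1}",
                    segment="foot", side=side, ring=row, sx=j + 1,
                    axial_fraction=0.0, angle_deg=np.degrees(t), radius_m=0.0,
                    explicit_offset=tuple(float(v) for v in off),
                )
            )
    xs = np.linspace(*_INSTEP_X, _INSTEP_N)
    zs = np.linspace(*_INSTEP_Z, _INSTEP_N)
    k = 0
    for x in xs:
        for z in zs:
            k += 1
            out.append(
                SensorSpec(
                    id=f"foot_{side}_R3S{k}",
                    segment="foot", side=side, ring=3, sx=k,
                    axial_fraction=0.0, angle_deg=0.0, radius_m=0.0,
                    explicit_offset=(float(x), _INSTEP_Y, float(zsign * z)),
                )
            )
    return out


def build_fullbody_layout() -> SensorLayout:
    """The 834-sensor full-body layout (arms, legs and feet, both sides)."""
    sensors: list[SensorSpec] = []
    for side in ("R", "L"):
        for segment, n_rings in _FULLBODY_RINGS.items():
            sensors.extend(_ring_sensors(segment, side, n_rings))
        sensors.extend(_foot_sensors(side))
    return SensorLayout(name="fullbody_cs1", sensors=sensors)


def build_upperleg_layout() -> SensorLayout:
    """The 384-sensor upper-leg layout: 12 rings x 16 per upper leg."""
    sensors: list[SensorSpec] = []
    for side in ("R", "L"):
        sensors.extend(_ring_sensors("upper_leg", side, 12))
    return SensorLayout(name="upperleg_cs2", sensors=sensors)


_BUILDERS = {"fullbody_cs1": build_fullbody_layout, "upperleg_cs2": build_upperleg_layout}


def build_layout(name: str) -> SensorLayout:
    """Build a named standard layout; raises for an unknown name."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise ValueError(f"unknown layout {name!r}; available: {sorted(_BUILDERS)}") from None


# ---------------------------------------------------------------------------
# offset resolution
# ---------------------------------------------------------------------------

def resolve_offsets(layout: SensorLayout, body: BodyModel) -> dict[str, np.ndarray]:
    """Rigid segment-frame offset for every sensor in the layout.

    For ring sensors the offset is the axial position (ring fraction
    along the bone axis) plus the radial offset at the sensor's angle,
    measured from the ventral (+x) direction toward the lateral side
    (+z on the right, -z on the left, giving left/right mirror
    symmetry).  Foot sensors use their stored shoe-surface offsets.

    Raises
    ------
    KeyError
        Listing every sensor whose body segment does not exist.
    """
    missing = [s.id for s in layout if s.body_segment not in body.segments]
    if missing:
        raise KeyError(f"unresolved sensors (unknown segments): {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    offsets: dict[str, np.ndarray] = {}
    for s in layout:
        if s.explicit_offset is not None:
            offsets[s.id] = np.asarray(s.explicit_offset, dtype=float)
            continue
        seg = body.segments[s.body_segment]
        axial = seg.axis() * (s.axial_fraction * seg.length)
        zsign = 1.0 if s.side == "R" else -1.0
        a = np.radians(s.angle_deg)
        radial = s.radius_m * (np.cos(a) * np.array([1.0, 0.0, 0.0])
                               + np.sin(a) * np.array([0.0, 0.0, zsign]))
        offsets[s.id] = axial + radial
    return offsets
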