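"""Rigid articulated body model.

The body is a kinematic tree of rigid segments rooted at the pelvis:
pelvis, thorax, upper/lower arms, upper/lower legs and feet, left and
right.  Each segment has a length, a proximal joint attached to a point
on its parent, and a rest direction of its long (bone) axis expressed in
its own frame.  Named landmarks (one calcaneus per foot) are points
rigidly attached to a segment.

Frame convention throughout the package: x anterior-posterior (forward
positive), y vertical (up positive), z lateral (toward the right side
positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["Segment", "BodyModel", "default_body"]


@dataclass(frozen=True)
class Segment:
    """One rigid segment of the kinematic tree.

    Parameters
    ----------
    name : str
        Unique segment name, e.g. ``"upper_leg_r"``.
    length : float
        Bone length in metres; must be positive.
    parent : str or None
        Name of the parent segment; ``None`` only for the pelvis root.
    attach : tuple of float
        Position of this segment's proximal joint in the parent frame (m).
    direction : tuple of float
        Unit vector of the bone long axis in the segment's own frame at
        rest, pointing proximal -> distal.
    """

    name: str
    length: float
    parent: str | None
    attach: tuple[float, float, float]
    direction: tuple[float, float, float]

    def axis(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError(f"segment {self.name!r} has zero direction")
        return d / n


@dataclass
class BodyModel:
    """Kinematic tree of segments plus named landmarks.

    ``landmarks`` maps a landmark name to ``(segment, offset)`` where the
    offset is expressed in the segment frame (origin at the proximal
    joint).
    """

    segments: dict[str, Segment]
    landmarks: dict[str, tuple[str, tuple[float, float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        if "pelvis" not in self.segments:
            raise ValueError("body must contain a 'pelvis' root segment")
        roots = [s for s in self.segments.values() if s.parent is None]
        if [s.name for s in roots] != ["pelvis"]:
            raise ValueError("segment graph must have the pelvis as its only root")
        for seg in self.segments.values():
            if seg.length <= 0:
                raise ValueError(f"segment {seg.name!r} has non-positive length")
            if seg.parent is not None and seg.parent not in self.segments:
                raise ValueError(f"segment {seg.name!r} has unknown parent {seg.parent!r}")
        # tree check: walking to the root from every node must terminate
        for seg in self.segments.values():
            seen = set()
            cur: str | None = seg.name
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in segment graph at {cur!r}")
                seen.add(cur)
                cur = self.segments[cur].parent
        for name, (segname, _) in self.landmarks.items():
            if segname not in self.segments:
                raise ValueError(f"landmark {name!r} on unknown segment {segname!r}")
        for side in ("l", "r"):
            foot = f"foot_{side}"
            if foot in self.segments:
                calcs = [n for n, (s, _) in self.landmarks.items() if s == foot and n.startswith("calcaneus")]
                if len(calcs) != 1:
                    raise ValueError(f"{foot} must carry exactly one calcaneus landmark")

    # -- ordering -----------------------------------------------------
    def topological_order(self) -> list[str]:
        """Segment names ordered so every parent precedes its children."""
        order: list[str] = []
        remaining = dict(self.segments)
        placed: set[str] = set()
        while remaining:
            progressed = False
            for name, seg in list(remaining.items()):
                if seg.parent is None or seg.parent in placed:
                    order.append(name)
                    placed.add(name)
                    del remaining[name]
                    progressed = True
            if not progressed:  # pragma: no cover - validate() already rejects
                raise ValueError("segment graph is not a tree")
        return order

    # -- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "segments": {
                s.name: {
                    "length": s.length,
                    "parent": s.parent,
                    "attach": list(s.attach),
                    "direction": list(s.direction),
                }
                for s in self.segments.values()
            },
            "landmarks": {n: {"segment": s, "offset": list(o)} for n, (s, o) in self.landmarks.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BodyModel":
        segments = {
            name: Segment(
                name=name,
                length=float(v["length"]),
                parent=v.get("parent"),
                attach=tuple(v.get("attach", (0.0, 0.0, 0.0))),
                direction=tuple(v.get("direction", (0.0, -1.0, 0.0))),
            )
            for name, v in d["segments"].items()
        }
        landmarks = {
            n: (v["segment"], tuple(v["offset"])) for n, v in d.get("landmarks", {}).items()
        }
        return cls(segments=segments, landmarks=landmarks)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "BodyModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: default anthropometry (m); roughly a 1.77 m adult
_DEFAULT_GEOMETRY = {
    "pelvis": dict(length=0.10, parent=None, attach=(0, 0, 0), direction=(0, 1, 0)),
    "thorax": dict(length=0.50, parent="pelvis", attach=(0, 0.10, 0), direction=(0, 1, 0)),
    "upper_arm_r": dict(length=0.33, parent="thorax", attach=(0, 0.50, 0.20), direction=(0, -1, 0)),
    "upper_arm_l": dict(length=0.33, parent="thorax", attach=(0, 0.50, -0.20), direction=(0, -1, 0)),
    "lower_arm_r": dict(length=0.27, parent="upper_arm_r", attach=(0, -0.33, 0), direction=(0, -1, 0)),
    "lower_arm_l": dict(length=0.27, parent="upper_arm_l", attach=(0, -0.33, 0), direction=(0, -1, 0)),
    "upper_leg_r": dict(length=0.42, parent="pelvis", attach=(0, 0, 0.12), direction=(0, -1, 0)),
    "upper_leg_l": dict(length=0.42, parent="pelvis", attach=(0, 0, -0.12), direction=(0, -1, 0)),
    "lower_leg_r": dict(length=0.43, parent="upper_leg_r", attach=(0, -0.42, 0), direction=(0, -1, 0)),
    "lower_leg_l": dict(length=0.43, parent="upper_leg_l", attach=(0, -0.42, 0), direction=(0, -1, 0)),
    "foot_r": dict(length=0.25, parent="lower_leg_r", attach=(0, -0.43, 0), direction=(1, 0, 0)),
    "foot_l": dict(length=0.25, parent="lower_leg_l", attach=(0, -0.43, 0), direction=(1, 0, 0)),
}

_DEFAULT_LANDMARKS = {
    "calcaneus_r": ("foot_r", (-0.05, -0.04, 0.0)),
    "calcaneus_l": ("foot_l", (-0.05, -0.04, 0.0)),
}


def default_body() -> BodyModel:
    """The default 12-segment body model."""
    segments = {name: Segment(name=name, **kw) for name, kw in _DEFAULT_GEOMETRY.items()}
    return BodyModel(segments=segments, landmarks=dict(_DEFAULT_LANDMARKS))
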