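"""Clinician-style (trapezoid technique) neck-shaft angle measurement.

The trapezoid technique treats an elongated structure (femoral neck,
femoral shaft, or prosthesis stem) as a quadrangle: two transverse
segments are marked across the structure and its axis is the straight
line through the two segment midpoints.  The NSA is then the angle
between the shaft axis and the neck (or stem) axis.

This module is the measurement oracle for synthetic scenes: the scene
generator emits landmark segments, and the trapezoid construction here
must recover the generating geometry exactly (up to floating point).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import fold_half_open, segment_angle, unit_vector

__all__ = [
    "Axis",
    "LandmarkSegmentPair",
    "trapezoid_axis",
    "axes_angle",
    "nsa_from_landmarks",
    "read_landmarks",
    "write_landmarks",
    "nsa_table",
]

#: structures a landmark pair may annotate
STRUCTURES = ("femoral_neck", "femoral_shaft", "stem")


@dataclass(frozen=True)
class Axis:
    """A directed line: a point on it and a unit direction vector."""

    point: tuple
    direction: tuple

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.hypot(d[0], d[1]), 1.0, atol=1e-9):
            raise ValueError("axis direction must have unit norm")

    @property
    def angle(self) -> float:
        """Signed angle from horizontal in (-90, 90]."""
        dx, dy = self.direction
        p0 = (0.0, 0.0)
        p1 = (dx, dy)
        return segment_angle(p0, p1)


@dataclass(frozen=True)
class LandmarkSegmentPair:
    """Two transverse segments marked across one anatomical structure.

    Each segment is a pair of ``(x, y)`` points in image coordinates.
    """

    segment_a: tuple
    segment_b: tuple
    structure: str = "femoral_neck"

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        for seg in (self.segment_a, self.segment_b):
            p, q = np.asarray(seg[0], float), np.asarray(seg[1], float)
            if np.allclose(p, q):
                raise ValueError("degenerate landmark segment")

    def midpoints(self):
        ma = (np.asarray(self.segment_a[0], float) + np.asarray(self.segment_a[1], float)) / 2.0
        mb = (np.asarray(self.segment_b[0], float) + np.asarray(self.segment_b[1], float)) / 2.0
        return ma, mb


def trapezoid_axis(pair: LandmarkSegmentPair) -> Axis:
    """Axis through the midpoints of the two transverse segments.

    The direction is normalised to have a non-negative second (y)
    component; for a horizontal axis the x component is made
    non-negative instead.
    """
    ma, mb = pair.midpoints()
    if np.allclose(ma, mb):
        raise ValueError("segment midpoints coincide; axis undefined")
    d = unit_vector(mb - ma)
    if d[1] < 0 or (d[1] == 0 and d[0] < 0):
        d = -d
    return Axis(point=tuple(ma), direction=(float(d[0]), float(d[1])))


def axes_angle(axis_1: Axis, axis_2: Axis) -> float:
    """Angle in [0, 180] degrees between two *directed* axes.

    The full signed directions are used (the result is not folded into
    [0, 90]), so the caller's orientation of each axis selects between
    an angle and its supplement.
    """
    d1 = unit_vector(axis_1.direction)
    d2 = unit_vector(axis_2.direction)
    cos = float(np.clip(np.dot(d1, d2), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))


def nsa_from_landmarks(
    shaft_pair: LandmarkSegmentPair, neck_pair: LandmarkSegmentPair
) -> float:
    """Neck-shaft angle from shaft and neck (or stem) landmark pairs.

    Each axis is reduced to its signed from-horizontal angle in
    (-90, 90] and the NSA is the sum of the two absolute values.  Under
    the package-wide convention (shaft tilted one way, neck/stem the
    other) this equals the angle between the distally-directed shaft
    axis and the proximally-directed neck axis, i.e. the clinical NSA.
    """
    a_shaft = fold_half_open(trapezoid_axis(shaft_pair).angle)
    a_neck = fold_half_open(trapezoid_axis(neck_pair).angle)
    return abs(a_shaft) + abs(a_neck)


# ---------------------------------------------------------------------------
# landmark CSV interchange: one row per segment,
# hip_id,structure,x1,y1,x2,y2 (two rows per structure per hip)
# ---------------------------------------------------------------------------

_COLUMNS = ["hip_id", "structure", "x1", "y1", "x2", "y2"]


def write_landmarks(path, landmarks: dict) -> None:
    """Write a ``{hip_id: {structure: LandmarkSegmentPair}}`` mapping to CSV."""
    rows = []
    for hip_id in sorted(landmarks):
        for structure in sorted(landmarks[hip_id]):
            pair = landmarks[hip_id][structure]
            for seg in (pair.segment_a, pair.segment_b):
                (x1, y1), (x2, y2) = seg
                rows.append([hip_id, structure, x1, y1, x2, y2])
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False, float_format="%.6f")


def read_landmarks(path) -> dict:
    """Read a landmark CSV into ``{hip_id: {structure: LandmarkSegmentPair}}``.

    Each (hip, structure) must appear exactly twice (the two transverse
    segments of the trapezoid).
    """
    df = pd.read_csv(Path(path))
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing columns: {sorted(missing)}")
    out: dict = {}
    for (hip_id, structure), grp in df.groupby(["hip_id", "structure"], sort=False):
        if len(grp) != 2:
            raise ValueError(
                f"hip {hip_id!r} structure {structure!r}: expected 2 segments, got {len(grp)}"
            )
        segs = [((r.x1, r.y1), (r.x2, r.y2)) for r in grp.itertuples()]
        out.setdefault(str(hip_id), {})[structure] = LandmarkSegmentPair(
            segment_a=segs[0], segment_b=segs[1], structure=structure
        )
    return out


def nsa_table(landmarks: dict) -> pd.DataFrame:
    """Per-hip trapezoid-technique NSA from a landmark mapping.

    Uses the femoral shaft pair plus the femoral neck pair if present,
    falling back to the stem pair (post-resurfacing the stem axis stands
    in for the native neck axis).
    """
    rows = []
    for hip_id in sorted(landmarks):
        pairs = landmarks[hip_id]
        if "femoral_shaft" not in pairs:
            raise ValueError(f"hip {hip_id!r}: femoral_shaft landmarks required")
        neck = pairs.get("femoral_neck") or pairs.get("stem")
        if neck is None:
            raise ValueError(f"hip {hip_id!r}: femoral_neck or stem landmarks required")
        rows.append([hip_id, nsa_from_landmarks(pairs["femoral_shaft"], neck)])
    return pd.DataFrame(rows, columns=["hip_id", "nsa_ap_clinician"])
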