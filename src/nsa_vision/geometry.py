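"""Planar geometry helpers shared across the measurement pipeline.

Coordinate and angle conventions
--------------------------------
Points are ``(x, y)`` pairs with ``x`` the image column and ``y`` the image
row, i.e. ``y`` grows *downward* as is usual for raster images.

Axis angles are signed degrees measured from the image horizontal,
counter-clockwise positive in the conventional (y-up) mathematical sense,
and folded into the half-open interval ``(-90, 90]``.  A vertical axis is
``+90`` (never ``-90``); a horizontal axis is ``0``.  Under this shared
convention a near-vertical femoral shaft has an angle near ``+85`` and an
oblique prosthesis stem an angle near ``-50``, so the neck-shaft angle
(NSA) is the sum of their absolute values (``~135`` degrees).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["fold_half_open", "segment_angle", "unit_vector"]


def fold_half_open(angle_deg: float) -> float:
    """Fold an angle in degrees into the half-open interval (-90, 90].

    ``-90`` maps to ``+90`` so that a vertical axis has a unique
    representation.
    """
    a = (float(angle_deg) + 90.0) % 180.0 - 90.0
    if a == -90.0:
        a = 90.0
    return a


def segment_angle(p0, p1) -> float:
    """Signed angle of the segment from ``p0`` to ``p1`` in (-90, 90].

    Points are ``(x, y)`` in image coordinates (y down); the angle is
    measured from the horizontal, counter-clockwise positive with y up,
    which is the convention used throughout the package.
    """
    x0, y0 = float(p0[0]), float(p0[1])
    x1, y1 = float(p1[0]), float(p1[1])
    dx = x1 - x0
    dy_up = -(y1 - y0)
    if dx == 0.0 and dy_up == 0.0:
        raise ValueError("degenerate segment: endpoints coincide")
    return fold_half_open(math.degrees(math.atan2(dy_up, dx)))


def unit_vector(v) -> np.ndarray:
    """Normalise a 2-vector; raises on the zero vector."""
    v = np.asarray(v, dtype=float)
    n = float(np.hypot(v[0], v[1]))
    if n == 0.0:
        raise ValueError("zero direction vector")
    return v / n
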