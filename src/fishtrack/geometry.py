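"""Shared spatial primitives: boxes, centroids, overlap, displacement angles.

Boxes are axis-aligned pixel rectangles ``(x, y, w, h)`` in a 0-based image
frame, *x* rightward and *y* downward, with half-open extent
``[x, x+w) x [y, y+h)``.  Angles follow the compass convention used for the
movement bins: 0 deg points *up* in the image (decreasing y) and angles
increase clockwise, so 90 deg is rightward, 180 deg downward, 270 deg
leftward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BoundingBox",
    "Point",
    "iou",
    "centroid",
    "displacement_angle",
    "MIN_DISPLACEMENT_PX",
]

#: Displacements shorter than this (pixels) yield no angle observation:
#: the direction of a (near-)null vector is meaningless and sub-pixel
#: jitter would otherwise pollute the direction bins.
MIN_DISPLACEMENT_PX = 0.5


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel rectangle with positive width and height."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"degenerate box: w={self.w}, h={self.h} (must be > 0)")
        for v in (self.x, self.y, self.w, self.h):
            if not math.isfinite(v):
                raise ValueError(f"non-finite box coordinate: {v}")

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    def area(self) -> float:
        return self.w * self.h

    def as_xywh(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.w, self.h)


@dataclass(frozen=True)
class Point:
    x: float
    y: float


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes, in [0, 1].

    Symmetric; 1.0 iff the boxes coincide, 0.0 iff they are disjoint.
    """
    ix = min(a.x2, b.x2) - max(a.x, b.x)
    iy = min(a.y2, b.y2) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area() + b.area() - inter
    return inter / union


def centroid(b: BoundingBox) -> Point:
    """Center point of a box: ``(x + w/2, y + h/2)``."""
    return Point(b.x + b.w / 2.0, b.y + b.h / 2.0)


def displacement_angle(
    p_from: Point, p_to: Point, min_displacement: float = MIN_DISPLACEMENT_PX
) -> float | None:
    """Compass angle (degrees in [0, 360)) of the displacement p_from -> p_to.

    Under the image-frame compass convention (0 = up, clockwise positive),
    the angle is ``atan2(dx, -dy)`` because image *y* grows downward.
    Returns ``None`` when the displacement magnitude is below
    ``min_displacement`` pixels.
    """
    dx = p_to.x - p_from.x
    dy = p_to.y - p_from.y
    if math.hypot(dx, dy) < min_displacement:
        return None
    ang = math.degrees(math.atan2(dx, -dy))
    return ang % 360.0
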